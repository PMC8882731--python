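"""The six sequence feature encoders and concatenation-based fusion.

Every encoder is a pure function from a DNA window over {A,C,G,T,N} to a
dense numeric vector. Dimensionalities for a window of length L:

=========  ==============================  ==================
encoder    idea                            dimension
=========  ==============================  ==================
ONEHOT1    per-nucleotide one-hot (5 bits) 5 L
ONEHOT2    per-dinucleotide one-hot (25)   25 (L - 1)
AMNF       running mono-nucleotide freq.   L
ADNF       running di-nucleotide freq.     L - 1
DPCP       dinucleotide count x property   25 x P_d
TPCP       trinucleotide count x property  125 x P_t
FUSED      concatenation of components     sum of components
=========  ==============================  ==================

The one-hot codebook is lexicographic over the symbol order A<C<G<T<N
(AA -> 0, AC -> 1, ..., NT -> 23, NN -> 24). AMNF element t is the
frequency of the nucleotide at position t within the prefix of length t
(N counts like any symbol), so e.g. ACGTNA encodes to
(1, 0.5, 1/3, 0.25, 0.2, 1/3); ADNF does the same over the L-1
overlapping dinucleotides. DPCP/TPCP multiply each k-mer's count in the
window by its tabulated property values, flattened token-major.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from methylvote.property_tables import PropertyTable, kmer_tokens
from methylvote.sequence_io import DnaWindow, LabeledDataset

_SYMBOLS = "ACGTN"
_SYMBOL_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}

#: Dinucleotide one-hot codebook: token -> index, AA=0 ... NN=24.
DINUCLEOTIDE_CODEBOOK = {t: i for i, t in enumerate(kmer_tokens(2))}

ENCODER_NAMES = ("AMNF", "ADNF", "DPCP", "TPCP", "ONEHOT1", "ONEHOT2")


def _as_sequence(seq) -> str:
    s = seq.sequence if isinstance(seq, DnaWindow) else str(seq)
    bad = set(s) - set(_SYMBOLS)
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)}; sequences must be "
                         "normalized to {A,C,G,T,N} first")
    return s


def tokenize(seq, k: int) -> list[str]:
    """The L-k+1 overlapping k-mers of ``seq`` in 5'->3' order (step 1)."""
    s = _as_sequence(seq)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(s) < k:
        raise ValueError(f"window of length {len(s)} is shorter than k={k}")
    return [s[i:i + k] for i in range(len(s) - k + 1)]


def encode_onehot1(seq) -> np.ndarray:
    """Per-nucleotide one-hot encoding; dimension 5L, exactly L ones."""
    s = _as_sequence(seq)
    if not s:
        raise ValueError("cannot encode an empty sequence")
    out = np.zeros(5 * len(s))
    for t, c in enumerate(s):
        out[5 * t + _SYMBOL_INDEX[c]] = 1.0
    return out


def encode_onehot2(seq) -> np.ndarray:
    """Per-dinucleotide one-hot encoding; dimension 25(L-1), L-1 ones."""
    toks = tokenize(seq, 2)
    out = np.zeros(25 * len(toks))
    for t, tok in enumerate(toks):
        out[25 * t + DINUCLEOTIDE_CODEBOOK[tok]] = 1.0
    return out


def _accumulated_frequency(tokens: Sequence[str]) -> np.ndarray:
    counts: dict[str, int] = {}
    out = np.empty(len(tokens))
    for t, tok in enumerate(tokens, start=1):
        counts[tok] = counts.get(tok, 0) + 1
        out[t - 1] = counts[tok] / t
    return out


def encode_amnf(seq) -> np.ndarray:
    """Accumulated mono-nucleotide frequency; dimension L, values in (0,1]."""
    return _accumulated_frequency(tokenize(seq, 1))


def encode_adnf(seq) -> np.ndarray:
    """Accumulated di-nucleotide frequency; dimension L-1, values in (0,1]."""
    return _accumulated_frequency(tokenize(seq, 2))


def encode_pcp(seq, table: PropertyTable, normalize: bool = False) -> np.ndarray:
    """Count x property encoding (DPCP for k=2 tables, TPCP for k=3).

    Output cell (i, j) is N_i * PC_ij where N_i is the count of token i in
    the window and PC_ij its j-th tabulated property value; flattened
    token-major. With ``normalize=True`` counts are divided by the number
    of k-mers (L - k + 1).
    """
    toks = tokenize(seq, table.kmer_size)
    counts = np.zeros(len(table.tokens))
    index = {t: i for i, t in enumerate(table.tokens)}
    for tok in toks:
        try:
            counts[index[tok]] += 1
        except KeyError:
            raise KeyError(f"token {tok!r} missing from property table") from None
    if normalize:
        counts = counts / len(toks)
    return (counts[:, None] * table.values).ravel()


@dataclass(frozen=True)
class Encoder:
    """A named encoder specification: a pure window -> vector function.

    ``spec`` records how to rebuild the encoder (base name, fusion
    components, property tables) so a trained model can re-encode query
    windows identically.
    """

    name: str
    _fn: Callable[[str], np.ndarray]
    spec: dict | None = None

    def __call__(self, seq) -> np.ndarray:
        return self._fn(seq)

    def dim(self, length: int) -> int:
        probe = "A" * max(length, 1)
        return self(probe).shape[0]


def encode_fused(seq, encoders: Sequence) -> np.ndarray:
    """Concatenate the encodings of ``seq`` under >= 2 encoders, in order."""
    if len(encoders) < 2:
        raise ValueError("fusion needs at least 2 encoders")
    return np.concatenate([enc(seq) for enc in encoders])


def get_encoder(
    name: str,
    dinucleotide_table: PropertyTable | None = None,
    trinucleotide_table: PropertyTable | None = None,
    components: Sequence[str] | None = None,
) -> Encoder:
    """Build an :class:`Encoder` by name (case-insensitive).

    ``DPCP``/``TPCP`` use the bundled default property tables unless one
    is supplied. ``FUSED`` concatenates the named ``components`` (default
    ONEHOT1 + ONEHOT2).
    """
    key = name.upper()
    if key == "ONEHOT1":
        return Encoder("ONEHOT1", encode_onehot1, {"name": "ONEHOT1"})
    if key == "ONEHOT2":
        return Encoder("ONEHOT2", encode_onehot2, {"name": "ONEHOT2"})
    if key == "AMNF":
        return Encoder("AMNF", encode_amnf, {"name": "AMNF"})
    if key == "ADNF":
        return Encoder("ADNF", encode_adnf, {"name": "ADNF"})
    if key == "DPCP":
        if dinucleotide_table is None:
            from methylvote.property_tables import default_dinucleotide_table
            dinucleotide_table = default_dinucleotide_table()
        if dinucleotide_table.kmer_size != 2:
            raise ValueError("DPCP requires a kmer_size=2 property table")
        table = dinucleotide_table
        return Encoder("DPCP", lambda s: encode_pcp(s, table),
                       {"name": "DPCP", "dinucleotide_table": table})
    if key == "TPCP":
        if trinucleotide_table is None:
            from methylvote.property_tables import default_trinucleotide_table
            trinucleotide_table = default_trinucleotide_table()
        if trinucleotide_table.kmer_size != 3:
            raise ValueError("TPCP requires a kmer_size=3 property table")
        table = trinucleotide_table
        return Encoder("TPCP", lambda s: encode_pcp(s, table),
                       {"name": "TPCP", "trinucleotide_table": table})
    if key == "FUSED":
        names = tuple(components) if components else ("ONEHOT1", "ONEHOT2")
        subs = [get_encoder(n, dinucleotide_table, trinucleotide_table)
                for n in names]
        label = "FUSED(" + "+".join(e.name for e in subs) + ")"
        return Encoder(label, lambda s: encode_fused(s, subs),
                       {"name": "FUSED", "components": names,
                        "dinucleotide_table": dinucleotide_table,
                        "trinucleotide_table": trinucleotide_table})
    raise ValueError(f"unknown encoder {name!r}; choose from "
                     f"{ENCODER_NAMES + ('FUSED',)}")


def encode_matrix(data: LabeledDataset, encoder) -> np.ndarray:
    """Encode every window of ``data`` into a row of a feature matrix.

    Rows preserve dataset order. All windows must share one length so the
    rows have a common dimension.
    """
    if len(data) == 0:
        raise ValueError("cannot encode an empty dataset")
    if isinstance(encoder, str):
        encoder = get_encoder(encoder)
    lengths = {w.length for w in data.windows}
    if len(lengths) > 1:
        raise ValueError(f"windows have heterogeneous lengths {sorted(lengths)}")
    return np.vstack([encoder(w) for w in data.windows])


def export_matrix_csv(data: LabeledDataset, encoder, path) -> None:
    """Write the feature matrix as CSV with header ``id,label,f0,f1,...``."""
    import pandas as pd

    X = encode_matrix(data, encoder)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "label", data.labels)
    df.insert(0, "id", data.ids())
    df.to_csv(path, index=False)
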