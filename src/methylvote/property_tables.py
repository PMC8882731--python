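"""Physicochemical property tables for the DPCP/TPCP encoders.

A :class:`PropertyTable` maps every k-mer token over the {A,C,G,T,N}
alphabet (25 dinucleotides or 125 trinucleotides) to a vector of named
real-valued properties. Tables are pluggable inputs: they can be loaded
from TSV, and the bundled defaults below can be swapped for any table
with the same schema.

Bundled defaults — a synthetic stand-in
---------------------------------------
The bundled dinucleotide table carries 15 properties and the
trinucleotide table 11. Thermodynamic columns (enthalpy, entropy, free
energy) are the standard nearest-neighbor values; geometric and
flexibility columns are representative values assembled from the DNA
physicochemical property literature, not a byte-exact copy of any single
published compilation. Trinucleotide values are derived by averaging the
two constituent dinucleotide steps over the 11 structural scales.
Tokens containing ``N`` (the unidentified nucleotide) carry 0 for every
property. Treat the defaults as a reasonable stand-in, and supply your
own TSV when exact published scales matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SYMBOLS = "ACGTN"

# 16 standard dinucleotides x 15 properties. Enthalpy (kcal/mol), entropy
# (cal/mol/K) and free energy (kcal/mol, 37C) are unified nearest-neighbor
# parameters; the remaining columns are representative literature scales.
_DINUC_TSV = """\
token	Twist	Tilt	Roll	Shift	Slide	Rise	Stacking_energy	Enthalpy	Entropy	Free_energy	Melting_temperature	Hydrophilicity	Bendability	Propeller_twist	Protein_deformability
AA	35.62	-1.4	0.7	-0.03	-0.08	3.16	-5.37	-7.9	-22.2	-1.00	54.50	0.04	-0.27	-18.66	2.9
AC	34.40	-0.1	0.7	0.13	-0.58	3.41	-10.51	-8.4	-22.4	-1.44	97.73	0.14	-0.20	-13.10	2.3
AG	27.70	-1.7	4.5	0.09	-0.25	3.63	-6.78	-7.8	-21.0	-1.28	58.42	0.08	-0.08	-14.00	2.1
AT	31.50	0.0	1.1	0.00	-0.59	3.89	-6.57	-7.2	-20.4	-0.88	57.02	0.10	-0.28	-15.01	1.6
CA	34.50	0.5	4.7	0.09	0.53	3.23	-6.57	-8.5	-22.7	-1.45	54.71	0.21	-0.01	-9.45	9.8
CC	33.67	-0.1	3.6	0.05	-0.22	3.47	-8.26	-8.0	-19.9	-1.84	85.97	0.49	-0.03	-8.11	6.1
CG	29.80	0.0	5.4	0.00	0.41	3.21	-9.61	-10.6	-27.2	-2.17	72.55	0.35	-0.03	-10.03	12.1
CT	27.70	1.7	4.5	-0.09	-0.25	3.63	-6.78	-7.8	-21.0	-1.28	58.42	0.08	-0.08	-14.00	2.1
GA	36.90	-1.5	1.9	-0.28	0.09	3.47	-9.81	-8.2	-22.2	-1.30	86.44	0.12	-0.10	-13.48	4.5
GC	40.00	0.0	0.3	0.00	-0.38	3.81	-14.59	-9.8	-24.4	-2.24	136.12	0.26	0.05	-11.08	4.0
GG	33.67	0.1	3.6	-0.05	-0.22	3.47	-8.26	-8.0	-19.9	-1.84	85.97	0.49	-0.03	-8.11	6.1
GT	34.40	0.1	0.7	-0.13	-0.58	3.41	-10.51	-8.4	-22.4	-1.44	97.73	0.14	-0.20	-13.10	2.3
TA	36.00	0.0	3.3	0.00	0.05	3.21	-3.82	-7.2	-21.3	-0.58	36.73	0.02	0.18	-11.85	6.3
TC	36.90	1.5	1.9	0.28	0.09	3.47	-9.81	-8.2	-22.2	-1.30	86.44	0.12	-0.10	-13.48	4.5
TG	34.50	-0.5	4.7	-0.09	0.53	3.23	-6.57	-8.5	-22.7	-1.45	54.71	0.21	-0.01	-9.45	9.8
TT	35.62	1.4	0.7	0.03	-0.08	3.16	-5.37	-7.9	-22.2	-1.00	54.50	0.04	-0.27	-18.66	2.9
"""

# The 11 structural/thermodynamic scales kept for the trinucleotide table.
_TRINUC_PROPERTIES = (
    "Twist", "Tilt", "Roll", "Shift", "Slide", "Rise",
    "Stacking_energy", "Enthalpy", "Entropy", "Free_energy", "Bendability",
)


def kmer_tokens(k: int) -> tuple[str, ...]:
    """All k-mers over A<C<G<T<N in lexicographic (codebook) order."""
    tokens = [""]
    for _ in range(k):
        tokens = [t + s for t in tokens for s in _SYMBOLS]
    return tuple(tokens)


@dataclass(frozen=True)
class PropertyTable:
    """Complete k-mer x property value matrix (k in {2, 3})."""

    kmer_size: int
    tokens: tuple[str, ...]
    properties: tuple[str, ...]
    values: np.ndarray  # shape (len(tokens), len(properties))

    def __post_init__(self) -> None:
        if self.kmer_size not in (2, 3):
            raise ValueError(f"kmer_size must be 2 or 3, got {self.kmer_size}")
        expected = kmer_tokens(self.kmer_size)
        if tuple(self.tokens) != expected:
            missing = set(expected) - set(self.tokens)
            extra = set(self.tokens) - set(expected)
            raise ValueError(
                f"token set must be exactly the {len(expected)} "
                f"{self.kmer_size}-mers in codebook order "
                f"(missing: {sorted(missing)[:5]}, extra: {sorted(extra)[:5]})"
            )
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.tokens), len(self.properties)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"({len(self.tokens)}, {len(self.properties)})"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("property table contains non-finite cells")
        object.__setattr__(self, "values", vals)

    @property
    def n_properties(self) -> int:
        return len(self.properties)

    def row(self, token: str) -> np.ndarray:
        try:
            i = self.tokens.index(token)
        except ValueError:
            raise KeyError(f"token {token!r} not in property table") from None
        return self.values[i]

    def scaled(self, factor: float) -> "PropertyTable":
        return PropertyTable(self.kmer_size, self.tokens, self.properties,
                             self.values * factor)


def _parse_tsv(text: str, kmer_size: int) -> PropertyTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "token":
        raise ValueError("property TSV must start with a 'token' column")
    properties = tuple(header[1:])
    if not properties:
        raise ValueError("property TSV has no property columns")
    given: dict[str, list[float]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"malformed property TSV row: {ln!r}")
        given[parts[0]] = [float(v) for v in parts[1:]]
    tokens = kmer_tokens(kmer_size)
    values = np.zeros((len(tokens), len(properties)))
    covered = 0
    for i, tok in enumerate(tokens):
        if tok in given:
            values[i] = given[tok]
            covered += 1
        elif "N" not in tok:
            raise ValueError(f"property TSV missing standard token {tok!r}")
        # N-containing tokens absent from the TSV default to all-zero rows.
    extra = set(given) - set(tokens)
    if extra:
        raise ValueError(f"property TSV has unexpected tokens: {sorted(extra)[:5]}")
    return PropertyTable(kmer_size, tokens, properties, values)


def read_property_table(path_or_text, kmer_size: int) -> PropertyTable:
    """Load a property table from a TSV file path or file-like object.

    Schema: header ``token<TAB>prop1<TAB>...``, one row per k-mer token.
    Rows for N-containing tokens may be omitted; they default to zero.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    return _parse_tsv(text, kmer_size)


def write_property_table(table: PropertyTable, path) -> None:
    """Write a property table in the TSV interchange schema."""
    with open(path, "w") as fh:
        fh.write("token\t" + "\t".join(table.properties) + "\n")
        for tok, row in zip(table.tokens, table.values):
            fh.write(tok + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def default_dinucleotide_table() -> PropertyTable:
    """The bundled 25-dinucleotide x 15-property table (see module docs)."""
    return _parse_tsv(_DINUC_TSV, kmer_size=2)


def default_trinucleotide_table() -> PropertyTable:
    """The bundled 125-trinucleotide x 11-property table.

    Each standard trinucleotide XYZ takes the mean of its two constituent
    dinucleotide steps (XY, YZ) on the 11 structural scales; N-containing
    trinucleotides are all-zero.
    """
    din = _parse_tsv(_DINUC_TSV, kmer_size=2)
    keep = [din.properties.index(p) for p in _TRINUC_PROPERTIES]
    tokens = kmer_tokens(3)
    values = np.zeros((len(tokens), len(_TRINUC_PROPERTIES)))
    for i, tok in enumerate(tokens):
        if "N" in tok:
            continue
        a = din.row(tok[:2])[keep]
        b = din.row(tok[1:])[keep]
        values[i] = (a + b) / 2.0
    return PropertyTable(3, tokens, _TRINUC_PROPERTIES, values)
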