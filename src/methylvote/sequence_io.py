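"""Sequence I/O: FASTA parsing, normalization, cleaning, and splitting.

The unit of prediction is a fixed-length DNA window (41 nt by default)
centered on a candidate adenine. This module reads such windows from
FASTA, normalizes them onto the {A, C, G, T, N} alphabet, applies the
standard dataset-cleaning rules (length filter, exact deduplication,
positive/negative overlap removal) and performs the stratified random
train/test split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
DEFAULT_WINDOW_LENGTH = 41

# Any character outside the four standard bases (after uppercasing) maps
# to N, the unidentified nucleotide: U, IUPAC ambiguity codes, gaps, ...
_NORMALIZE = {c: (c if c in "ACGT" else "N") for c in map(chr, range(128))}


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map every non-ACGT character to ``N``.

    A pure character map: applying it twice equals applying it once.
    """
    return "".join(_NORMALIZE.get(c, "N") for c in seq.upper())


@dataclass(frozen=True)
class DnaWindow:
    """A fixed-length DNA string over {A,C,G,T,N} with an identifier.

    Model-ready windows have odd length (default 41) and an ``A`` at the
    central position; arbitrary windows may violate that until cleaned.
    """

    sequence: str
    id: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"window {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}; normalize first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def center(self) -> str:
        """The central character (requires odd length)."""
        if self.length % 2 == 0:
            raise ValueError(f"window {self.id!r} has even length {self.length}")
        return self.sequence[self.length // 2]

    def is_model_ready(self, length: int = DEFAULT_WINDOW_LENGTH) -> bool:
        return self.length == length and length % 2 == 1 and self.center == "A"


@dataclass
class LabeledDataset:
    """Parallel windows and binary labels (1 = 6mA-positive at center)."""

    windows: list[DnaWindow]
    labels: list[int]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.labels):
            raise ValueError(
                f"{len(self.windows)} windows but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.windows)

    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def subset(self, indices, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            windows=[self.windows[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            name=name if name is not None else self.name,
        )

    def concat(self, other: "LabeledDataset", name: str = "") -> "LabeledDataset":
        return LabeledDataset(
            windows=self.windows + other.windows,
            labels=self.labels + other.labels,
            name=name or self.name,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the random train/test partition (default 80/20)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0,1), got {self.train_fraction}"
            )


@dataclass
class CleaningReport:
    """Per-label counts removed at each cleaning stage."""

    positive: dict[str, int] = field(default_factory=dict)
    negative: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"positive": self.positive, "negative": self.negative},
                          indent=2)


def read_fasta(path, label: int) -> LabeledDataset:
    """Read a FASTA file into a :class:`LabeledDataset` with one label.

    Sequences are uppercased and any character outside {A,C,G,T} is
    mapped to ``N``; the number of replaced characters is logged.

    Raises
    ------
    ValueError
        If the file contains no records, or ``label`` is not 0/1.
    OSError
        If the file cannot be read.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    windows: list[DnaWindow] = []
    n_replaced = 0
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        norm = normalize_sequence(raw)
        n_replaced += sum(1 for a, b in zip(raw.upper(), norm) if a != b)
        windows.append(DnaWindow(sequence=norm, id=record.id))
    if not windows:
        raise ValueError(f"no records found in FASTA file {path}")
    if n_replaced:
        logger.warning("%d non-ACGT characters mapped to N while reading %s",
                       n_replaced, path)
    return LabeledDataset(windows=windows, labels=[label] * len(windows),
                          name=str(path))


def write_fasta(data: LabeledDataset, path) -> None:
    """Write one unwrapped FASTA record per window, ids preserved."""
    if len(data) == 0:
        raise ValueError("refusing to write an empty dataset")
    records = [
        SeqRecord(Seq(w.sequence), id=w.id, description="")
        for w in data.windows
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def _clean_one(data: LabeledDataset, max_len: int) -> tuple[LabeledDataset, dict]:
    counts = {"input": len(data)}
    kept = [i for i, w in enumerate(data.windows) if w.length == max_len]
    counts["removed_length"] = len(data) - len(kept)
    seen: set[str] = set()
    deduped: list[int] = []
    for i in kept:
        s = data.windows[i].sequence
        if s not in seen:
            seen.add(s)
            deduped.append(i)
    counts["removed_duplicate"] = len(kept) - len(deduped)
    return data.subset(deduped), counts


def clean_datasets(
    positives: LabeledDataset,
    negatives: LabeledDataset,
    max_len: int = DEFAULT_WINDOW_LENGTH,
) -> tuple[LabeledDataset, LabeledDataset, CleaningReport]:
    """Apply the three cleaning rules to a positive/negative dataset pair.

    In order: (1) remove windows whose length differs from ``max_len``
    (downstream encoders assume fixed length, so shorter windows are
    removed alongside longer ones); (2) within each label, drop exact
    duplicate sequences keeping the first occurrence; (3) remove any
    sequence present in both cleaned sets from BOTH sets.

    Windows without a central ``A`` are kept with a warning here; the
    central-A requirement becomes a hard error at prediction time.

    Returns the cleaned pair and a :class:`CleaningReport`; raises
    ``ValueError`` if either side ends up empty.
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both input datasets must be non-empty")

    pos, pos_counts = _clean_one(positives, max_len)
    neg, neg_counts = _clean_one(negatives, max_len)

    overlap = set(pos.sequences()) & set(neg.sequences())
    pos_keep = [i for i, w in enumerate(pos.windows) if w.sequence not in overlap]
    neg_keep = [i for i, w in enumerate(neg.windows) if w.sequence not in overlap]
    pos_counts["removed_overlap"] = len(pos) - len(pos_keep)
    neg_counts["removed_overlap"] = len(neg) - len(neg_keep)
    pos = pos.subset(pos_keep)
    neg = neg.subset(neg_keep)
    pos_counts["output"] = len(pos)
    neg_counts["output"] = len(neg)

    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("cleaning left an empty dataset "
                         f"(positives: {len(pos)}, negatives: {len(neg)})")

    off_center = sum(1 for w in pos.windows + neg.windows
                     if not w.is_model_ready(max_len))
    if off_center and max_len % 2 == 1:
        logger.warning("%d cleaned windows lack a central 'A'; they will be "
                       "rejected at prediction time", off_center)
    return pos, neg, CleaningReport(positive=pos_counts, negative=neg_counts)


def split_dataset(
    data: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Randomly partition ``data`` into train and test per ``spec``.

    Deterministic for a given seed; with ``stratified=True`` each label's
    train share is within one sample of ``train_fraction``.
    """
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    labels = data.label_array()
    if spec.stratified and min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("stratified split needs >= 2 samples of each label")
    n_train = round(n * spec.train_fraction)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={spec.train_fraction} yields an empty partition "
            f"for n={n}"
        )
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        shuffle=True,
        stratify=labels if spec.stratified else None,
    )
    return (
        data.subset(sorted(train_idx), name=f"{data.name}/train"),
        data.subset(sorted(test_idx), name=f"{data.name}/test"),
    )
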