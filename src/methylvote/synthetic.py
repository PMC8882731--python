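"""Synthetic 41-nt window generator with position-specific enrichment.

Real 6mA-positive windows show nucleotide enrichment at specific
positions flanking the methylated adenine (visible in two-sample
sequence logos of plant genomes). This generator emulates that
structure: every window is a fixed-length string with a forced central
"A"; positive windows additionally force an enriched nucleotide at each
listed flank position with probability equal to the enrichment strength,
while negative windows are i.i.d. background throughout.

The default profile plants the enrichment positions observed in plant
6mA logos: A at -6, -4, -3, +4, +7, +8, +10, +11, +12; C at -7, -2, +2,
+6, +9; G at -8, -1, +2, +3, +5, +8; T at +3 (21 position/nucleotide
pairs, positions relative to the central adenine at 0). Strengths are a
free parameter — the logos are qualitative — with default 0.5.

What this emulates and what it does not: the generator reproduces
per-position compositional bias only. Real negatives come from
chromosomes without detected 6mA and carry genome-scale composition, CG
skew and chromosomal context that i.i.d. background does not; a model
that separates these synthetic classes has learned positional
composition, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from methylvote.sequence_io import DnaWindow, LabeledDataset

_BASES = "ACGT"

#: (position relative to center, enriched nucleotide) pairs of the
#: default profile; 9 A + 5 C + 6 G + 1 T = 21 entries.
DEFAULT_ENRICHED_POSITIONS: tuple[tuple[int, str], ...] = (
    (-6, "A"), (-4, "A"), (-3, "A"), (4, "A"), (7, "A"),
    (8, "A"), (10, "A"), (11, "A"), (12, "A"),
    (-7, "C"), (-2, "C"), (2, "C"), (6, "C"), (9, "C"),
    (-8, "G"), (-1, "G"), (2, "G"), (3, "G"), (5, "G"), (8, "G"),
    (3, "T"),
)


@dataclass(frozen=True)
class EnrichmentProfile:
    """Positional enrichment rules planted into positive windows.

    ``enriched`` lists (position, nucleotide, strength) triples with
    positions relative to the central adenine (position 0 excluded —
    the center is always "A"). At each listed position a positive window
    carries the enriched nucleotide with probability ``strength``,
    otherwise a draw from ``background``. ``n_rate`` optionally masks
    flank positions to N, emulating unidentified nucleotides.
    """

    window_length: int = 41
    enriched: tuple[tuple[int, str, float], ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 3")
        half = (self.window_length - 1) // 2
        for pos, nuc, s in self.enriched:
            if pos == 0 or not -half <= pos <= half:
                raise ValueError(
                    f"enriched position {pos} outside [-{half}, {half}] \\ {{0}}"
                )
            if nuc not in _BASES:
                raise ValueError(f"enriched nucleotide must be one of ACGT, got {nuc!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"enrichment strength {s} outside [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 non-negative probabilities summing to 1")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must lie in [0, 1]")

    @property
    def center_index(self) -> int:
        return (self.window_length - 1) // 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Sizes, profile and seed of one synthetic dataset."""

    n_pos: int
    n_neg: int
    profile: EnrichmentProfile = field(default_factory=EnrichmentProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")


def default_profile(strength: float = 0.5, window_length: int = 41,
                    n_rate: float = 0.0) -> EnrichmentProfile:
    """The default plant-6mA-logo profile at a common enrichment strength."""
    return EnrichmentProfile(
        window_length=window_length,
        enriched=tuple((p, n, strength) for p, n in DEFAULT_ENRICHED_POSITIONS),
        n_rate=n_rate,
    )


def _draw_background(rng: np.random.Generator, n: int, length: int,
                     background) -> np.ndarray:
    codes = rng.choice(4, size=(n, length), p=np.asarray(background, dtype=float))
    return codes


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate ``n_pos`` positive + ``n_neg`` negative labeled windows.

    Positives come first (ids ``pos_<i>``), then negatives (``neg_<i>``).
    Deterministic for a given spec. Duplicate sequences are possible by
    chance and are left to the standard cleaning step, mirroring the real
    pipeline's flow.
    """
    profile = spec.profile
    rng = np.random.default_rng(spec.seed)
    L, c = profile.window_length, profile.center_index
    lookup = np.array(list(_BASES + "N"))

    def build(n: int, positive: bool) -> list[str]:
        codes = _draw_background(rng, n, L, profile.background)
        if positive:
            for pos, nuc, s in profile.enriched:
                forced = rng.random(n) < s
                codes[forced, c + pos] = _BASES.index(nuc)
        if profile.n_rate > 0:
            mask = rng.random((n, L)) < profile.n_rate
            mask[:, c] = False  # the center stays an identified adenine
            codes[mask] = 4
        codes[:, c] = 0  # central A
        return ["".join(row) for row in lookup[codes]]

    pos_seqs = build(spec.n_pos, positive=True)
    neg_seqs = build(spec.n_neg, positive=False)
    windows = (
        [DnaWindow(s, f"pos_{i}") for i, s in enumerate(pos_seqs)]
        + [DnaWindow(s, f"neg_{i}") for i, s in enumerate(neg_seqs)]
    )
    labels = [1] * spec.n_pos + [0] * spec.n_neg
    return LabeledDataset(windows, labels,
                          name=f"synthetic(seed={spec.seed})")


def generate_pair(spec: SyntheticSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Like :func:`generate` but returning (positives, negatives) separately."""
    data = generate(spec)
    pos_idx = [i for i, l in enumerate(data.labels) if l == 1]
    neg_idx = [i for i, l in enumerate(data.labels) if l == 0]
    return (data.subset(pos_idx, name=data.name + "/pos"),
            data.subset(neg_idx, name=data.name + "/neg"))
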