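"""Canonical frequency bands and the coupling-mode label algebra.

The framework analyses eight conventional neurophysiological bands
(delta through high gamma) and labels every possible interaction type
between a pair of regions with a single integer:

* ``0``      — no statistically significant coupling,
* ``1..8``   — within-frequency phase coupling (delta-delta ... gamma2-gamma2),
* ``9..36``  — the 28 phase-to-amplitude cross-frequency pairs, enumerated
  lexicographically with the low (modulating) band major:
  9 = delta-theta, 10 = delta-alpha1, ..., 15 = delta-gamma2,
  16 = theta-alpha1, ..., 36 = gamma1-gamma2.

The delta band defaults to 1-4 Hz (matching a 1-Hz acquisition high-pass);
a 0.5-Hz lower edge can be configured via a custom band table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "N_BANDS",
    "N_MODES",
    "INTRA_MODES",
    "CROSS_MODES",
    "CROSS_PAIRS",
    "mode_label",
    "mode_bands",
    "mode_name",
    "is_cross",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges: {self.f_lo}-{self.f_hi} Hz")

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.0),
    BandSpec("alpha2", 10.0, 13.0),
    BandSpec("beta1", 13.0, 20.0),
    BandSpec("beta2", 20.0, 30.0),
    BandSpec("gamma1", 30.0, 45.0),
    BandSpec("gamma2", 55.0, 90.0),
)

N_BANDS = len(CANONICAL_BANDS)
INTRA_MODES = N_BANDS                      # 8 within-frequency modes
#: ordered (low, high) band-index pairs for cross-frequency coupling
CROSS_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(N_BANDS), 2))
CROSS_MODES = len(CROSS_PAIRS)             # C(8,2) = 28
N_MODES = INTRA_MODES + CROSS_MODES        # 36 nonzero labels


def mode_label(low: int, high: int) -> int:
    """Integer label of the coupling mode between band indices ``low``/``high``.

    ``low == high`` gives the within-frequency label (1..8); ``low < high``
    gives the cross-frequency label (9..36).
    """
    if low == high:
        return low + 1
    if not 0 <= low < high < N_BANDS:
        raise ValueError(f"invalid band pair ({low}, {high})")
    return INTRA_MODES + 1 + CROSS_PAIRS.index((low, high))


def mode_bands(label: int) -> tuple[int, int]:
    """Inverse of :func:`mode_label`: (low, high) band indices of a nonzero label."""
    if not 1 <= label <= N_MODES:
        raise ValueError(f"mode label {label} outside 1..{N_MODES}")
    if label <= INTRA_MODES:
        return label - 1, label - 1
    return CROSS_PAIRS[label - INTRA_MODES - 1]


def is_cross(label: int) -> bool:
    return label > INTRA_MODES


def mode_name(label: int, bands: tuple[BandSpec, ...] = CANONICAL_BANDS) -> str:
    if label == 0:
        return "none"
    lo, hi = mode_bands(label)
    return f"{bands[lo].name}-{bands[hi].name}"
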