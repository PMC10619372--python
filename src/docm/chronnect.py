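"""Chronnectomic descriptors of dominant-coupling-mode dynamics.

* **Comodulogram** — an 8x8 probability table of an edge's dominant modes
  over time: the diagonal holds within-frequency modes, the off-diagonal
  cell (low, high) the corresponding cross-frequency mode.  Probabilities
  are taken over the windows in which *some* coupling was significant, so
  the table sums to 1 whenever the edge was ever coupled.
* **Flexibility index (FI)** — the fraction of consecutive-window
  transitions at which an edge's dominant mode changes; 0 for a perfectly
  stable edge, 1 for an edge that never repeats a mode twice in a row.
  The global FI averages over all region pairs.
* **Window-parameter optimisation** — a grid search over sliding-window
  width and step, scored by the between-session repeatability (Pearson r,
  with ICC(2,1) reported alongside) of the pairwise FI across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import INTRA_MODES, N_BANDS, N_MODES, mode_bands
from .coupling import WindowSpec, compute_dfcg
from .docm_select import SurrogateConfig, build_idfcg

__all__ = [
    "comodulogram",
    "flexibility_index",
    "FlexibilityMatrix",
    "icc_2_1",
    "optimize_window_params",
]


def comodulogram(seq: np.ndarray) -> np.ndarray:
    """8x8 dominant-mode probability table for one edge's label sequence.

    Rows index the modulating (low) band, columns the modulated (high)
    band; within-frequency modes sit on the diagonal.  Zero labels (no
    coupling) are excluded from the normalisation; an all-zero sequence
    yields the all-zero table.
    """
    seq = np.asarray(seq)
    if seq.min(initial=0) < 0 or seq.max(initial=0) > N_MODES:
        raise ValueError(f"labels must lie in 0..{N_MODES}")
    out = np.zeros((N_BANDS, N_BANDS))
    nz = seq[seq > 0]
    if nz.size == 0:
        return out
    counts = np.bincount(nz, minlength=N_MODES + 1)
    for label in range(1, N_MODES + 1):
        if counts[label]:
            lo, hi = mode_bands(label)
            out[lo, hi] += counts[label]
    return out / nz.size


@dataclass
class FlexibilityMatrix:
    """Pairwise FI values and their global mean over the upper triangle."""

    fi: np.ndarray         # (R, R), symmetric, zero diagonal
    fi_global: float


def flexibility_index(labels: np.ndarray) -> FlexibilityMatrix:
    """FI(i,j) = (1/(T-1)) * #{t : label_t(i,j) != label_{t+1}(i,j)}.

    ``labels`` is (windows, R, R); at least two windows are required.
    The global index is the mean over the R(R-1)/2 distinct pairs.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None, None]
    T = labels.shape[0]
    if T < 2:
        raise ValueError("need at least two windows")
    changes = (labels[1:] != labels[:-1]).sum(axis=0)
    fi = changes / (T - 1)
    if fi.shape[0] == 1:
        return FlexibilityMatrix(fi, float(fi[0, 0]))
    iu, ju = np.triu_indices(fi.shape[0], 1)
    np.fill_diagonal(fi, 0.0)
    return FlexibilityMatrix(fi, float(fi[iu, ju].mean()))


def icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1) — two-way random effects, absolute agreement, single rater."""
    data = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=1)
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    ss_err = (np.sum((data - grand) ** 2)
              - np.sum((data.mean(axis=1) - grand) ** 2) * k
              - np.sum((data.mean(axis=0) - grand) ** 2) * n)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        return 1.0 if ms_rows == ms_err else 0.0
    return float((ms_rows - ms_err) / denom)


def _pairwise_fi(session: np.ndarray, rate: float, spec: WindowSpec,
                 cfg: SurrogateConfig) -> np.ndarray:
    dfcg = compute_dfcg(session, rate, spec=spec)
    idfcg = build_idfcg(dfcg, cfg)
    fm = flexibility_index(idfcg.labels)
    iu, ju = np.triu_indices(fm.fi.shape[0], 1)
    return fm.fi[iu, ju]


def optimize_window_params(sessions1: list[np.ndarray], sessions2: list[np.ndarray],
                           rate: float, widths: list[float], steps: list[float],
                           cfg: SurrogateConfig = SurrogateConfig()):
    """Grid-search the sliding-window geometry by FI repeatability.

    For every (width, step) the full dominant-mode pipeline is run on both
    sessions of every subject; pairwise FI values are pooled across
    subjects and the Pearson correlation between sessions is the
    repeatability score (ICC(2,1) is reported alongside).  Returns
    ``(best_width, best_step, surface)`` where ``surface`` is a
    (len(widths), len(steps)) array of Pearson r.
    """
    if not widths or not steps:
        raise ValueError("empty parameter grid")
    surface = np.full((len(widths), len(steps)), np.nan)
    icc_surface = np.full_like(surface, np.nan)
    for a, width in enumerate(widths):
        for b, step in enumerate(steps):
            spec = WindowSpec(width, step)
            fi1, fi2 = [], []
            for s1, s2 in zip(sessions1, sessions2):
                if width * rate > s1.shape[1]:
                    raise ValueError(f"window width {width}s exceeds recording")
                fi1.append(_pairwise_fi(s1, rate, spec, cfg))
                fi2.append(_pairwise_fi(s2, rate, spec, cfg))
            v1, v2 = np.concatenate(fi1), np.concatenate(fi2)
            if v1.std() == 0 or v2.std() == 0:
                surface[a, b] = 1.0 if np.allclose(v1, v2) else 0.0
            else:
                surface[a, b] = np.corrcoef(v1, v2)[0, 1]
            icc_surface[a, b] = icc_2_1(v1, v2)
    best = np.unravel_index(np.nanargmax(surface), surface.shape)
    return widths[best[0]], steps[best[1]], surface, icc_surface
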