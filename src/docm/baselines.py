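"""Reference fingerprinting baselines.

These establish what simpler subject descriptors achieve on the same data:
per-ROI Welch spectra, static (whole-recording) connectomes, the raw
strength dynamics of the integrated graph, and random edge subsets of the
dHMM pipeline.  The scientific claim being checked is an ordering — the
dominant-coupling-mode dHMM identification should not be beaten by any of
them — not the baselines' absolute numbers.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .bands import CANONICAL_BANDS, BandSpec
from .fingerprint import identification_accuracy, similarity_matrix

__all__ = [
    "psd_profile",
    "correlation_match",
    "static_fc_profile",
    "dynamic_strength_match",
    "random_subset_control",
]


def psd_profile(rois: np.ndarray, rate: float, band: BandSpec | None = None,
                f_max: float = 90.0, resolution: float = 0.5) -> np.ndarray:
    """Concatenated per-ROI Welch PSD feature vector.

    2-s Hann segments with 50% overlap and constant detrending give a
    ``resolution`` (default 0.5 Hz) grid; the profile is restricted to
    ``band`` when given, otherwise to [0, f_max] (181 bins at defaults).
    """
    rois = np.atleast_2d(np.asarray(rois, dtype=float))
    if rate < 2 * f_max:
        raise ValueError(f"rate {rate} Hz cannot resolve {f_max} Hz")
    nperseg = int(round(rate / resolution))
    if rois.shape[1] < nperseg:
        raise ValueError("recording shorter than one PSD segment")
    f, pxx = sp_signal.welch(rois, fs=rate, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2, detrend="constant", axis=-1)
    if band is not None:
        sel = (f >= band.f_lo) & (f <= band.f_hi)
    else:
        sel = f <= f_max
    return pxx[:, sel].ravel()


def correlation_match(profiles_s1: np.ndarray, profiles_s2: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Identify by maximum absolute Pearson correlation between profiles.

    Returns (accuracy, predicted assignment); subject m of session 1 is
    matched to the session-2 profile with the largest |r|.
    """
    a = np.atleast_2d(np.asarray(profiles_s1, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_s2, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimension mismatch")
    if np.any(a.std(axis=1) == 0) or np.any(b.std(axis=1) == 0):
        raise ValueError("zero-variance profile")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    corr = np.abs(az @ bz.T) / a.shape[1]
    assignment = np.argmax(corr, axis=1)
    accuracy = float(np.mean(assignment == np.arange(len(a))))
    return accuracy, assignment


def static_fc_profile(rois: np.ndarray, rate: float,
                      band: BandSpec = CANONICAL_BANDS[2]) -> np.ndarray:
    """Whole-recording iPLV connectome, upper triangle vectorised row-major.

    Each ROI is filtered once; the all-pairs mean phase-difference phasor
    is then a single Gram product of the unit-phasor matrix.
    """
    from scipy import signal as sp

    from .preprocess import bandpass

    rois = np.asarray(rois, dtype=float)
    R = rois.shape[0]
    if R < 2:
        raise ValueError("need at least two ROIs")
    z = np.exp(1j * np.angle(sp.hilbert(bandpass(rois, band, rate), axis=-1)))
    gram = (z @ z.conj().T) / rois.shape[1]
    iu, ju = np.triu_indices(R, 1)
    return np.abs(gram.imag)[iu, ju]


def dynamic_strength_match(strengths_s1: list[np.ndarray],
                           strengths_s2: list[np.ndarray]) -> float:
    """Identify by minimal Euclidean distance between the (windows x pairs)
    dominant-coupling strength matrices of the two sessions."""
    shapes1 = {np.asarray(s).shape for s in strengths_s1}
    shapes2 = {np.asarray(s).shape for s in strengths_s2}
    if len(shapes1 | shapes2) != 1 or len(strengths_s1) != len(strengths_s2):
        raise ValueError("shape mismatch between sessions")
    a = np.stack([np.asarray(s, float).ravel() for s in strengths_s1])
    b = np.stack([np.asarray(s, float).ravel() for s in strengths_s2])
    d2 = (a ** 2).sum(1)[:, None] + (b ** 2).sum(1)[None, :] - 2 * a @ b.T
    pred = np.argmin(d2, axis=1)
    return float(np.mean(pred == np.arange(len(a))))


def random_subset_control(L: np.ndarray, k: int = 76, n_draws: int = 1000,
                          seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Identification accuracy of random k-edge subsets of the dHMM pipeline.

    Each draw samples ``k`` edges without replacement from the edge
    universe of the cached log-likelihood tensor ``L[e, k, m]`` and scores
    the summed-log-likelihood identification.  Returns (mean, sd, draws).
    """
    E = L.shape[0]
    if k > E:
        raise ValueError("subset larger than the edge universe")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_draws)
    for d in range(n_draws):
        edges = rng.choice(E, size=k, replace=False)
        accs[d] = identification_accuracy(similarity_matrix(L, edges))
    return float(accs.mean()), float(accs.std()), accs
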