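"""Synthetic multichannel cohorts with planted, time-varying coupling.

Real source-space MEG is not redistributable, so every downstream stage is
exercised on generated data whose ground truth is known.  The generative
ingredients:

* ROI "oscillations" are band-passed Gaussian noise (not sinusoids), so
  instantaneous phases are non-degenerate and surrogate nulls behave like
  real narrowband activity; every ROI carries all eight canonical bands
  plus 1/f-shaped background noise.
* A :class:`CouplingPlan` drives a set of disjoint region pairs.  Each
  driven pair carries a small menu of coupling modes and a Markov chain
  (piecewise-constant at a configurable segment resolution) that switches
  the active mode over time.  Within-frequency modes are planted as
  lagged phase coupling; cross-frequency modes as phase-modulated
  high-band carriers.
* A subject's identity *is* the plan — mode menus and switching dynamics.
  The two sessions of a subject are independent realisations (fresh noise,
  fresh state path) of the same plan, mirroring the premise that coupling
  dynamics are stable within a person.

Ground truth (the active mode per driven pair per sample) is stored next
to, but separate from, the pipeline-visible signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import CANONICAL_BANDS, BandSpec, mode_bands, mode_label
from .preprocess import bandpass

__all__ = [
    "gen_oscillatory_source",
    "plant_phase_coupling",
    "plant_pac",
    "pink_noise",
    "PairPlan",
    "CouplingPlan",
    "random_plan",
    "SubjectRecord",
    "SyntheticCohort",
    "gen_subject",
    "gen_cohort",
    "gen_two_cohorts",
    "gen_voxel_rois",
    "default_mode_universe",
]


# ---------------------------------------------------------------------------
# Primitive sources
# ---------------------------------------------------------------------------

def gen_oscillatory_source(band: BandSpec, duration: float, rate: float,
                           seed) -> np.ndarray:
    """Unit-variance band-limited Gaussian-noise oscillation."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 2 * band.f_hi:
        raise ValueError(f"rate {rate} Hz cannot carry {band.f_hi} Hz")
    if duration * band.f_lo < 10:
        raise ValueError("need at least 10 cycles of the band's lower edge")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = bandpass(rng.standard_normal(n), band, rate)
    return x / x.std()


def pink_noise(n: int, rate: float, seed, f_min: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise (flat below ``f_min``)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = 1.0 / np.sqrt(np.maximum(f, f_min))
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / x.std()


def plant_phase_coupling(x: np.ndarray, band: BandSpec, lag: float,
                         strength: float, rate: float, seed) -> np.ndarray:
    """A series whose band-limited phase tracks ``x``'s phase + ``lag``.

    ``strength`` in [0, 1] mixes the exactly lagged copy with an
    independent band-limited source; strength 1 with lag pi/2 drives the
    iPLV of the pair to 1, while strength 0 reproduces the independent
    null.  A zero-lag design at full strength is flagged (imaginary phase
    locking cannot see it) but not refused.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    if lag == 0.0 and strength == 1.0:
        warnings.warn("zero-lag coupling at full strength is invisible to iPLV")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    analytic = signal.hilbert(bandpass(np.asarray(x, float), band, rate))
    lagged = np.real(analytic * np.exp(1j * lag))
    lagged /= lagged.std()
    noise = gen_oscillatory_source(band, len(x) / rate, rate, rng)
    y = strength * lagged + (1.0 - strength) * noise
    return y / y.std()


def plant_pac(x: np.ndarray, f_low: BandSpec, f_high: BandSpec, depth: float,
              rate: float, seed, lag: float = np.pi / 2,
              noise_level: float = 0.1) -> np.ndarray:
    """A high-band carrier whose envelope is modulated by ``x``'s low-band
    phase: ``carrier * (1 + depth cos(phi_low - lag))`` plus background.

    ``lag`` defaults to a quarter cycle because the phase-locking PAC
    estimator reads the *imaginary* part of the phase alignment between
    driver phase and envelope phase — a zero-lag modulation is invisible
    to it, exactly as zero-lag phase coupling is to iPLV.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    if f_low.f_hi >= f_high.f_lo:
        raise ValueError("low band must lie strictly below the high band")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    phi = np.angle(signal.hilbert(bandpass(x, f_low, rate)))
    # constant-modulus carrier (random high-band phase, unit envelope): the
    # planted modulation then fully determines the envelope instead of
    # riding on the carrier's own stochastic amplitude fluctuations
    raw = signal.hilbert(gen_oscillatory_source(f_high, len(x) / rate, rate, rng))
    carrier = np.cos(np.angle(raw))
    y = carrier * (1.0 + depth * np.cos(phi - lag))
    if noise_level > 0:
        y = y + noise_level * rng.standard_normal(len(x))
    return y / y.std()


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairPlan:
    """Coupling schedule for one driven region pair (i -> j).

    ``modes`` are the coupling-mode labels the pair alternates between;
    ``transmat`` is the Markov transition matrix over those modes, applied
    at ``segment`` resolution; ``strength`` scales phase coupling and
    ``depth`` the PAC modulation.
    """

    i: int
    j: int
    modes: tuple[int, ...]
    transmat: np.ndarray
    strength: float = 0.9
    depth: float = 0.9
    lag: float = np.pi / 2

    def __post_init__(self):
        tm = np.asarray(self.transmat, dtype=float)
        if tm.shape != (len(self.modes), len(self.modes)):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("transition-matrix rows must sum to 1")
        for m in self.modes:
            if not 0 <= m <= 36:
                raise ValueError("mode labels must lie in 0..36")


@dataclass
class CouplingPlan:
    """Subject-level generative plan: the identity-carrying structure."""

    n_rois: int
    pairs: list[PairPlan] = field(default_factory=list)
    segment_s: float = 0.5

    def __post_init__(self):
        for p in self.pairs:
            if p.i >= self.n_rois or p.j >= self.n_rois:
                raise ValueError(f"pair ({p.i},{p.j}) outside {self.n_rois} ROIs")


def default_mode_universe() -> list[int]:
    """Default plantable modes: the couplings that are *recoverable* at the
    default 1-s analysis window.

    Window-level detection hinges on the phase-estimation degrees of
    freedom a band offers within one window (roughly bandwidth x width):
    narrow low-frequency bands (delta through alpha2, 2-4 Hz wide) yield a
    surrogate null whose extreme tail overlaps even perfect coupling, and a
    phase-to-amplitude modulation is carried intact only when the modulated
    band is wider than twice the modulating frequency.  The default
    universe therefore plants within-frequency coupling in beta2/gamma1/
    gamma2 and phase-to-amplitude coupling of beta1/beta2 onto gamma2; all
    36 modes are still estimated and statistically filtered downstream,
    and callers may plant any mode set explicitly.
    """
    return [mode_label(5, 5), mode_label(6, 6), mode_label(7, 7),
            mode_label(4, 7), mode_label(5, 7)]


def random_plan(n_rois: int, seed, n_driven: int | None = None,
                mode_universe: list[int] | None = None,
                strength: float = 0.9, depth: float = 0.9,
                self_prob_range: tuple[float, float] = (0.75, 0.92),
                segment_s: float = 0.5) -> CouplingPlan:
    """Draw a subject-specific plan: disjoint driven pairs (0-1, 2-3, ...),
    each with a two-mode menu and subject-specific switching rates."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_driven is None:
        n_driven = n_rois // 2
    if 2 * n_driven > n_rois:
        raise ValueError("not enough ROIs for disjoint driven pairs")
    universe = list(mode_universe) if mode_universe else default_mode_universe()
    pairs = []
    for k in range(n_driven):
        modes = tuple(int(m) for m in rng.choice(universe, size=2, replace=False))
        p_stay = rng.uniform(*self_prob_range, size=2)
        tm = np.array([[p_stay[0], 1 - p_stay[0]],
                       [1 - p_stay[1], p_stay[1]]])
        pairs.append(PairPlan(2 * k, 2 * k + 1, modes, tm,
                              strength=strength, depth=depth))
    return CouplingPlan(n_rois, pairs, segment_s)


# ---------------------------------------------------------------------------
# Subject and cohort synthesis
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    sessions: list[np.ndarray]          # each (n_rois, n_samples)
    rate: float
    plan: CouplingPlan
    truth: list[np.ndarray]             # per session: (n_driven, n_samples) labels


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    rate: float
    n_rois: int

    def session_stack(self, session: int) -> np.ndarray:
        """(n_subjects, n_rois, n_samples) array of one session per subject."""
        return np.stack([s.sessions[session] for s in self.subjects])


def _sample_state_path(pair: PairPlan, n_segments: int,
                       rng: np.random.Generator) -> np.ndarray:
    states = np.empty(n_segments, dtype=np.int64)
    s = int(rng.integers(len(pair.modes)))
    cum = np.cumsum(pair.transmat, axis=1)
    draws = rng.random(n_segments)
    for t in range(n_segments):
        states[t] = s
        s = int(np.searchsorted(cum[s], draws[t], side="right"))
        s = min(s, len(pair.modes) - 1)
    return states


def _realize_session(plan: CouplingPlan, duration: float, rate: float,
                     noise_level: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One session from a plan: returns (rois, truth_labels_per_sample)."""
    n = int(round(duration * rate))
    R = plan.n_rois
    bands = CANONICAL_BANDS
    osc = np.empty((R, len(bands), n))
    for r in range(R):
        for b, band in enumerate(bands):
            osc[r, b] = gen_oscillatory_source(band, duration, rate, rng)

    seg_n = int(round(plan.segment_s * rate))
    n_segments = int(np.ceil(n / seg_n))
    truth = np.zeros((len(plan.pairs), n), dtype=np.int16)

    for p_idx, pair in enumerate(plan.pairs):
        states = _sample_state_path(pair, n_segments, rng)
        labels = np.repeat(np.asarray(pair.modes)[states], seg_n)[:n]
        truth[p_idx] = labels
        for m in pair.modes:
            lo, hi = mode_bands(m)
            mask = labels == m
            if not mask.any():
                continue
            if lo == hi:
                coupled = plant_phase_coupling(osc[pair.i, lo], bands[lo],
                                               pair.lag, pair.strength, rate, rng)
                osc[pair.j, lo, mask] = coupled[mask]
            else:
                coupled = plant_pac(osc[pair.i, lo], bands[lo], bands[hi],
                                    pair.depth, rate, rng, lag=pair.lag)
                osc[pair.j, hi, mask] = coupled[mask]

    rois = osc.sum(axis=1)
    if noise_level > 0:
        for r in range(R):
            rois[r] += noise_level * pink_noise(n, rate, rng)
    return rois, truth


def gen_subject(plan: CouplingPlan, duration: float = 60.0, rate: float = 600.0,
                noise_level: float = 1.0, seed=0, n_sessions: int = 2,
                subject_id: str = "sub-00") -> SubjectRecord:
    """Realise ``n_sessions`` independent recordings from one plan.

    Both sessions share the plan (the identity-carrying structure) and
    differ only in their random realisation.
    """
    sessions, truths = [], []
    for s in range(n_sessions):
        rng = np.random.default_rng([int(seed), s])
        rois, truth = _realize_session(plan, duration, rate, noise_level, rng)
        sessions.append(rois)
        truths.append(truth)
    return SubjectRecord(subject_id, sessions, rate, plan, truths)


def gen_cohort(n_subjects: int, n_rois: int = 20, duration: float = 60.0,
               rate: float = 600.0, noise_level: float = 1.0, seed: int = 0,
               n_sessions: int = 2, **plan_kw) -> SyntheticCohort:
    """A cohort of subjects with independently drawn plans."""
    subjects = []
    for k in range(n_subjects):
        plan = random_plan(n_rois, np.random.default_rng([seed, 7, k]), **plan_kw)
        subjects.append(gen_subject(plan, duration, rate, noise_level,
                                    seed=seed * 100003 + k, n_sessions=n_sessions,
                                    subject_id=f"sub-{k:02d}"))
    return SyntheticCohort(subjects, rate, n_rois)


def gen_two_cohorts(n1: int, n2: int, n_overlap: int, seed: int = 0,
                    n_rois: int = 20, duration: float = 60.0,
                    rate: float = 600.0, noise_level: float = 1.0,
                    **plan_kw):
    """Two cohorts with a planted, manifest-recorded subject overlap.

    Cohort 1 has two sessions per subject (a test-retest study); cohort 2
    has one session per subject.  ``n_overlap`` cohort-2 members are
    regenerated from cohort-1 plans with fresh seeds and placed at shuffled
    positions; the manifest lists the true (cohort1, cohort2) id pairs and
    is the only place the overlap is recorded.
    """
    if min(n1, n2, n_overlap) < 0:
        raise ValueError("cohort sizes and overlap must be non-negative")
    if n_overlap > min(n1, n2):
        raise ValueError("overlap exceeds cohort size")
    cohort1 = gen_cohort(n1, n_rois, duration, rate, noise_level, seed=seed,
                         n_sessions=2, **plan_kw)
    rng = np.random.default_rng([seed, 99])
    positions = rng.permutation(n2)
    overlap_c1 = rng.choice(n1, size=n_overlap, replace=False)
    manifest = sorted(zip(overlap_c1.tolist(), positions[:n_overlap].tolist()))
    subjects2: list[SubjectRecord | None] = [None] * n2
    for slot, (c1_idx, c2_pos) in enumerate(zip(overlap_c1, positions[:n_overlap])):
        plan = cohort1.subjects[c1_idx].plan
        subjects2[c2_pos] = gen_subject(plan, duration, rate, noise_level,
                                        seed=seed * 100003 + 5000 + slot,
                                        n_sessions=1,
                                        subject_id=f"sub2-{c2_pos:02d}")
    fresh = iter(positions[n_overlap:])
    for k in range(n2 - n_overlap):
        pos = int(next(fresh))
        plan = random_plan(n_rois, np.random.default_rng([seed, 13, k]), **plan_kw)
        subjects2[pos] = gen_subject(plan, duration, rate, noise_level,
                                     seed=seed * 100003 + 9000 + k,
                                     n_sessions=1, subject_id=f"sub2-{pos:02d}")
    cohort2 = SyntheticCohort(subjects2, rate, n_rois)
    return cohort1, cohort2, [tuple(m) for m in manifest]


def gen_voxel_rois(roi_signal: np.ndarray, n_voxels: int,
                   weight_profile: np.ndarray | None = None,
                   noise: float = 0.1, seed=0) -> np.ndarray:
    """Voxel bundle around a known ROI signal: voxel k = w_k * signal + noise."""
    if n_voxels < 1:
        raise ValueError("need at least one voxel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = np.asarray(roi_signal, dtype=float)
    if weight_profile is None:
        weight_profile = np.full(n_voxels, 1.0 / n_voxels)
    w = np.asarray(weight_profile, dtype=float)
    if len(w) != n_voxels:
        raise ValueError("weight profile length mismatch")
    if np.all(w == 0):
        raise ValueError("all-zero voxel weights")
    return w[:, None] * sig[None, :] + noise * rng.standard_normal((n_voxels, len(sig)))
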