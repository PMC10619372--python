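"""Shared fixtures.

The expensive end-to-end objects (a two-cohort study with the full
dominant-coupling-mode pipeline, per-edge dHMM banks and log-likelihood
tensors) are built once per session and shared by the acceptance tests;
module tests use small dedicated inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from docm.bands import CANONICAL_BANDS as BANDS
from docm.bands import mode_label
from docm.coupling import compute_dfcg
from docm.docm_select import SurrogateConfig, build_idfcg
from docm.synth import (gen_oscillatory_source, gen_two_cohorts, pink_noise,
                        plant_pac, plant_phase_coupling)

RATE = 600.0


@pytest.fixture(scope="session")
def planted_pair_idfcg():
    """Small 6-ROI recording with an always-on phase pair and a PAC pair."""
    from docm.synth import CouplingPlan, PairPlan, gen_subject

    plan = CouplingPlan(6, [
        PairPlan(0, 1, (mode_label(6, 6),), np.array([[1.0]])),
        PairPlan(2, 3, (mode_label(4, 7),), np.array([[1.0]])),
    ])
    sub = gen_subject(plan, duration=30, rate=RATE, noise_level=1.0, seed=11,
                      n_sessions=1)
    dfcg = compute_dfcg(sub.sessions[0], RATE)
    idfcg = build_idfcg(dfcg, SurrogateConfig(seed=5))
    return {"subject": sub, "dfcg": dfcg, "idfcg": idfcg, "plan": plan}


@pytest.fixture(scope="session")
def recovery_fixture():
    """Twenty driven pairs built directly from the planting primitives:
    ten alpha1 phase-coupled pairs (strength 1, lag pi/2) and ten
    theta->gamma2 PAC pairs (depth 0.9), in weak 1/f background."""
    dur = 60.0
    n = int(dur * RATE)
    rng = np.random.default_rng(7)
    rois, targets = [], []
    for _ in range(10):
        x = gen_oscillatory_source(BANDS[2], dur, RATE, rng)
        y = plant_phase_coupling(x, BANDS[2], np.pi / 2, 1.0, RATE, rng)
        rois += [x, y]
        targets.append(mode_label(2, 2))
    for _ in range(10):
        x = gen_oscillatory_source(BANDS[1], dur, RATE, rng)
        y = plant_pac(x, BANDS[1], BANDS[7], 0.9, RATE, rng)
        rois += [x, y]
        targets.append(mode_label(1, 7))
    rois = np.stack(rois) + 0.2 * np.stack([pink_noise(n, RATE, rng)
                                            for _ in range(40)])
    idfcg = build_idfcg(compute_dfcg(rois, RATE), SurrogateConfig(seed=3))
    return {"idfcg": idfcg, "targets": targets}


@pytest.fixture(scope="session")
def study_bundle():
    """The full desk-scale two-cohort study.

    Cohort 1: 10 subjects x 2 sessions (20 ROIs, 60 s at 600 Hz); cohort 2:
    20 subjects x 1 session with 6 cohort-1 members hidden inside.  The
    bundle carries the fitted models, the log-likelihood tensors, the
    greedy edge selection and the external matching result.
    """
    from docm.pipeline import (cohort_sequences, run_external_match,
                               run_fingerprint_study)

    c1, c2, manifest = gen_two_cohorts(10, 20, 6, seed=1)
    s1, iu, ju, strengths1 = cohort_sequences(c1, 0, keep_strengths=True)
    s2, _, _, strengths2 = cohort_sequences(c1, 1, keep_strengths=True)
    res = run_fingerprint_study(s1, s2, iu, ju, seed=1)
    sc2, _, _ = cohort_sequences(c2, 0)
    matches, scores, L2 = run_external_match(res, sc2)
    return {
        "cohort1": c1, "cohort2": c2, "manifest": manifest,
        "train_seqs": s1, "test_seqs": s2, "cohort2_seqs": sc2,
        "strengths1": strengths1, "strengths2": strengths2,
        "iu": iu, "ju": ju, "result": res,
        "matches": matches, "external_scores": scores, "L2": L2,
    }
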