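"""Identification of individuals from dominant-coupling-mode dynamics.

The pipeline treats each region pair's label sequence as the observable of
a per-subject discrete HMM:

1. fit one dHMM per (subject, edge) on the training session;
2. classify test sequences by the model giving the highest log-likelihood;
3. rank edges by single-edge identification accuracy;
4. greedily aggregate edges (summed log-likelihood) while accuracy strictly
   improves, stopping at 100% or a plateau;
5. summarise train/test similarity as a subjects x subjects matrix of
   summed log-likelihoods, from which match/non-match thresholds are
   learned for blind matching against an external cohort;
6. score per-subject distinctiveness (differentiability: z-score of the
   self-match against the cross-subject distribution).

Everything heavy runs on a cached log-likelihood tensor ``L[e, k, m]``
(edge, training subject, test subject) so that ranking, greedy selection,
random-subset controls and subnetwork analyses are all cheap sums.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bands import N_MODES
from .hmm import BatchModels, fit_batch_bic

__all__ = [
    "pd_feature_matrix",
    "EdgeModels",
    "fit_edge_models",
    "edge_logliks",
    "identification_accuracy",
    "rank_edges",
    "stepwise_select",
    "similarity_matrix",
    "MatchDecision",
    "learn_thresholds",
    "external_match",
    "differentiability",
    "subnetwork_performance",
    "SUBNETWORK_LABELS",
]

#: canonical epoch boundaries for a 2991-window recording
_EPOCH_EDGES_2991 = (0, 500, 1000, 1500, 2000, 2500, 2991)


def pd_feature_matrix(seq: np.ndarray, n_epochs: int = 6) -> np.ndarray:
    """Per-epoch probability distribution of nonzero labels: (6, 36).

    The canonical epoching splits 2991 windows as {500 x 5, 491}; other
    lengths scale those boundaries proportionally.  Row e holds the
    empirical frequency of each nonzero label among epoch e's windows
    (rows sum to <= 1 because label 0 means "no coupling").
    """
    seq = np.asarray(seq)
    T = len(seq)
    if T < n_epochs:
        raise ValueError("sequence shorter than the number of epochs")
    edges = np.round(np.asarray(_EPOCH_EDGES_2991) * T / 2991.0).astype(int)
    edges[0], edges[-1] = 0, T
    if np.any(np.diff(edges) <= 0):  # very short sequences: equal split
        edges = np.linspace(0, T, n_epochs + 1).astype(int)
    fm = np.zeros((n_epochs, N_MODES))
    for e in range(n_epochs):
        chunk = seq[edges[e]:edges[e + 1]]
        if chunk.size == 0:
            raise ValueError("empty epoch")
        counts = np.bincount(chunk, minlength=N_MODES + 1)
        fm[e] = counts[1:] / chunk.size
    return fm


# ---------------------------------------------------------------------------
# Per-edge model banks and the log-likelihood tensor
# ---------------------------------------------------------------------------

@dataclass
class EdgeModels:
    """One dHMM per (training subject, edge), padded to a common state count.

    Arrays are (K, E, n), (K, E, n, n), (K, E, n, S); ``n_states`` holds the
    BIC-selected count per model.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray
    n_states: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.startprob.shape[0]

    @property
    def n_edges(self) -> int:
        return self.startprob.shape[1]


def fit_edge_models(train_seqs: np.ndarray, state_grid=(2, 3), *,
                    n_iter: int = 50, tol: float = 1e-3, n_restarts: int = 1,
                    seed: int = 0) -> EdgeModels:
    """Fit the full (subject, edge) bank of dHMMs.

    ``train_seqs`` is (K subjects, E edges, T windows) of integer labels.
    Desk-scale defaults (state grid {2,3}, one restart) keep the ~2000 fits
    tractable; the grid and restart count are free parameters.
    """
    K, E, T = train_seqs.shape
    fits: list[BatchModels] = []
    for k in range(K):
        fits.append(fit_batch_bic(train_seqs[k], state_grid, n_iter=n_iter,
                                  tol=tol, n_restarts=n_restarts,
                                  seed=seed + 1000 * k))
    nmax = max(int(f.startprob.shape[1]) for f in fits)
    S = fits[0].emissionprob.shape[2]
    start = np.zeros((K, E, nmax))
    trans = np.tile(np.eye(nmax), (K, E, 1, 1))
    emis = np.full((K, E, nmax, S), 1.0 / S)
    nst = np.zeros((K, E), dtype=int)
    for k, f in enumerate(fits):
        n = f.startprob.shape[1]
        start[k, :, :n] = f.startprob
        trans[k, :, :n, :n] = f.transmat
        emis[k, :, :n, :] = f.emissionprob
        nst[k] = f.n_states
    return EdgeModels(start, trans, emis, nst)


def edge_logliks(models: EdgeModels, test_seqs: np.ndarray) -> np.ndarray:
    """Forward log-likelihood tensor ``L[e, k, m]`` for every edge, training
    subject and test subject, computed in one scaled pass over time."""
    K, E, n, S = models.emissionprob.shape
    test_seqs = np.asarray(test_seqs)
    M = test_seqs.shape[0]
    if test_seqs.shape[1] != E:
        raise ValueError("edge count mismatch between models and sequences")
    T = test_seqs.shape[2]
    # reorder to edge-major: (E, K, ...)
    start = models.startprob.transpose(1, 0, 2)
    trans = models.transmat.transpose(1, 0, 2, 3)
    emis = models.emissionprob.transpose(1, 0, 2, 3)
    seqs = test_seqs.transpose(1, 0, 2)                    # (E, M, T)
    eidx = np.arange(E)[:, None, None]
    kidx = np.arange(K)[None, :, None]

    def frames(t):
        sym = seqs[:, :, t]                                # (E, M)
        return emis[eidx, kidx, :, sym[:, None, :]]        # (E, K, M, n)

    a = start[:, :, None, :] * frames(0)
    c = np.maximum(a.sum(axis=3), 1e-300)
    a /= c[..., None]
    ll = np.log(c)
    for t in range(1, T):
        a = np.einsum("ekmi,ekij->ekmj", a, trans) * frames(t)
        c = np.maximum(a.sum(axis=3), 1e-300)
        a /= c[..., None]
        ll += np.log(c)
    return ll                                              # (E, K, M)


# ---------------------------------------------------------------------------
# Ranking, greedy aggregation, similarity
# ---------------------------------------------------------------------------

def identification_accuracy(scores: np.ndarray) -> float:
    """Fraction of test subjects m whose best-scoring training model is m.

    ``scores`` is (K, M) with aligned identities on the diagonal; argmax
    ties resolve to the lowest subject index."""
    pred = np.argmax(scores, axis=0)
    m = scores.shape[1]
    return float(np.mean(pred == np.arange(m)))


def rank_edges(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank edges by single-edge identification accuracy (descending; ties
    break toward the lower edge index).  Returns (order, accuracies)."""
    E = L.shape[0]
    acc = np.array([identification_accuracy(L[e]) for e in range(E)])
    order = np.lexsort((np.arange(E), -acc))
    return order, acc


def stepwise_select(L: np.ndarray, order: np.ndarray | None = None, *,
                    plateau_patience: int = 5
                    ) -> tuple[list[int], np.ndarray]:
    """Greedy edge aggregation by summed log-likelihood.

    Walk the ranked edge list; an edge is retained only if adding it
    strictly improves identification accuracy.  Stops at 100% accuracy or
    after ``plateau_patience`` consecutive non-improving candidates.
    Returns the selected edge indices and the (non-decreasing) accuracy
    curve after each retained edge.
    """
    if order is None:
        order, _ = rank_edges(L)
    selected: list[int] = []
    curve: list[float] = []
    cum = np.zeros(L.shape[1:])
    best = -1.0
    misses = 0
    for e in order:
        cand = cum + L[e]
        acc = identification_accuracy(cand)
        if acc > best:
            selected.append(int(e))
            curve.append(acc)
            cum = cand
            best = acc
            misses = 0
            if best >= 1.0:
                break
        else:
            misses += 1
            if misses >= plateau_patience:
                break
    return selected, np.asarray(curve)


def similarity_matrix(L: np.ndarray, edge_set) -> np.ndarray:
    """(K, M) summed log-likelihoods over an edge subset."""
    edge_set = list(edge_set)
    if not edge_set:
        raise ValueError("empty edge set")
    return L[edge_set].sum(axis=0)


@dataclass
class MatchDecision:
    """Match/non-match decision rule learned from a training similarity
    matrix: the cutoff sits midway between the off-diagonal mean + 3 SD and
    the diagonal mean - 3 SD."""

    off_mean: float
    off_sd: float
    diag_mean: float
    diag_sd: float
    cutoff: float


def learn_thresholds(sim: np.ndarray) -> MatchDecision:
    """Derive the external-matching cutoff from a within-study similarity
    matrix.  Raises if the 3-SD intervals of the diagonal (self-match) and
    off-diagonal (cross-subject) populations overlap."""
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    diag = np.diag(sim)
    off = sim[~np.eye(sim.shape[0], dtype=bool)]
    off_m, off_s = float(off.mean()), float(off.std(ddof=1)) if off.size > 1 else 0.0
    d_m, d_s = float(diag.mean()), float(diag.std(ddof=1)) if diag.size > 1 else 0.0
    lo = off_m + 3.0 * off_s
    hi = d_m - 3.0 * d_s
    if lo >= hi:
        raise ValueError("cohort not separable: self/cross score intervals overlap")
    return MatchDecision(off_m, off_s, d_m, d_s, 0.5 * (lo + hi))


def external_match(L2: np.ndarray, edge_set, decision: MatchDecision
                   ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Blind matching of training subjects into an external cohort.

    ``L2[e, k, m]`` holds log-likelihoods of cohort-2 sequences under
    cohort-1 models.  Subject k is declared present in cohort 2 when the
    maximum summed log-likelihood over cohort-2 subjects exceeds the
    decision cutoff; the matched identity is the argmax.  Returns the list
    of (train_subject, cohort2_subject) matches and the (K, M) score matrix.
    """
    scores = similarity_matrix(L2, edge_set)
    matches = []
    for k in range(scores.shape[0]):
        m = int(np.argmax(scores[k]))
        if scores[k, m] > decision.cutoff:
            matches.append((k, m))
    return matches, scores


def differentiability(row: np.ndarray, self_index: int | None = None) -> float:
    """z-score of a subject's self-match against their cross-subject scores.

    With a known self entry: (self - mean(others)) / sd(others).  Blind
    (external) matching has no self entry, so the max plays that role.
    """
    row = np.asarray(row, dtype=float)
    if self_index is None:
        self_index = int(np.argmax(row))
    others = np.delete(row, self_index)
    if others.size < 3:
        raise ValueError("need at least 3 non-self entries")
    sd = others.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance among non-self scores")
    return float((row[self_index] - others.mean()) / sd)


# ---------------------------------------------------------------------------
# Subnetwork grouping
# ---------------------------------------------------------------------------

SUBNETWORK_LABELS = ("DMN", "FP", "CO", "SM", "O")


def subnetwork_performance(L: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                           roi_networks: dict[int, str]
                           ) -> dict[tuple[str, str], float | None]:
    """Identification accuracy per within/between-subnetwork edge group.

    ``roi_networks`` maps every ROI index to one of the five canonical
    subnetwork labels, yielding 5 within-network groups and C(5,2) = 10
    between-network groups (15 runs).  Groups without edges report None.
    """
    n_rois = int(max(iu.max(), ju.max())) + 1
    missing = [r for r in range(n_rois) if r not in roi_networks]
    if missing:
        raise ValueError(f"ROIs without a subnetwork label: {missing}")
    bad = set(roi_networks.values()) - set(SUBNETWORK_LABELS)
    if bad:
        raise ValueError(f"unknown subnetwork labels: {bad}")
    groups = [(a, a) for a in SUBNETWORK_LABELS] + \
             list(itertools.combinations(SUBNETWORK_LABELS, 2))
    out: dict[tuple[str, str], float | None] = {}
    for a, b in groups:
        sel = [e for e in range(len(iu))
               if {roi_networks[int(iu[e])], roi_networks[int(ju[e])]} == ({a} if a == b else {a, b})]
        out[(a, b)] = (identification_accuracy(similarity_matrix(L, sel))
                       if sel else None)
    return out
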