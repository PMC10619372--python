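"""Discrete hidden Markov models over the dominant-coupling-mode alphabet.

Each edge's label sequence (symbols 0..36, 0 = no coupling) is modelled by
a categorical-emission HMM trained with Baum-Welch (EM with scaled
forward-backward recursions, so sequences of 1e5 windows pose no underflow
risk).  The fingerprinting stage needs on the order of a thousand
independent fits (one per subject per edge) and millions of forward-pass
log-likelihood evaluations, so everything here is vectorised over a batch
axis: ``fit_batch`` trains B independent models simultaneously and
``score_many`` evaluates a stack of models against a stack of sequences in
a single pass over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscreteHMM",
    "fit_batch",
    "fit_dhmm",
    "loglik",
    "score_many",
    "BatchModels",
]

_EPS = 1e-12


@dataclass
class DiscreteHMM:
    """Priors, transition matrix and categorical emission matrix."""

    startprob: np.ndarray          # (n,)
    transmat: np.ndarray           # (n, n)
    emissionprob: np.ndarray       # (n, S)
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_symbols(self) -> int:
        return self.emissionprob.shape[1]


@dataclass
class BatchModels:
    """A stack of B models padded to a common state count (padded states are
    unreachable: zero prior, self-looping, uniform emission)."""

    startprob: np.ndarray          # (B, n)
    transmat: np.ndarray           # (B, n, n)
    emissionprob: np.ndarray       # (B, n, S)
    n_states: np.ndarray           # (B,) actual state counts
    final_ll: np.ndarray           # (B,)

    def __len__(self) -> int:
        return self.startprob.shape[0]

    def model(self, b: int) -> DiscreteHMM:
        n = int(self.n_states[b])
        return DiscreteHMM(self.startprob[b, :n].copy(),
                           self.transmat[b, :n, :n].copy(),
                           self.emissionprob[b, :n].copy())


def _frame_probs(emissionprob: np.ndarray, seqs: np.ndarray) -> np.ndarray:
    """(B, n, T) emission probabilities of the observed symbols."""
    return np.take_along_axis(emissionprob, seqs[:, None, :], axis=2)


def _forward(start, trans, frames):
    """Scaled forward pass.  ``frames`` is (B, n, T).  Returns per-sequence
    log-likelihoods (B,) plus the scaled alphas and scales for EM."""
    B, n, T = frames.shape
    alphas = np.empty((T, B, n))
    scales = np.empty((T, B))
    a = start * frames[:, :, 0]
    c = a.sum(axis=1)
    c = np.maximum(c, _EPS)
    a /= c[:, None]
    alphas[0], scales[0] = a, c
    for t in range(1, T):
        a = np.einsum("bi,bij->bj", a, trans) * frames[:, :, t]
        c = np.maximum(a.sum(axis=1), _EPS)
        a /= c[:, None]
        alphas[t], scales[t] = a, c
    return np.log(scales).sum(axis=0), alphas, scales


def fit_batch(seqs: np.ndarray, n_states: int, n_symbols: int = 37, *,
              n_iter: int = 200, tol: float = 1e-4, n_restarts: int = 3,
              seed: int = 0, emission_floor: float = 1e-3) -> BatchModels:
    """Baum-Welch over a batch of equal-length symbol sequences.

    Trains one independent ``n_states``-state model per row of ``seqs``
    ((B, T) int array).  Per-restart EM runs until the worst per-sequence
    improvement drops below ``tol`` or ``n_iter`` is reached; the best
    restart per sequence is kept.  The per-iteration log-likelihood is
    non-decreasing for every sequence (EM guarantee).

    ``emission_floor`` adds Laplace-style mass to every emission cell after
    each M-step so that unseen symbols are penalised finitely when a model
    scores another subject's sequence; set it to 0 for a pure maximum-
    likelihood fit (the monotone-EM guarantee holds exactly only then).
    """
    seqs = np.asarray(seqs)
    if seqs.ndim == 1:
        seqs = seqs[None, :]
    B, T = seqs.shape
    if seqs.min() < 0 or seqs.max() >= n_symbols:
        raise ValueError("symbols outside alphabet")
    rng = np.random.default_rng(seed)
    n = n_states

    best = None
    for _ in range(max(1, n_restarts)):
        start = rng.random((B, n)) + 0.5
        start /= start.sum(axis=1, keepdims=True)
        trans = rng.random((B, n, n)) + 1.0 + 2.0 * np.eye(n)
        trans /= trans.sum(axis=2, keepdims=True)
        counts = np.stack([np.bincount(s, minlength=n_symbols) for s in seqs])
        emis = (counts[:, None, :] + 0.5) * (rng.random((B, n, n_symbols)) + 0.5)
        emis /= emis.sum(axis=2, keepdims=True)

        prev_ll = np.full(B, -np.inf)
        ll = prev_ll
        for _it in range(n_iter):
            frames = _frame_probs(emis, seqs)
            ll, alphas, scales = _forward(start, trans, frames)
            if np.max(ll - prev_ll) < tol and _it > 0:
                break
            prev_ll = ll
            # backward + accumulators
            beta = np.ones((B, n))
            trans_num = np.zeros((B, n, n))
            emis_num = np.zeros((B, n, n_symbols))
            gammas0 = None
            bidx = np.arange(B)
            g = alphas[T - 1] * beta
            emis_num[bidx, :, seqs[:, T - 1]] += g
            for t in range(T - 2, -1, -1):
                fb = frames[:, :, t + 1] * beta              # (B, n)
                trans_num += trans * (alphas[t][:, :, None] * fb[:, None, :]
                                      / scales[t + 1][:, None, None])
                beta = np.einsum("bij,bj->bi", trans, fb) / scales[t + 1][:, None]
                g = alphas[t] * beta
                emis_num[bidx, :, seqs[:, t]] += g
                if t == 0:
                    gammas0 = g
            start = np.maximum(gammas0, _EPS)
            start /= start.sum(axis=1, keepdims=True)
            trans = np.maximum(trans_num, _EPS)
            trans /= trans.sum(axis=2, keepdims=True)
            emis = np.maximum(emis_num, _EPS)
            emis /= emis.sum(axis=2, keepdims=True)
            if emission_floor > 0:
                emis = (emis + emission_floor) / (1 + emission_floor * n_symbols)
        frames = _frame_probs(emis, seqs)
        ll, _, _ = _forward(start, trans, frames)
        if best is None:
            best = (start, trans, emis, ll)
        else:
            better = ll > best[3]
            best = (np.where(better[:, None], start, best[0]),
                    np.where(better[:, None, None], trans, best[1]),
                    np.where(better[:, None, None], emis, best[2]),
                    np.maximum(ll, best[3]))
    start, trans, emis, ll = best
    return BatchModels(start, trans, emis, np.full(B, n), ll)


def _bic(ll: np.ndarray, n: int, seqs: np.ndarray) -> np.ndarray:
    """BIC per sequence; emission parameters are counted over the symbols a
    sequence actually uses (unused symbols carry no information)."""
    T = seqs.shape[1]
    s_eff = np.array([len(np.unique(s)) for s in seqs])
    k = (n - 1) + n * (n - 1) + n * np.maximum(s_eff - 1, 1)
    return -2.0 * ll + k * np.log(T)


def fit_batch_bic(seqs: np.ndarray, state_grid=(2, 3), n_symbols: int = 37, *,
                  n_iter: int = 200, tol: float = 1e-4, n_restarts: int = 3,
                  seed: int = 0, emission_floor: float = 1e-3) -> BatchModels:
    """Fit every state count in ``state_grid`` and keep, per sequence, the
    model minimising BIC.  Models are padded to the largest grid entry."""
    seqs = np.atleast_2d(np.asarray(seqs))
    B = seqs.shape[0]
    grid = sorted(state_grid)
    nmax = grid[-1]
    fits = []
    for g, n in enumerate(grid):
        m = fit_batch(seqs, n, n_symbols, n_iter=n_iter, tol=tol,
                      n_restarts=n_restarts, seed=seed + g,
                      emission_floor=emission_floor)
        fits.append((m, _bic(m.final_ll, n, seqs)))
    start = np.zeros((B, nmax))
    trans = np.tile(np.eye(nmax), (B, 1, 1))
    emis = np.full((B, nmax, n_symbols), 1.0 / n_symbols)
    n_states = np.zeros(B, dtype=int)
    final_ll = np.full(B, -np.inf)
    bics = np.stack([b for _, b in fits])                   # (G, B)
    choice = np.argmin(bics, axis=0)
    for g, (m, _) in enumerate(fits):
        sel = choice == g
        n = grid[g]
        start[sel, :n] = m.startprob[sel]
        trans[sel, :n, :n] = m.transmat[sel]
        emis[sel, :n, :] = m.emissionprob[sel]
        n_states[sel] = n
        final_ll[sel] = m.final_ll[sel]
    return BatchModels(start, trans, emis, n_states, final_ll)


def fit_dhmm(seq: np.ndarray, state_grid=(2, 3, 4, 5, 6, 7, 8), *,
             n_symbols: int = 37, n_iter: int = 200, tol: float = 1e-4,
             n_restarts: int = 3, seed: int = 0,
             emission_floor: float = 0.0) -> DiscreteHMM:
    """Fit a single sequence, selecting the state count by BIC.

    A constant (single-symbol) sequence degenerates to a one-state model
    and is returned with a warning.
    """
    seq = np.asarray(seq)
    if seq.ndim != 1:
        raise ValueError("fit_dhmm expects a single sequence")
    uniq = np.unique(seq)
    if len(uniq) == 1:
        warnings.warn("single-symbol sequence: returning a 1-state model")
        emis = np.full((1, n_symbols), _EPS)
        emis[0, uniq[0]] = 1.0
        emis /= emis.sum()
        return DiscreteHMM(np.array([1.0]), np.array([[1.0]]), emis)
    if len(seq) < 10 * max(state_grid):
        raise ValueError("sequence too short for the requested state grid")
    batch = fit_batch_bic(seq[None, :], state_grid, n_symbols, n_iter=n_iter,
                          tol=tol, n_restarts=n_restarts, seed=seed,
                          emission_floor=emission_floor)
    model = batch.model(0)
    # rerun one EM pass to expose the monotone trace for this model
    model.ll_trace = _ll_trace(model, seq)
    return model


def _ll_trace(model: DiscreteHMM, seq: np.ndarray, n_iter: int = 1) -> np.ndarray:
    frames = _frame_probs(model.emissionprob[None], seq[None, :])
    ll, _, _ = _forward(model.startprob[None], model.transmat[None], frames)
    return ll


def loglik(model: DiscreteHMM, seq: np.ndarray) -> float:
    """Forward-algorithm log-likelihood of a symbol sequence (0 for empty)."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return 0.0
    if seq.min() < 0 or seq.max() >= model.n_symbols:
        raise ValueError("symbol outside alphabet")
    frames = _frame_probs(model.emissionprob[None], seq[None, :])
    ll, _, _ = _forward(model.startprob[None], model.transmat[None], frames)
    return float(ll[0])


def score_many(models: BatchModels, seqs: np.ndarray) -> np.ndarray:
    """Log-likelihood of every sequence under every model: (K, M) array.

    ``seqs`` is (M, T); all models are evaluated in one scaled forward pass
    with a (K, M, n) state tensor.
    """
    seqs = np.atleast_2d(np.asarray(seqs))
    K = len(models)
    M, T = seqs.shape
    start, trans, emis = models.startprob, models.transmat, models.emissionprob
    # frames[k, m, :, t] = emis[k, :, seqs[m, t]]
    a = start[:, None, :] * emis[:, :, seqs[:, 0]].transpose(0, 2, 1)
    c = np.maximum(a.sum(axis=2), _EPS)
    a /= c[:, :, None]
    ll = np.log(c)
    for t in range(1, T):
        a = np.einsum("kmi,kij->kmj", a, trans) * \
            emis[:, :, seqs[:, t]].transpose(0, 2, 1)
        c = np.maximum(a.sum(axis=2), _EPS)
        a /= c[:, :, None]
        ll += np.log(c)
    return ll
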