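"""Maximum-likelihood univariate normal mixture fitting by EM.

Punctum-area distributions in condensate-forming cells are well
described by a two-component normal mixture: a population of uniformly
small puncta (P1) and a broader population of larger ones (P2).
This module fits K-component mixtures by expectation–maximization with
multiple jittered restarts, resolves label switching by sorting
components by mean (P1 = smallest mean), and compares component counts
by information criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class MixtureModel:
    """A fitted K-component univariate normal mixture.

    Components are sorted by mean ascending, so index 0 is the
    small-mean population (P1).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    seed: int | None = None
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def n_parameters(self) -> int:
        return 3 * self.k - 1

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = self.weights * norm.pdf(x[:, None], self.means, self.sds)
        return comp.sum(axis=1)


def _log_likelihood(x, weights, means, sds) -> float:
    comp = np.log(weights) + norm.logpdf(x[:, None], means, sds)
    m = comp.max(axis=1)
    return float((m + np.log(np.exp(comp - m[:, None]).sum(axis=1))).sum())


def _quantile_init(x_sorted, k, rng=None):
    """Split sorted data into K contiguous blocks; optionally jitter cuts."""
    n = len(x_sorted)
    cuts = np.linspace(0, n, k + 1).astype(int)
    if rng is not None and k > 1:
        jitter = rng.integers(-n // (4 * k) or 0, (n // (4 * k) or 0) + 1, size=k - 1)
        cuts[1:-1] = np.clip(cuts[1:-1] + jitter, 1, n - 1)
        cuts[1:-1].sort()
    means, sds = [], []
    for i in range(k):
        block = x_sorted[cuts[i] : max(cuts[i + 1], cuts[i] + 1)]
        means.append(block.mean())
        sds.append(block.std() if block.std() > 0 else x_sorted.std() / k + 1e-6)
    return np.full(k, 1.0 / k), np.array(means), np.array(sds)


def _em_single(x, weights, means, sds, var_floor, tol, max_iter):
    ll_history = []
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        # E step: responsibilities via log-sum-exp
        logc = np.log(weights) + norm.logpdf(x[:, None], means, sds)
        m = logc.max(axis=1, keepdims=True)
        logsum = m + np.log(np.exp(logc - m).sum(axis=1, keepdims=True))
        resp = np.exp(logc - logsum)
        ll = float(logsum.sum())
        ll_history.append(ll)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
        if ll - ll_old < tol * max(abs(ll), 1.0) and it > 1:
            return weights, means, sds, ll, it, True, np.array(ll_history)
        ll_old = ll
    return weights, means, sds, ll, max_iter, False, np.array(ll_history)


def em_fit(
    values,
    k: int = 2,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureModel:
    """Best-of-restarts EM fit of a K-component normal mixture.

    Initialization is a quantile split of the sorted data into K blocks
    (block means and SDs, equal weights); each restart jitters the block
    boundaries. The variance floor ``1e-6·range²`` prevents component
    collapse onto single points. The log-likelihood is non-decreasing
    across EM iterations (``ll_history`` records it per iteration).
    """
    x = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(x)) < 2 * k:
        raise ValueError(f"need at least {2 * k} distinct values for k={k}")
    x_sorted = np.sort(x)
    var_floor = 1e-6 * np.ptp(x) ** 2
    rng = np.random.default_rng(seed)

    if k == 1:
        mu = x.mean()
        sd = max(x.std(), np.sqrt(var_floor))  # ML (1/n) estimate
        ll = _log_likelihood(x, np.ones(1), np.array([mu]), np.array([sd]))
        return MixtureModel(
            weights=np.ones(1), means=np.array([mu]), sds=np.array([sd]),
            log_likelihood=ll, n_iterations=0, converged=True, seed=seed,
            ll_history=np.array([ll]),
        )

    best = None
    for r in range(max(restarts, 1)):
        w0, m0, s0 = _quantile_init(x_sorted, k, rng=None if r == 0 else rng)
        w, m, s, ll, n_it, conv, hist = _em_single(
            x, w0, m0, s0, var_floor, tol, max_iter
        )
        if best is None or ll > best[3]:
            best = (w, m, s, ll, n_it, conv, hist)
    w, m, s, ll, n_it, conv, hist = best
    order = np.argsort(m)
    return MixtureModel(
        weights=w[order], means=m[order], sds=s[order],
        log_likelihood=ll, n_iterations=n_it, converged=conv, seed=seed,
        ll_history=hist,
    )


def classify_points(
    model: MixtureModel, values
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior component membership by Bayes' rule.

    Returns ``(responsibilities, labels)`` where responsibilities is an
    (n, K) matrix of posterior probabilities and labels the argmax
    component per value (0 = P1).
    """
    if not model.converged:
        raise ValueError("model did not converge")
    x = np.atleast_1d(np.asarray(values, dtype=float))
    logc = np.log(model.weights) + norm.logpdf(x[:, None], model.means, model.sds)
    m = logc.max(axis=1, keepdims=True)
    resp = np.exp(logc - m)
    resp /= resp.sum(axis=1, keepdims=True)
    return resp, resp.argmax(axis=1)


def compare_components(
    values, k_list=(1, 2, 3), restarts: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Fit one mixture per K and tabulate log-likelihood, AIC and BIC."""
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    rows = []
    models = {}
    for k in k_list:
        model = em_fit(x, k=k, restarts=restarts, seed=seed)
        models[k] = model
        p = model.n_parameters
        rows.append(
            {
                "k": k,
                "log_likelihood": model.log_likelihood,
                "aic": 2 * p - 2 * model.log_likelihood,
                "bic": p * np.log(n) - 2 * model.log_likelihood,
                "converged": model.converged,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["models"] = models
    return table
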