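"""Two-component Gaussian mixture on VAFs for clonal/subclonal calls.

Somatic VAF histograms of a near-clonal tumor line typically show a high
mode near the clonal fraction and a low-VAF subclonal tail.  A k=2
Gaussian mixture fitted by EM separates the two; the component with the
higher mean is labeled *clonal* and a variant is called clonal when its
posterior for that component reaches 0.5.

The fit is deliberately plain: untransformed VAFs, deterministic
initialization at the 25th/75th percentiles, a small variance floor, and
a 1e-8 log-likelihood convergence tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SD_FLOOR = 1e-4
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureFit:
    component_weights: np.ndarray  # (2,), sums to 1
    component_means: np.ndarray  # (2,), ascending; index 1 = clonal
    component_sds: np.ndarray  # (2,)
    posteriors: np.ndarray  # (n,), P(clonal component | vaf)
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray

    @property
    def clonal_labels(self) -> np.ndarray:
        """Boolean per-variant clonal call at the 0.5 posterior cutoff."""
        return self.posteriors >= 0.5


def _log_gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + 2.0 * np.log(sd) + ((x - mu) / sd) ** 2)


def fit_vaf_mixture(
    vafs,
    k: int = 2,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to VAFs by EM.

    ``seed`` is accepted for interface stability; the default
    initialization is deterministic, so it is unused.
    """
    if k != 2:
        raise ValueError("only k=2 is supported")
    x = np.asarray(vafs, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("insufficient data: need at least 10 VAF values")
    if np.ptp(x) == 0.0:
        raise ValueError("no mixture structure: all VAF values identical")

    q25, q75 = np.percentile(x, [25, 75])
    if q25 == q75:
        q25, q75 = float(x.min()), float(x.max())
    mu = np.array([q25, q75], dtype=float)
    sd = np.full(2, max(float(x.std()), _SD_FLOOR))
    w = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    n_iter = 0
    resp = np.empty((x.size, 2))
    for n_iter in range(1, max_iter + 1):
        # E step
        log_comp = np.column_stack(
            [np.log(w[j]) + _log_gauss(x, mu[j], sd[j]) for j in range(2)]
        )
        m = log_comp.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        loglik = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[:, None])
        if trace and abs(loglik - trace[-1]) <= tol * (1.0 + abs(trace[-1])):
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        # M step
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    resp = resp[:, order]
    return MixtureFit(
        component_weights=w,
        component_means=mu,
        component_sds=sd,
        posteriors=resp[:, 1],
        log_likelihood=trace[-1],
        n_iterations=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def single_component_loglik(vafs) -> float:
    """Log-likelihood of a single Gaussian fit (comparison baseline)."""
    x = np.asarray(vafs, dtype=float)
    sd = max(float(x.std()), _SD_FLOOR)
    return float(_log_gauss(x, float(x.mean()), sd).sum())
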