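"""Negative-binomial GLM fitting by iteratively reweighted least squares.

The NB2 parameterisation is used throughout: Var(Y) = mu + alpha * mu^2 with a
log link. The dispersion alpha is treated as known (estimated upstream by the
method of moments) so the IRLS weights are w = mu / (1 + alpha * mu) and the
Wald covariance is the inverse Fisher information (X' W X)^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_ETA_CLIP = 30.0  # keep exp() finite; counts beyond e^30 are outside scope


@dataclass
class NbGlmFit:
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    mu: np.ndarray
    df_resid: int

    def wald(self, index: int) -> tuple[float, float]:
        """Wald z statistic and two-sided normal p-value for one coefficient.

        The normal reference presumes the plugged-in dispersion is precise;
        pair this with a dispersion pooled across many features (see
        ``pooled_dispersion``) rather than a single-feature estimate, which
        is far too noisy at three replicates per group.
        """
        se = self.se[index]
        if not np.isfinite(se) or se <= 0:
            return np.nan, np.nan
        z = self.coef[index] / se
        return float(z), float(2.0 * stats.norm.sf(abs(z)))


def fit_nb_glm(y: np.ndarray, X: np.ndarray, alpha: float,
               offset: np.ndarray | None = None,
               max_iter: int = 100, tol: float = 1e-8) -> NbGlmFit:
    """Fit a log-link NB regression with fixed dispersion by IRLS.

    Parameters
    ----------
    y : non-negative counts, shape (n,)
    X : design matrix, shape (n, p)
    alpha : NB2 dispersion (>= 0; 0 reduces to Poisson weights)
    offset : optional known term added to the linear predictor (e.g. log size
        factors); defaults to 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    if alpha < 0:
        raise ValueError("dispersion alpha must be non-negative")

    # start from a weighted LS fit on the log scale
    eta = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        xtx = X.T @ Xw
        xtz = Xw.T @ z
        try:
            beta_new = np.linalg.solve(xtx, xtz)
        except np.linalg.LinAlgError:
            return NbGlmFit(beta, np.full(p, np.nan), False, it, mu, n - p)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break

    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    xtx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtx)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return NbGlmFit(beta, se, converged, it, mu, n - p)


def _raw_mom(norm_counts: np.ndarray, groups: np.ndarray) -> float:
    """Unfloored within-group MoM dispersion (s^2 - m) / m^2 for one feature.

    Returns NaN when no group has two observations or the mean is zero.
    Negative values are informative noise and are deliberately kept: they
    cancel when averaging across features.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    groups = np.asarray(groups)
    ss = 0.0
    df = 0
    for g in np.unique(groups):
        x = norm_counts[groups == g]
        if x.size >= 2:
            ss += np.sum((x - x.mean()) ** 2)
            df += x.size - 1
    m = norm_counts.mean()
    if df == 0 or m <= 0:
        return np.nan
    return float((ss / df - m) / m**2)


def mom_dispersion(norm_counts: np.ndarray, groups: np.ndarray,
                   eps: float = 1e-8) -> float:
    """Single-feature method-of-moments NB dispersion, floored at ``eps``.

    Within-cell variances are pooled so real signal between cells does not
    inflate the estimate.
    """
    raw = _raw_mom(norm_counts, groups)
    if np.isnan(raw):
        return eps
    return float(max(eps, raw))


def pooled_dispersion(norm_counts: np.ndarray, groups: np.ndarray,
                      eps: float = 1e-8) -> float:
    """Common NB dispersion pooled across features.

    ``norm_counts`` is a features x samples array of library-size-normalised
    counts. Per-feature unfloored MoM estimates are averaged (negative noise
    cancels) and the result floored at ``eps``. With a few replicates per
    group a single-feature dispersion is far too noisy for a normal-reference
    Wald test; averaging over features gives a precise common estimate, at
    the cost of ignoring feature-to-feature dispersion differences.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    per = np.array([_raw_mom(row, groups) for row in norm_counts])
    per = per[np.isfinite(per)]
    if per.size == 0:
        return eps
    return float(max(eps, per.mean()))
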