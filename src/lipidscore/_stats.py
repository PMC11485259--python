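"""Small shared numerical helpers (fast OLS with classical inference)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class CollinearityError(ValueError):
    """Raised when a design matrix is rank deficient."""


@dataclass
class OLSResult:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df_resid: int
    names: tuple[str, ...]
    residuals: np.ndarray

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        lo = self.beta - tcrit * self.se
        hi = self.beta + tcrit * self.se
        return np.column_stack([lo, hi])


def ols(y: np.ndarray, X: np.ndarray, names: tuple[str, ...] | None = None) -> OLSResult:
    """Ordinary least squares with t-based two-sided p-values.

    Parameters
    ----------
    y : response vector, shape (n,)
    X : design matrix including any intercept column, shape (n, k)
    names : optional column names used in error messages and results
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(k))
    if n <= k:
        raise ValueError(f"insufficient residual degrees of freedom (n={n}, k={k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j in range(k):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j])
        raise CollinearityError(f"collinear design columns: {bad}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    return OLSResult(beta=beta, se=se, p=p, df_resid=df, names=names, residuals=resid)


def require_seed(seed) -> np.random.Generator:
    """All stochastic operations require an explicit seed."""
    if seed is None:
        raise ValueError("an explicit integer seed is required for stochastic operations")
    return np.random.default_rng(seed)
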