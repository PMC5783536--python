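"""Binary logistic regression for the zero process of the two-part model.

Models the probability p_i of doing any leisure-time physical activity via
logit(p_i) = x_i'alpha, fitted by Newton-Raphson (equivalently iteratively
reweighted least squares) from a zero start.  Wald confidence intervals come
from the inverse observed information, and effects are reported as odds
ratios per model column (per 10 years of age, per US$1,000 of income, and
versus the reference level for dummies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._linalg import as_matrix, check_full_rank, invert_information, solve_psd, wald_z
from .exceptions import ConvergenceError, SeparationError

__all__ = ["LogisticPart", "LogisticFit", "fit_logistic", "odds_ratios"]

_TOL = 1e-10
_MAX_ITER = 100
_SEPARATION_BOUND = 30.0  # |log-odds| beyond this flags separation


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log(1 + e^eta) computed stably for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogisticFit:
    """MLE of the logistic zero-process model."""

    params: np.ndarray
    cov_params: np.ndarray
    loglik: float
    n: int
    converged: bool
    iterations: int
    term_names: list

    @property
    def coefficients(self) -> np.ndarray:
        return self.params

    @property
    def covariance(self) -> np.ndarray:
        return self.cov_params

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = wald_z(level)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratio exp(alpha_j) with Wald CI, one row per model column."""
        if not self.converged:
            raise ConvergenceError("odds ratios requested from an unconverged fit")
        ci = self.conf_int(level)
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.params,
                "se": self.bse,
                "OR": np.exp(self.params),
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
            }
        )

    def predict_proba(self, X) -> np.ndarray:
        Xv, _ = as_matrix(X)
        return expit(Xv @ self.params)

    def summary(self) -> str:
        lines = [
            "Logistic part (any activity vs none)",
            f"  n = {self.n}, log-likelihood = {self.loglik:.4f}, "
            f"converged = {self.converged} ({self.iterations} iterations)",
            f"  {'term':<14}{'coef':>10}{'se':>10}{'OR':>8}{'95% CI':>20}",
        ]
        table = self.odds_ratios()
        for _, r in table.iterrows():
            lines.append(
                f"  {r['term']:<14}{r['estimate']:>10.4f}{r['se']:>10.4f}"
                f"{r['OR']:>8.2f}   ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            )
        return "\n".join(lines)


class LogisticPart:
    """Model object; ``fit()`` returns a :class:`LogisticFit`."""

    def __init__(self, y, X):
        self.X, self.term_names = as_matrix(X)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y and X have different numbers of rows")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("y must be binary (0/1)")
        if self.y.min() == self.y.max():
            raise ValueError("both outcome classes must be present")
        check_full_rank(self.X, self.term_names)

    def loglik(self, alpha) -> float:
        return _bernoulli_loglik(self.y, self.X @ np.asarray(alpha, dtype=float))

    def score(self, alpha) -> np.ndarray:
        p = expit(self.X @ np.asarray(alpha, dtype=float))
        return self.X.T @ (self.y - p)

    def fit(self, tol: float = _TOL, max_iter: int = _MAX_ITER) -> LogisticFit:
        X, y = self.X, self.y
        n, p = X.shape
        alpha = np.zeros(p)
        ll = _bernoulli_loglik(y, X @ alpha)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            prob = expit(X @ alpha)
            w = prob * (1.0 - prob)
            H = X.T @ (X * w[:, None])
            g = X.T @ (y - prob)
            step = solve_psd(H, g)
            # step-halving keeps the likelihood monotone
            new_ll, lam = -np.inf, 1.0
            for _ in range(30):
                cand = alpha + lam * step
                new_ll = _bernoulli_loglik(y, X @ cand)
                if new_ll >= ll - 1e-12:
                    break
                lam /= 2.0
            improving = new_ll > ll
            alpha = alpha + lam * step
            if np.max(np.abs(alpha)) > _SEPARATION_BOUND and improving:
                j = int(np.argmax(np.abs(alpha)))
                raise SeparationError(self.term_names[j])
            if abs(new_ll - ll) <= tol * (abs(new_ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        prob = expit(X @ alpha)
        info = X.T @ (X * (prob * (1.0 - prob))[:, None])
        return LogisticFit(
            params=alpha,
            cov_params=invert_information(info),
            loglik=ll,
            n=n,
            converged=converged,
            iterations=it,
            term_names=list(self.term_names),
        )


def fit_logistic(X, y, **kwargs) -> LogisticFit:
    """Functional wrapper: fit the logistic zero-process model."""
    return LogisticPart(y, X).fit(**kwargs)


def odds_ratios(fit: LogisticFit, level: float = 0.95) -> pd.DataFrame:
    return fit.odds_ratios(level)
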