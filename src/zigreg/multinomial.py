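"""Baseline-category multinomial logit on the three-level activity outcome.

The comparator analysis: weekly minutes collapsed to none / low (<150
min/week) / high (>=150 min/week), with physical inactivity ("none") as the
reference category.  Coefficients are log-odds of each non-reference
category versus the reference; fitted by Newton-Raphson with the same
tolerance policy as the logistic part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import as_matrix, check_full_rank, invert_information, solve_psd, wald_z
from .data import ACTIVITY_CATEGORIES
from .exceptions import ConvergenceError, SeparationError

__all__ = [
    "BaselineMultinomial",
    "MultinomialFit",
    "fit_multinomial",
    "odds_ratios_multinomial",
]

_TOL = 1e-10
_MAX_ITER = 100
_SEPARATION_BOUND = 30.0


def _softmax_with_baseline(eta: np.ndarray) -> np.ndarray:
    """Probabilities for (baseline, cat1, cat2, ...) given non-baseline etas."""
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MultinomialFit:
    """MLE of the baseline-category multinomial model."""

    params: np.ndarray  # (n_categories-1, p), rows ordered as `categories`
    cov_params: np.ndarray  # ((n_categories-1)*p, (n_categories-1)*p)
    loglik: float
    n: int
    reference: str
    categories: list  # non-reference categories, row order of `params`
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
        return np.sqrt(np.diag(self.cov_params)).reshape(self.params.shape)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = wald_z(level)
        se = self.bse
        return np.stack([self.params - z * se, self.params + z * se], axis=-1)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """OR versus the reference category per non-reference category."""
        if not self.converged:
            raise ConvergenceError("odds ratios requested from an unconverged fit")
        ci = self.conf_int(level)
        rows = []
        for c, cat in enumerate(self.categories):
            for j, term in enumerate(self.term_names):
                rows.append(
                    {
                        "category": cat,
                        "term": term,
                        "estimate": self.params[c, j],
                        "se": self.bse[c, j],
                        "OR": np.exp(self.params[c, j]),
                        "ci_low": np.exp(ci[c, j, 0]),
                        "ci_high": np.exp(ci[c, j, 1]),
                    }
                )
        return pd.DataFrame(rows)

    def predict_proba(self, X) -> pd.DataFrame:
        """Per-row category probabilities (reference first); rows sum to 1."""
        Xv, _ = as_matrix(X)
        probs = _softmax_with_baseline(Xv @ self.params.T)
        return pd.DataFrame(probs, columns=[self.reference] + list(self.categories))

    def summary(self) -> str:
        lines = [
            "Multinomial model (reference category: does no physical activity)",
            f"  n = {self.n}, log-likelihood = {self.loglik:.4f}, "
            f"converged = {self.converged} ({self.iterations} iterations)",
        ]
        table = self.odds_ratios()
        for cat in self.categories:
            sub = table[table["category"] == cat]
            label = "< 150 min/week" if cat == "low" else ">= 150 min/week"
            lines.append(f"  {label}:")
            for _, r in sub.iterrows():
                lines.append(
                    f"    {r['term']:<14}OR {r['OR']:.2f} "
                    f"({r['ci_low']:.2f}-{r['ci_high']:.2f})"
                )
        return "\n".join(lines)


class BaselineMultinomial:
    """Model object; ``fit()`` returns a :class:`MultinomialFit`."""

    def __init__(self, y3, X, reference: str = "none", categories=None):
        self.X, self.term_names = as_matrix(X)
        y3 = np.asarray(y3, dtype=object).ravel()
        if y3.shape[0] != self.X.shape[0]:
            raise ValueError("y3 and X have different numbers of rows")
        if categories is None:
            found = set(y3)
            categories = [c for c in ACTIVITY_CATEGORIES if c in found]
            extra = sorted(found - set(categories))
            categories += extra
        if reference not in categories:
            raise ValueError(f"reference {reference!r} not among categories")
        present = pd.Series(y3).value_counts()
        empty = [c for c in categories if present.get(c, 0) == 0]
        if empty:
            raise ValueError(f"empty outcome categories: {empty}")
        unknown = set(y3) - set(categories)
        if unknown:
            raise ValueError(f"unknown outcome categories: {sorted(unknown)}")
        self.reference = reference
        self.categories = [c for c in categories if c != reference]
        # indicator matrix for the non-reference categories
        self.Y = np.column_stack([(y3 == c).astype(float) for c in self.categories])
        check_full_rank(self.X, self.term_names)

    def loglik(self, B) -> float:
        B = np.asarray(B, dtype=float).reshape(len(self.categories), self.X.shape[1])
        eta = self.X @ B.T
        full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
        lse = np.logaddexp.reduce(full, axis=1)
        return float(np.sum(self.Y * eta) - np.sum(lse))

    def _information(self, P: np.ndarray) -> np.ndarray:
        X = self.X
        C, p = len(self.categories), X.shape[1]
        info = np.empty((C * p, C * p))
        for c in range(C):
            for d in range(c, C):
                w = P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
                block = X.T @ (X * w[:, None])
                info[c * p : (c + 1) * p, d * p : (d + 1) * p] = block
                info[d * p : (d + 1) * p, c * p : (c + 1) * p] = block.T
        return info

    def fit(self, tol: float = _TOL, max_iter: int = _MAX_ITER) -> MultinomialFit:
        X, Y = self.X, self.Y
        n, p = X.shape
        C = len(self.categories)
        B = np.zeros((C, p))
        ll = self.loglik(B)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            P = _softmax_with_baseline(X @ B.T)[:, 1:]
            g = (X.T @ (Y - P)).T.ravel()  # ordered category-major like B
            info = self._information(P)
            step = solve_psd(info, g).reshape(C, p)
            new_ll, lam = -np.inf, 1.0
            for _ in range(30):
                cand = B + lam * step
                new_ll = self.loglik(cand)
                if new_ll >= ll - 1e-12:
                    break
                lam /= 2.0
            improving = new_ll > ll
            B = B + lam * step
            if np.max(np.abs(B)) > _SEPARATION_BOUND and improving:
                c, j = np.unravel_index(int(np.argmax(np.abs(B))), B.shape)
                raise SeparationError(f"{self.term_names[j]} ({self.categories[c]})")
            if abs(new_ll - ll) <= tol * (abs(new_ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        P = _softmax_with_baseline(X @ B.T)[:, 1:]
        return MultinomialFit(
            params=B,
            cov_params=invert_information(self._information(P)),
            loglik=ll,
            n=n,
            reference=self.reference,
            categories=list(self.categories),
            converged=converged,
            iterations=it,
            term_names=list(self.term_names),
        )


def fit_multinomial(X, y3, reference: str = "none", **kwargs) -> MultinomialFit:
    """Functional wrapper: fit the baseline-category multinomial model."""
    return BaselineMultinomial(y3, X, reference=reference).fit(**kwargs)


def odds_ratios_multinomial(fit: MultinomialFit, level: float = 0.95) -> pd.DataFrame:
    return fit.odds_ratios(level)
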