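"""Cohort statistics: directional correlations, gated pairwise t-tests,
plain t-tests, OLS regression and Bonferroni control.

Correlations are one-tailed by default because the brain-behavior
hypotheses are directional (e.g. higher left-hemisphere modularity is
expected with *lower* behavior scores); the tail is always stated
explicitly through a ``direction`` argument rather than inferred from the
data.  Partial correlations use the residual method: x and y are each
regressed (OLS with intercept) on the covariates and the residuals are
correlated, with the t-transform on n - 2 - q degrees of freedom.

The pairwise co-membership test asks, for every pair of left-hemisphere
regions, whether subjects in whom the pair is *always* co-assigned
(affiliation entry = 1) score higher than subjects in whom it is not.  The
test is gated: a subject contributes to a pair only if both regions are
sufficiently preserved (damage fraction below 1 - preservation threshold),
the t-test runs only when both groups reach a minimum size, and Bonferroni
correction counts only the tests actually executed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .community import AffiliationResult
from .io import CohortData

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "RegressionSummary",
    "pearson_one_tailed",
    "pearson_two_tailed",
    "partial_correlation_one_tailed",
    "pairwise_module_ttests",
    "ttest_unpaired",
    "fit_ols",
    "bonferroni",
]

_DIRECTIONS = ("positive", "negative")

#: An affiliation entry counts as "always co-assigned" when it reaches 1;
#: entries are exact multiples of 1/n_runs so the tolerance only absorbs
#: float division noise.
_AFFILIATED_TOL = 1e-9


@dataclass(frozen=True)
class CorrelationResult:
    """A (possibly partial) Pearson correlation with a directional p-value."""

    r: float
    p: float
    n: int
    direction: str | None
    tails: int = 1
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit: per-predictor estimates/p-values, model F and adjusted R²."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, p)
    intercept: float
    F: float
    p_model: float
    R2: float
    adjusted_R2: float
    n: int


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("x and y must be 1-D")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return x, y


def _r_to_p(r: float, df: int, direction: str | None, tails: int) -> float:
    """p-value of r via the t-transform t = r * sqrt(df / (1 - r^2))."""
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({df})")
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    if tails == 2:
        return float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if not np.isfinite(t):
        aligned = (t > 0) == (direction == "positive")
        return 0.0 if aligned else 1.0
    if direction == "positive":
        return float(sps.t.sf(t, df))
    return float(sps.t.cdf(t, df))


def pearson_one_tailed(x, y, direction: str) -> CorrelationResult:
    """Pearson r with a one-tailed p in the stated a-priori direction."""
    x, y = _validate_xy(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    p = _r_to_p(r, x.shape[0] - 2, direction, tails=1)
    return CorrelationResult(r=r, p=p, n=x.shape[0], direction=direction, tails=1)


def pearson_two_tailed(x, y) -> CorrelationResult:
    x, y = _validate_xy(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    p = _r_to_p(r, x.shape[0] - 2, None, tails=2)
    return CorrelationResult(r=r, p=p, n=x.shape[0], direction=None, tails=2)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation_one_tailed(
    x,
    y,
    covariates,
    direction: str,
    tails: int = 1,
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Correlation of x and y after removing covariates from both.

    ``covariates`` is an (n, q) matrix (or 1-D for a single covariate); an
    empty covariate set reduces exactly to the plain Pearson test.
    """
    x, y = _validate_xy(x, y)
    n = x.shape[0]
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariate rows do not match x/y length")
    q = Z.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 (n={n}, q={q})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(), ry.std()
    scale = max(x.std(), 1.0) * 1e-12
    if sx <= scale or sy <= max(y.std(), 1.0) * 1e-12:
        raise ValueError("zero-variance residuals: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    p = _r_to_p(r, n - 2 - q, direction if tails == 1 else None, tails=tails)
    names = tuple(covariate_names) if covariate_names else tuple(
        f"cov{i}" for i in range(q)
    )
    return CorrelationResult(
        r=r, p=p, n=n, direction=direction if tails == 1 else None,
        tails=tails, covariates=names,
    )


def ttest_unpaired(
    x, y, tails: int = 2, direction: str | None = None, equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired t-test (pooled-variance Student by default; Welch optional).

    One-tailed with ``direction='positive'`` tests mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            raise ValueError("degenerate: zero variance and equal means")
        raise ValueError("degenerate: zero variance in both groups")
    if tails == 1:
        if direction not in _DIRECTIONS:
            raise ValueError(f"one-tailed test needs direction in {_DIRECTIONS}")
        alternative = "greater" if direction == "positive" else "less"
    else:
        alternative = "two-sided"
    t, p = sps.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    return float(t), float(p)


def bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """adjusted = min(1, p * m); significant iff adjusted <= alpha."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    adjusted = np.minimum(1.0, p * p.size)
    return adjusted, adjusted <= alpha


def _student_t_greater(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance one-tailed (mean(a) > mean(b)) t-test, fast path."""
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 <= 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf, 0.0) if a.mean() > b.mean() else (-np.inf, 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(t), float(sps.t.sf(t, df))


def pairwise_module_ttests(
    cohort: CohortData,
    affiliations: dict[str, AffiliationResult],
    score_name: str = "wab_aq",
    min_group: int = 5,
    preservation_threshold: float = 0.5,
    alpha: float = 0.05,
    preservation_scope: str = "subject",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per region pair: do always-co-assigned subjects score higher?

    ``affiliations`` maps subject_id to that subject's left-hemisphere
    AffiliationResult (all sharing one region order).  With the default
    ``preservation_scope='subject'`` a subject enters a pair's test only if
    both regions are at least ``preservation_threshold`` preserved *for that
    subject*; with ``'cohort'`` a pair is tested only when every subject
    preserves both regions.  Returns one row per pair; pairs failing the
    group-size gate carry ``skipped_reason='group_too_small'``.
    """
    if preservation_scope not in ("subject", "cohort"):
        raise ValueError("preservation_scope must be 'subject' or 'cohort'")
    scores = cohort.score_series(score_name)  # raises on unknown score
    sids = sorted(affiliations)
    missing = [s for s in sids if s not in scores.index]
    if missing:
        raise ValueError(f"subjects without scores: {missing[:3]}")
    first = affiliations[sids[0]]
    region_ids = first.region_ids
    n_regions = len(region_ids)
    for sid in sids:
        if affiliations[sid].region_ids != region_ids:
            raise ValueError("affiliation matrices do not share a region order")
    A = np.stack([affiliations[sid].A for sid in sids])
    y = scores.loc[sids].to_numpy(dtype=float)
    parc_index = {rid: i for i, rid in enumerate(cohort.parcellation.region_ids)}
    D = np.stack(
        [
            cohort.subject(sid).damage_vector(cohort.parcellation)
            for sid in sids
        ]
    )
    # damage per affiliation-region, aligned to the affiliation order
    dmg = np.stack([D[:, parc_index[rid]] for rid in region_ids], axis=1)
    preserved = dmg <= (1.0 - preservation_threshold)

    rows = []
    executed = []
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            if preservation_scope == "subject":
                eligible = preserved[:, i] & preserved[:, j]
            else:
                eligible = (
                    np.ones(len(sids), dtype=bool)
                    if preserved[:, i].all() and preserved[:, j].all()
                    else np.zeros(len(sids), dtype=bool)
                )
            aij = A[:, i, j]
            g1 = eligible & (aij >= 1.0 - _AFFILIATED_TOL)
            g2 = eligible & (aij < 1.0 - _AFFILIATED_TOL)
            n1, n2 = int(g1.sum()), int(g2.sum())
            row = {
                "region_i": region_ids[i],
                "region_j": region_ids[j],
                "n_affiliated": n1,
                "n_other": n2,
                "t": np.nan,
                "p_one_tailed": np.nan,
                "p_bonferroni": np.nan,
                "significant": False,
                "skipped_reason": "",
            }
            if n1 < min_group or n2 < min_group:
                row["skipped_reason"] = "group_too_small"
            else:
                if equal_var:
                    t, p = _student_t_greater(y[g1], y[g2])
                else:
                    t, p = ttest_unpaired(
                        y[g1], y[g2], tails=1, direction="positive",
                        equal_var=False,
                    )
                row["t"] = t
                row["p_one_tailed"] = p
                executed.append(len(rows))
            rows.append(row)
    df = pd.DataFrame(rows)
    if executed:
        adj, sig = bonferroni(
            df.loc[executed, "p_one_tailed"].to_numpy(), alpha=alpha
        )
        df.loc[executed, "p_bonferroni"] = adj
        df.loc[executed, "significant"] = sig
    logger.info(
        "pairwise co-membership tests: %d pairs, %d executed, %d significant "
        "(Bonferroni alpha=%g)",
        len(df), len(executed), int(df["significant"].sum()), alpha,
    )
    return df


def fit_ols(y, predictors: pd.DataFrame, response: str = "y") -> RegressionSummary:
    """OLS with intercept; per-coefficient t-tests, model F, adjusted R²."""
    X = pd.DataFrame(predictors)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match predictors")
    if n <= k + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={k})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    coefficients = {
        name: (float(fit.params[name]), float(fit.pvalues[name]))
        for name in X.columns
    }
    return RegressionSummary(
        response=response,
        predictors=tuple(X.columns),
        coefficients=coefficients,
        intercept=float(fit.params["const"]),
        F=float(fit.fvalue),
        p_model=float(fit.f_pvalue),
        R2=float(fit.rsquared),
        adjusted_R2=float(fit.rsquared_adj),
        n=n,
    )
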