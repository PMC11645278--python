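"""Evaluation metrics and inferential statistics for brain-age gaps.

Conventions
-----------
* Brain-age gap = predicted - chronological age; positive gaps mean the
  model sees an "older" brain.
* MDE (mean directional error) = mean(predicted - chronological), so a
  positive MDE indicates systematic overprediction.
* Group comparisons use subsample permutation tests: the observed statistic
  is the full-group mean difference; the null distribution is built by, at
  each iteration, subsampling the larger group to the smaller group's size
  and permuting group labels within the subsample. With equal group sizes
  this reduces to the standard two-sample permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ContractError, DegenerateInputError


@dataclass
class MetricsReport:
    mde: float
    rmse: float
    pearson_r: float
    r_squared: float
    p_value: float
    cohens_f2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mde": self.mde, "rmse": self.rmse, "pearson_r": self.pearson_r,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "cohens_f2": self.cohens_f2, "n": self.n,
        }


@dataclass
class PermutationResult:
    observed_stat: float
    p_value: float
    iterations: int
    n_a: int
    n_b: int
    seed: int
    two_sided: bool = True


def _pair(chronological, predicted):
    y = np.asarray(chronological, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ContractError("inputs must be equal-length and non-empty")
    return y, yhat


def mde(chronological, predicted) -> float:
    """Mean directional error: mean(predicted - chronological)."""
    y, yhat = _pair(chronological, predicted)
    return float(np.mean(yhat - y))


def rmse(chronological, predicted) -> float:
    """Root-mean-square prediction error."""
    y, yhat = _pair(chronological, predicted)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def cohens_f2(r_squared: float) -> float:
    """Cohen's effect size f^2 = R^2 / (1 - R^2)."""
    if not 0.0 <= r_squared < 1.0:
        raise ContractError("r_squared must lie in [0, 1)")
    return r_squared / (1.0 - r_squared)


def fit_ols_metrics(chronological, predicted) -> MetricsReport:
    """OLS of predicted on chronological age, plus MDE/r.m.s.e./f^2."""
    y, yhat = _pair(chronological, predicted)
    if y.size < 3:
        raise ContractError("need at least 3 observations")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise DegenerateInputError("constant input; regression undefined")
    model = sm.OLS(yhat, sm.add_constant(y)).fit()
    r2 = float(model.rsquared)
    r = float(np.corrcoef(y, yhat)[0, 1])
    return MetricsReport(
        mde=mde(y, yhat),
        rmse=rmse(y, yhat),
        pearson_r=r,
        r_squared=r2,
        p_value=float(model.f_pvalue),
        cohens_f2=cohens_f2(min(r2, 1.0 - 1e-15)),
        n=int(y.size),
    )


def permutation_subsample_test(
    group_a, group_b, iterations: int = 5000, seed: int = 0
) -> PermutationResult:
    """Two-sided subsample permutation test on a difference of means.

    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + iterations).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    if iterations < 1:
        raise ContractError("iterations must be >= 1")
    t_obs = float(a.mean() - b.mean())
    n = min(a.size, b.size)
    rng = np.random.default_rng(seed)

    if a.size == b.size:
        sub = np.broadcast_to(np.concatenate([a, b]), (iterations, 2 * n)).copy()
    else:
        sub = np.empty((iterations, 2 * n))
        big, small, big_first = (a, b, True) if a.size > b.size else (b, a, False)
        for it in range(iterations):
            pick = rng.choice(big.size, size=n, replace=False)
            sub[it, :n] = big[pick] if big_first else small
            sub[it, n:] = small if big_first else big[pick]
    rng.permuted(sub, axis=1, out=sub)
    t_perm = sub[:, :n].mean(axis=1) - sub[:, n:].mean(axis=1)
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    p = (1.0 + exceed) / (1.0 + iterations)
    return PermutationResult(
        observed_stat=t_obs, p_value=p, iterations=iterations,
        n_a=int(a.size), n_b=int(b.size), seed=seed,
    )


def chi_square_test(table, yates_for_2x2: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table (Yates for 2x2 by default)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ContractError("contingency table must be at least 2x2")
    if np.any(t < 0):
        raise ContractError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ContractError("zero marginal in contingency table")
    correction = yates_for_2x2 and t.shape == (2, 2)
    res = sps.chi2_contingency(t, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def one_way_anova_eta(groups) -> tuple[float, float, float]:
    """One-way ANOVA F, p and partial eta squared = SSb / (SSb + SSw)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ContractError("need >= 2 groups with >= 2 observations each")
    F, p = sps.f_oneway(*gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    eta = ss_between / (ss_between + ss_within) if ss_between + ss_within > 0 else 0.0
    return float(F), float(p), float(eta)


def covariate_adjust_gaps(gaps, covariates) -> np.ndarray:
    """Residualize gaps on covariates (OLS with intercept) + grand mean."""
    g = np.asarray(gaps, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != g.size:
        raise ContractError("covariates and gaps must align")
    if not np.all(np.isfinite(C)):
        raise ContractError("covariates must be complete (no missing values)")
    Xd = sm.add_constant(C)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise DegenerateInputError("collinear covariates")
    fit = sm.OLS(g, Xd).fit()
    return np.asarray(fit.resid) + g.mean()


def group_gap_table(frame: pd.DataFrame, by: str, gap_col: str = "gap") -> pd.DataFrame:
    """Mean gap (= per-group MDE), r.m.s.e.-style spread and n per group."""
    rows = []
    for key, sub in frame.groupby(by):
        g = sub[gap_col].to_numpy()
        rows.append({by: key, "mde": float(g.mean()),
                     "rmse": float(np.sqrt(np.mean(g**2))), "n": int(g.size)})
    return pd.DataFrame(rows)
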