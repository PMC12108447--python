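"""Outcome statistics: logistic regression, Kaplan-Meier and log-rank tests.

This is the analysis stage applied to the cohort: univariate and multiple
logistic regression with Wald intervals for clinical cure and 30-day
mortality, and a time-to-discharge analysis that excludes 30-day deaths and
censors hospital stays beyond a horizon (50 days by default).

The logistic fit is a plain Newton / iteratively-reweighted-least-squares
maximum-likelihood fit with Wald standard errors from the observed
information; regimen change enters as categorical contrasts against the
no-change reference (the increase-vs-decrease contrast is derived from the
two fitted ones).  The survival stage is the product-limit estimator and the
aggregated observed-minus-expected chi-square log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "Term",
    "RegressionResult",
    "SurvivalCurve",
    "LogRankResult",
    "ConvergenceError",
    "SingularDesignError",
    "fit_logistic",
    "fit_logistic_arrays",
    "tte_prepare",
    "km_estimate",
    "log_rank",
    "CURE_MODEL",
    "MORTALITY_MODEL",
    "UNIVARIATE_SCREEN",
    "study_tables",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """Likelihood maximisation failed (typically separation)."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class Term:
    """One model term: a continuous or binary column, or a categorical column
    expanded to indicator contrasts against ``reference``."""

    name: str
    kind: str = "continuous"  # continuous | binary | categorical
    reference: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    terms: tuple[Term, ...]


#: Default model specifications mirroring the study's multivariable models:
#: clinical cure on TDM timing and regimen change; 30-day mortality on SOFA,
#: RRT, age, intra-abdominal source and regimen change.
CURE_MODEL = ModelSpec(
    outcome="clinical_cure",
    terms=(
        Term("days_to_tdm", "continuous"),
        Term("change_group", "categorical", reference="no_change"),
    ),
)

MORTALITY_MODEL = ModelSpec(
    outcome="mortality_30d",
    terms=(
        Term("sofa", "continuous"),
        Term("rrt", "binary"),
        Term("age", "continuous"),
        Term("intra_abdominal", "binary"),
        Term("change_group", "categorical", reference="no_change"),
    ),
)


@dataclass(frozen=True)
class RegressionResult:
    """Per-predictor estimates plus convergence diagnostics."""

    table: pd.DataFrame  # index: predictor; columns: coef, se, or, ci_low, ci_high, p
    n_obs: int
    n_iter: int
    max_abs_gradient: float
    converged: bool
    log_likelihood: float

    def odds_ratio(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "or"])

    def coef(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "coef"])

    def contrast(self, a: str, b: str) -> tuple[float, float, float]:
        """Derived contrast a vs b: OR, using cov for the CI requires the full
        covariance; returns (or, ci_low, ci_high) from the stored covariance."""
        cov = self.table.attrs["cov"]
        names = list(self.table.index)
        ia, ib = names.index(a), names.index(b)
        diff = self.table.loc[a, "coef"] - self.table.loc[b, "coef"]
        var = cov[ia, ia] + cov[ib, ib] - 2 * cov[ia, ib]
        se = math.sqrt(var)
        return (math.exp(diff), math.exp(diff - Z_95 * se), math.exp(diff + Z_95 * se))


def _build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    missing = [t.name for t in spec.terms if t.name not in data.columns]
    if spec.outcome not in data.columns:
        missing.append(spec.outcome)
    if missing:
        raise KeyError(f"columns missing from episode data: {missing}")
    y = data[spec.outcome].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    for t in spec.terms:
        if t.kind == "categorical":
            levels = sorted(set(data[t.name].astype(str)))
            if t.reference not in levels:
                raise ValueError(
                    f"reference level {t.reference!r} absent from {t.name!r} "
                    f"levels {levels}"
                )
            for lev in levels:
                if lev == t.reference:
                    continue
                cols.append((data[t.name].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{t.name}[{lev}]")
        else:
            cols.append(data[t.name].to_numpy(dtype=float))
            names.append(t.name)
    return np.column_stack(cols), y, names


def fit_logistic_arrays(
    x: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RegressionResult:
    """Newton/IRLS maximum-likelihood logistic fit on a prepared design matrix.

    ``x`` must include its intercept column.  Raises
    :class:`SingularDesignError` for rank-deficient designs (naming the
    collinear columns) and :class:`ConvergenceError` when the score does not
    vanish within ``max_iter`` iterations (e.g. separation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic model undefined")
    # rank check via pivoted QR; report which columns are collinear
    q, r, piv = _qr_pivot(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum())
    if rank < p:
        bad = [names[j] for j in piv[rank:]]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )

    beta = np.zeros(p)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu)
        grad_norm = float(np.abs(grad).max())
        if grad_norm <= tol:
            break
        xtwx = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"information matrix singular at iteration {it} "
                f"(possible separation); |grad|={grad_norm:.3g}"
            ) from exc
        beta = beta + step
    converged = grad_norm <= tol
    if not converged or np.abs(beta).max() > 30:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(max |gradient| {grad_norm:.3g}, max |coef| {np.abs(beta).max():.3g}); "
            "check for separation or extreme covariate scaling"
        )

    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((x * w[:, None]).T @ x)
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "p": pval,
        },
        index=list(names),
    )
    table.attrs["cov"] = cov
    return RegressionResult(
        table=table,
        n_obs=n,
        n_iter=it,
        max_abs_gradient=grad_norm,
        converged=True,
        log_likelihood=ll,
    )


def _qr_pivot(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def fit_logistic(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> RegressionResult:
    """Fit a logistic model described by ``spec`` on episode-level data."""
    x, y, names = _build_design(data, spec)
    return fit_logistic_arrays(x, y, names, **kwargs)


#: Predictors screened univariately per outcome (the mortality screen also
#: carries the intra-abdominal source indicator).
UNIVARIATE_SCREEN: dict[str, tuple[Term, ...]] = {
    "clinical_cure": (
        Term("sofa", "continuous"), Term("rrt", "binary"),
        Term("age", "continuous"), Term("days_to_tdm", "continuous"),
        Term("scr_mg_dl", "continuous"),
    ),
    "mortality_30d": (
        Term("sofa", "continuous"), Term("rrt", "binary"),
        Term("age", "continuous"), Term("days_to_tdm", "continuous"),
        Term("scr_mg_dl", "continuous"), Term("intra_abdominal", "binary"),
    ),
}


def study_tables(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Univariate screen plus multivariable models for both outcomes.

    Returns one table per outcome in the reporting layout of the analysis:
    predictor, univariate OR (95% CI), adjusted OR (95% CI), p, including the
    derived increase-vs-decrease contrast of the regimen-change terms.
    """
    out: dict[str, pd.DataFrame] = {}
    for label, spec in (("clinical_cure", CURE_MODEL), ("mortality_30d", MORTALITY_MODEL)):
        rows = []
        for term in UNIVARIATE_SCREEN[label]:
            uni = fit_logistic(data, ModelSpec(label, (term,)))
            r = uni.table.loc[term.name]
            rows.append({
                "predictor": term.name,
                "uni_or": r["or"], "uni_ci_low": r["ci_low"],
                "uni_ci_high": r["ci_high"], "uni_p": r["p"],
                "adj_or": np.nan, "adj_ci_low": np.nan, "adj_ci_high": np.nan,
                "adj_p": np.nan,
            })
        adj = fit_logistic(data, spec)
        for name in adj.table.index:
            if name == "intercept":
                continue
            r = adj.table.loc[name]
            hit = [row for row in rows if row["predictor"] == name]
            row = hit[0] if hit else None
            if row is None:
                row = {"predictor": name, "uni_or": np.nan, "uni_ci_low": np.nan,
                       "uni_ci_high": np.nan, "uni_p": np.nan}
                rows.append(row)
            row.update({"adj_or": r["or"], "adj_ci_low": r["ci_low"],
                        "adj_ci_high": r["ci_high"], "adj_p": r["p"]})
        inc, dec = "change_group[increase]", "change_group[decrease]"
        if inc in adj.table.index and dec in adj.table.index:
            o, lo, hi = adj.contrast(inc, dec)
            rows.append({
                "predictor": "change_group[increase_vs_decrease]",
                "uni_or": np.nan, "uni_ci_low": np.nan, "uni_ci_high": np.nan,
                "uni_p": np.nan, "adj_or": o, "adj_ci_low": lo,
                "adj_ci_high": hi, "adj_p": np.nan,
            })
        out[label] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# Time-to-event stage


@dataclass(frozen=True)
class SurvivalCurve:
    group: str
    times: np.ndarray           # ordered distinct event times
    at_risk: np.ndarray         # number at risk just before each event time
    survival: np.ndarray        # S(t) just after each event time
    censor_times: np.ndarray    # times of censored observations


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[str, ...]


def tte_prepare(
    episodes: pd.DataFrame,
    horizon_days: float = 50.0,
    los_col: str = "los_days",
    mortality_col: str = "mortality_30d",
    group_col: str = "change_group",
) -> pd.DataFrame:
    """Survival records for time-to-discharge: 30-day deaths are excluded,
    stays beyond ``horizon_days`` are censored at the horizon."""
    survivors = episodes.loc[episodes[mortality_col].astype(bool) == False]  # noqa: E712
    if survivors[los_col].isna().any():
        bad = survivors.index[survivors[los_col].isna()].tolist()[:5]
        raise ValueError(f"length of stay missing for surviving episodes {bad}")
    time = np.minimum(survivors[los_col].to_numpy(dtype=float), horizon_days)
    event = survivors[los_col].to_numpy(dtype=float) <= horizon_days
    return pd.DataFrame(
        {"time": time, "event": event, "group": survivors[group_col].to_numpy()}
    )


def km_estimate(records: pd.DataFrame, group: str | None = None) -> SurvivalCurve:
    """Product-limit survival estimate with right censoring."""
    if group is not None:
        records = records.loc[records["group"] == group]
    if len(records) == 0:
        raise ValueError(f"no records for group {group!r}")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    event_times, deaths = np.unique(t[e], return_counts=True)
    t_sorted = np.sort(t)
    at_risk = len(t) - np.searchsorted(t_sorted, event_times, side="left")
    survival = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(
        group=str(group) if group is not None else "all",
        times=event_times,
        at_risk=at_risk,
        survival=survival,
        censor_times=np.sort(t[~e]),
    )


def log_rank(records: pd.DataFrame, groups: Sequence[str] | None = None) -> LogRankResult:
    """k-sample log-rank test over pooled event times (aggregated-increment
    handling of ties); chi-square on k-1 degrees of freedom."""
    if groups is None:
        groups = sorted(map(str, pd.unique(records["group"])))
    else:
        groups = [str(g) for g in groups]
        records = records.loc[records["group"].astype(str).isin(groups)]
    k = len(groups)
    if k < 2:
        raise ValueError(f"log-rank needs at least two groups, got {groups}")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    g = records["group"].astype(str).to_numpy()
    event_times = np.unique(t[e])
    m = len(event_times)
    # per-group at-risk and event counts at every pooled event time
    n_gt = np.empty((m, k))
    d_gt = np.zeros((m, k))
    for j, gr in enumerate(groups):
        tg = np.sort(t[g == gr])
        n_gt[:, j] = len(tg) - np.searchsorted(tg, event_times, side="left")
        tg_ev, counts = np.unique(t[(g == gr) & e], return_counts=True)
        d_gt[np.searchsorted(event_times, tg_ev), j] = counts
    n_tot = n_gt.sum(axis=1)
    d_tot = d_gt.sum(axis=1)
    ok = n_tot > 1
    n_gt, d_gt, n_tot, d_tot = n_gt[ok], d_gt[ok], n_tot[ok], d_tot[ok]
    expected = n_gt * (d_tot / n_tot)[:, None]
    o_minus_e = (d_gt - expected)[:, : k - 1].sum(axis=0)
    # hypergeometric covariance, aggregated over tied events
    factor = d_tot * (n_tot - d_tot) / (n_tot - 1) / n_tot**2
    n1 = n_gt[:, : k - 1]
    var = np.diag(np.einsum("m,ma->a", factor * n_tot, n1)) - np.einsum(
        "m,ma,mb->ab", factor, n1, n1
    )
    if np.allclose(var, 0):
        chi2 = 0.0
    else:
        chi2 = float(o_minus_e @ np.linalg.solve(var, o_minus_e))
        chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1)) if chi2 > 0 else 1.0
    return LogRankResult(statistic=chi2, df=k - 1, p_value=p, groups=tuple(groups))
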