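"""Method-agreement statistics: linear regression with assumption
diagnostics, and Bland-Altman analysis with 1.96-SD limits of agreement.

Conventions (documented because they are easy to get silently wrong):

* Differences are oriented test - reference (internal - phantom), so a
  positive bias means the internal calibration *over*-estimates the
  phantom-based value.
* Limits of agreement use the fixed 1.96 multiplier, not small-sample
  t-quantiles.
* Percent error is 100 * bias / mean(reference series).
* Heteroscedasticity is probed by regressing |differences| on the pairwise
  means and reporting the slope p-value.
* Diagnostics (Shapiro-Wilk, Cook's distance) are reported, never used to
  remove observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import AgreementError, IncompleteCohortError

LOA_MULTIPLIER = 1.96
INTERNAL_METHODS = ("AAdC", "AAdCM", "ACM")
REFERENCE_METHOD = "PHANTOM"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_p_value: float
    residuals: np.ndarray
    shapiro_p: float
    max_cooks_d: float
    slope_vs_unity_p: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "residuals"}
        return {k: float(v) for k, v in d.items()}


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    upper_limit: float
    lower_limit: float
    percent_error: float
    heteroscedasticity_p: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class AgreementReport:
    measure: str                     # "vbmd" or "stiffness"
    method_pair: tuple[str, str]     # (reference, test)
    regression: RegressionResult | None  # None when n < 3 (no diagnostics)
    bland_altman: BlandAltmanResult
    n: int

    def to_dict(self) -> dict:
        return {"measure": self.measure,
                "reference": self.method_pair[0], "test": self.method_pair[1],
                "n": self.n,
                "regression": None if self.regression is None
                else self.regression.to_dict(),
                "bland_altman": self.bland_altman.to_dict()}


def fit_regression(x, y) -> RegressionResult:
    """OLS of y on x with the standard assumption diagnostics."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if len(x) < 3:
        raise AgreementError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise AgreementError("constant x: regression is degenerate")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    resid = np.asarray(res.resid)
    # Shapiro-Wilk needs some residual spread; an exact fit is trivially normal
    exact = np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max())))
    if exact:
        shapiro_p = 1.0
        cooks_max = 0.0
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)
        cooks_max = float(np.nanmax(OLSInfluence(res).cooks_distance[0]))
    se_slope = float(res.bse[1])
    if exact:
        # zero residual variance: the slope is known without error
        unity_p = 1.0 if abs(slope - 1.0) <= 1e-9 * max(1.0, abs(slope)) else 0.0
    elif se_slope > 0:
        t_unity = (slope - 1.0) / se_slope
        unity_p = float(2 * stats.t.sf(abs(t_unity), df=res.df_resid))
    else:
        unity_p = 0.0 if slope != 1.0 else 1.0
    return RegressionResult(
        slope=float(slope), intercept=float(intercept),
        r_squared=float(res.rsquared), slope_p_value=float(res.pvalues[1]),
        residuals=resid, shapiro_p=shapiro_p, max_cooks_d=cooks_max,
        slope_vs_unity_p=unity_p)


def bland_altman(reference, test) -> BlandAltmanResult:
    """Bland-Altman agreement of ``test`` against ``reference``."""
    ref = np.asarray(reference, float)
    tst = np.asarray(test, float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    if len(ref) < 2:
        raise AgreementError("Bland-Altman needs n >= 2")
    d = tst - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    ref_mean = float(ref.mean())
    if ref_mean == 0.0:
        raise AgreementError("percent error undefined: reference mean is zero")
    means = (tst + ref) / 2.0
    if len(ref) >= 3 and np.ptp(means) > 0 and np.ptp(np.abs(d - 0)) >= 0:
        try:
            het = sm.OLS(np.abs(d), sm.add_constant(means)).fit()
            hp = float(het.pvalues[1])
        except Exception:
            hp = float("nan")
    else:
        hp = float("nan")
    return BlandAltmanResult(
        mean_difference=bias, sd_difference=sd,
        upper_limit=bias + LOA_MULTIPLIER * sd,
        lower_limit=bias - LOA_MULTIPLIER * sd,
        percent_error=100.0 * bias / ref_mean,
        heteroscedasticity_p=hp)


def limits_from_bias_and_upper(bias: float, upper: float) -> tuple[float, float]:
    """Reconstruct (sd, lower limit) from a reported bias and upper limit.

    By construction upper = bias + 1.96*sd and lower = bias - 1.96*sd, hence
    lower = 2*bias - upper.
    """
    sd = (upper - bias) / LOA_MULTIPLIER
    return sd, 2.0 * bias - upper


@dataclass
class CohortAgreement:
    """All agreement reports for one cohort run."""

    reports: list[AgreementReport]
    vbmd_stiffness: dict = field(default_factory=dict)  # method -> RegressionResult

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reports": [r.to_dict() for r in self.reports],
            "vbmd_stiffness_regressions": {
                m: r.to_dict() for m, r in self.vbmd_stiffness.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            row = {"measure": r.measure, "reference": r.method_pair[0],
                   "test": r.method_pair[1], "n": r.n}
            if r.regression is not None:
                row.update({f"reg_{k}": v
                            for k, v in r.regression.to_dict().items()})
            row.update({f"ba_{k}": v for k, v in r.bland_altman.to_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _pivot(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    piv = table.pivot(index="specimen_id", columns="method", values=value_col)
    if piv.isna().any().any():
        missing = piv[piv.isna().any(axis=1)].index.tolist()
        raise IncompleteCohortError(f"missing (specimen, method) cells: {missing}")
    return piv


def cohort_agreement(vbmd_table: pd.DataFrame,
                     stiffness_table: pd.DataFrame | None = None,
                     internal_methods=INTERNAL_METHODS,
                     reference: str = REFERENCE_METHOD) -> CohortAgreement:
    """Agreement reports for every internal method against the phantom
    reference, for vBMD and (if provided) stiffness, plus the per-method
    vBMD-vs-stiffness regressions.

    Tables need columns ``specimen_id``, ``method`` and ``vbmd`` /
    ``stiffness_mpa`` respectively.
    """
    reports: list[AgreementReport] = []
    vb = _pivot(vbmd_table, "vbmd")
    tables = {"vbmd": vb}
    if stiffness_table is not None:
        st = _pivot(stiffness_table, "stiffness_mpa")
        if not st.index.equals(vb.index):
            st = st.reindex(vb.index)
            if st.isna().any().any():
                raise IncompleteCohortError("vBMD and stiffness cohorts differ")
        tables["stiffness"] = st
    for measure, piv in tables.items():
        for method in internal_methods:
            if method not in piv.columns or reference not in piv.columns:
                raise IncompleteCohortError(
                    f"method '{method}' or '{reference}' missing from {measure} table")
            reg = (fit_regression(piv[reference], piv[method])
                   if len(piv) >= 3 else None)
            reports.append(AgreementReport(
                measure=measure, method_pair=(reference, method),
                regression=reg,
                bland_altman=bland_altman(piv[reference], piv[method]),
                n=len(piv)))
    vbmd_stiffness = {}
    if stiffness_table is not None and len(vb) >= 3:
        st = tables["stiffness"]
        for method in (*internal_methods, reference):
            if method in vb.columns and method in st.columns:
                vbmd_stiffness[method] = fit_regression(vb[method], st[method])
    return CohortAgreement(reports, vbmd_stiffness)


# ---------------------------------------------------------------------------
# plots (optional outputs)

def plot_bland_altman(result: BlandAltmanResult, reference, test,
                      path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, float)
    tst = np.asarray(test, float)
    means = (ref + tst) / 2
    diffs = tst - ref
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18)
    ax.axhline(result.mean_difference, color="k")
    for lim in (result.upper_limit, result.lower_limit):
        ax.axhline(lim, color="k", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("test - reference")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_regression(x, y, result: RegressionResult, path: str | Path,
                    title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, "k-")
    ax.set_title(f"{title}  R^2={result.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
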