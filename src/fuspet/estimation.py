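"""Tissue-model fitting, AIC model comparison and cohort statistics.

Each region's TAC is fitted by weighted nonlinear least squares with the
subject's frozen plasma input function.  The prediction compared with an
observed frame value is the frame-averaged model signal.  Model order
(one- vs two-tissue) is selected by the least-squares AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PlasmaParams, TimeActivityCurve, TissueParams
from .fitting import (
    FitResult,
    aic_least_squares,
    frame_weights,
    multistart_least_squares,
    standard_errors_from_jacobian,
)
from .tissue import frame_averaged_total

__all__ = [
    "TISSUE_BOUNDS",
    "fit_tissue",
    "compare_models",
    "summarize_cohort",
    "group_compare",
    "plasma_param_ttest",
]

#: Default fitting box: roughly one order of magnitude around typical
#: estimates for IgG after ultrasound-aided delivery.
TISSUE_BOUNDS = {
    "K_FUS": (0.0, 2.0),  # mL/h/g
    "t_FUS": (0.0, 1.0),  # h
    "K1": (0.0, 2.0),  # mL/h/g
    "k2": (0.0, 5.0),  # 1/h
    "vB": (0.0, 0.2),
    "k3": (0.0, 5.0),  # 1/h
    "k4": (0.0, 1.0),  # 1/h
}

_M1_PARAMS = ("K_FUS", "t_FUS", "K1", "k2", "vB")
_M2_PARAMS = _M1_PARAMS + ("k3", "k4")
_HEURISTIC_START = {
    "K_FUS": 0.15,
    "t_FUS": 0.15,
    "K1": 0.05,
    "k2": 0.5,
    "vB": 0.06,
    "k3": 0.05,
    "k4": 0.01,
}


def _param_names(model: str, fus_window: bool) -> tuple[str, ...]:
    if model == "m1tcm":
        names = _M1_PARAMS
    elif model == "m2tcm":
        names = _M2_PARAMS
    else:
        raise ValueError(f"model must be 'm1tcm' or 'm2tcm', got {model!r}")
    if not fus_window:
        names = tuple(n for n in names if n not in ("K_FUS", "t_FUS"))
    return names


def _to_tissue_params(names, x, fus_window: bool) -> TissueParams:
    d = dict(zip(names, x))
    if not fus_window:
        d.setdefault("K_FUS", d.get("K1", 0.0))
        d.setdefault("t_FUS", 0.0)
    d.setdefault("k3", 0.0)
    d.setdefault("k4", 0.0)
    return TissueParams(**d)


def fit_tissue(
    tac: TimeActivityCurve,
    plasma: PlasmaParams,
    model: str = "m2tcm",
    dose: float = 100.0,
    weighting: str = "auto",
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 32,
    seed: int = 0,
    fus_window: bool = True,
) -> FitResult:
    """Fit the modified 1- or 2-tissue model to one regional TAC.

    ``plasma`` must come from the same subject's blood fit and is held
    fixed.  ``dose = 100`` keeps everything in %ID units.  Multistart is
    seeded; the best converged start by weighted SSR is returned.  With
    ``fus_window=False`` (sham animals) K_FUS and t_FUS are dropped from
    the parameter vector.  The default weighting is inverse-variance
    when the TAC reports per-frame SDs, frame-duration otherwise.
    """
    names = _param_names(model, fus_window)
    box = dict(TISSUE_BOUNDS)
    if bounds:
        box.update(bounds)
    lb = np.array([box[n][0] for n in names])
    ub = np.array([box[n][1] for n in names])

    obs = tac.value
    sched = tac.schedule
    w = frame_weights(sched, weighting, sd=tac.sd)
    sqw = np.sqrt(w)

    def residual(x):
        tp = _to_tissue_params(names, x, fus_window)
        pred = frame_averaged_total(plasma, dose, tp, sched, window=fus_window)
        return sqw * (pred - obs)

    first = np.array([_HEURISTIC_START[n] for n in names])
    best, n_used = multistart_least_squares(residual, lb, ub, n_starts, seed, first_start=first)

    n = len(obs)
    if best is None:
        nan = {k: np.nan for k in names}
        return FitResult(
            model=model,
            estimates=nan,
            standard_errors=nan,
            aic=np.nan,
            residuals=np.full(n, np.nan),
            weighted_ssr=np.nan,
            converged=False,
            n_starts_used=n_used,
            n_obs=n,
            flags=("all_starts_failed",),
        )

    est = dict(zip(names, best.x))
    tp = _to_tissue_params(names, best.x, fus_window)
    pred = frame_averaged_total(plasma, dose, tp, sched, window=fus_window)
    wssr = float(2 * best.cost)
    se = standard_errors_from_jacobian(best.jac, wssr, n)

    flags: list[str] = []
    if fus_window:
        if abs(est["t_FUS"] - box["t_FUS"][1]) < 1e-6:
            flags.append("t_fus_at_upper_bound")
        n_in_window = int(np.sum(sched.mid <= est["t_FUS"]))
        if n_in_window < 3:
            flags.append("t_fus_poorly_constrained")
    for nm in ("K_FUS", "K1"):
        if nm in est and abs(est[nm] - box[nm][0]) < 1e-6:
            flags.append(f"{nm}_at_lower_bound")

    return FitResult(
        model=model,
        estimates=est,
        standard_errors=dict(zip(names, se)),
        aic=aic_least_squares(n, wssr, len(names)),
        residuals=pred - obs,
        weighted_ssr=wssr,
        converged=bool(best.status > 0),
        n_starts_used=n_used,
        n_obs=n,
        flags=tuple(flags),
        predicted=pred,
    )


@dataclass(frozen=True)
class ModelSelection:
    selected: str
    delta_aic: float  # AIC(m2tcm) - AIC(m1tcm)
    aic: dict[str, float]


def compare_models(fit_m1: FitResult, fit_m2: FitResult) -> ModelSelection:
    """Select between nested tissue models by AIC (lower wins).

    Both fits must be on identical data and weights; only the difference
    in AIC is meaningful given the dropped likelihood constant.
    """
    if fit_m1.n_obs != fit_m2.n_obs:
        raise ValueError("fits compare different data (frame counts differ)")
    delta = fit_m2.aic - fit_m1.aic
    selected = "m2tcm" if delta < 0 else "m1tcm"
    return ModelSelection(
        selected=selected,
        delta_aic=float(delta),
        aic={"m1tcm": float(fit_m1.aic), "m2tcm": float(fit_m2.aic)},
    )


def summarize_cohort(fits: dict[tuple[str, str], list[FitResult]]) -> pd.DataFrame:
    """Per-group mean/SD/n of estimated parameters.

    ``fits`` maps (format, region) to the subjects' fit results.  Returns
    a long-format table (format, region, parameter, mean, sd, n) shaped
    like a cohort parameter-estimate table.
    """
    rows = []
    for (fmt, region), group in fits.items():
        if len(group) == 0:
            raise ValueError(f"empty group {(fmt, region)}")
        params = sorted({p for f in group for p in f.estimates})
        for p in params:
            vals = np.array([f.estimates[p] for f in group if p in f.estimates])
            rows.append(
                {
                    "format": fmt,
                    "region": region,
                    "parameter": p,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def group_compare(values: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-factor ANOVA (format x region) with Bonferroni pairwise tests.

    ``values`` needs columns 'value', 'format', 'region'; each cell (one
    parameter, one group) should hold >= 2 observations.  Returns the
    ANOVA table plus Bonferroni-adjusted pairwise comparisons of formats
    within each region.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"value", "format", "region"}
    if not required <= set(values.columns):
        raise ValueError(f"values needs columns {sorted(required)}")
    flagged = []
    for (fmt, region), grp in values.groupby(["format", "region"]):
        if len(grp) >= 2 and float(np.var(grp["value"])) == 0.0:
            flagged.append((fmt, region, "zero_within_group_variance"))

    terms = []
    if values["format"].nunique() > 1:
        terms.append("C(format)")
    if values["region"].nunique() > 1:
        terms.append("C(region)")
    if len(terms) == 2:
        formula = "value ~ C(format) * C(region)"
    elif terms:
        formula = f"value ~ {terms[0]}"
    else:
        raise ValueError("need at least two groups to compare")
    model = smf.ols(formula, data=values).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    pairs = []
    regions = sorted(values["region"].unique())
    fmts = sorted(values["format"].unique())
    comparisons = []
    for region in regions:
        for i in range(len(fmts)):
            for j in range(i + 1, len(fmts)):
                in_region = values["region"] == region
                a = values.loc[in_region & (values["format"] == fmts[i]), "value"]
                b = values.loc[in_region & (values["format"] == fmts[j]), "value"]
                if len(a) < 2 or len(b) < 2:
                    continue
                t, p = stats.ttest_ind(a, b, equal_var=False)
                comparisons.append((region, fmts[i], fmts[j], float(t), float(p)))
    m = max(len(comparisons), 1)
    for region, f1, f2, t, p in comparisons:
        pairs.append(
            {
                "region": region,
                "format_a": f1,
                "format_b": f2,
                "t": t,
                "p_raw": p,
                "p_adjusted": min(p * m, 1.0),
                "significant": min(p * m, 1.0) < alpha,
            }
        )
    return {"anova": anova, "pairwise": pd.DataFrame(pairs), "flags": flagged}


def plasma_param_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test used for plasma-parameter group comparisons."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)
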