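"""Synthetic cohort generation and the parameter-recovery harness.

Emulates the study design end to end: subjects' plasma and tissue
parameters scatter lognormally around the reference cohort means/SDs,
blood and regional TACs are computed from the forward models on the
acquisition schedule (24 dynamic frames over the first hour, then five
20-min static scans out to one week), frame-averaged, and degraded with
PET-count-like heteroscedastic noise.

The recovery harness closes the loop: generate a cohort, fit it with the
estimation pipeline, and report per-parameter bias — the package's
principal validation surface, since no animal data ship with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .data_model import (
    BLOOD_TO_PLASMA_RATIO,
    FrameSchedule,
    PlasmaParams,
    SubjectDataset,
    TimeActivityCurve,
    TissueParams,
)
from .estimation import compare_models, fit_tissue
from .fitting import FitResult
from .plasma import fit_plasma, plasma_concentration
from .tissue import _gl_average, frame_averaged_total

__all__ = [
    "CohortSpec",
    "RecoveryReport",
    "default_schedule",
    "generate_subject",
    "generate_cohort",
    "recovery_experiment",
    "model_selection_experiment",
]

#: Dynamic frame durations in seconds (sum exactly 3600 s = 24 frames),
#: followed by 20-min static scans centred at 5, 22, 46, 70 and 168 h.
DYNAMIC_FRAME_SECONDS = [30] * 3 + [60] * 5 + [120] * 5 + [180] * 3 + [240] * 3 + [300] * 4 + [150]
STATIC_CENTERS_H = (5.0, 22.0, 46.0, 70.0, 168.0)
STATIC_DURATION_H = 20.0 / 60.0


def default_schedule() -> FrameSchedule:
    """The acquisition schedule: 24 dynamic + 5 static frames."""
    edges = np.concatenate([[0.0], np.cumsum(DYNAMIC_FRAME_SECONDS) / 3600.0])
    starts = list(edges[:-1])
    ends = list(edges[1:])
    for c in STATIC_CENTERS_H:
        starts.append(c - STATIC_DURATION_H / 2)
        ends.append(c + STATIC_DURATION_H / 2)
    return FrameSchedule(starts, ends)


@dataclass(frozen=True)
class CohortSpec:
    """Generating distribution for one synthetic cohort arm."""

    n_subjects: int
    format: str
    fus_applied: bool
    plasma_mean: PlasmaParams
    plasma_sd: dict[str, float]
    tissue_mean: dict[str, TissueParams]
    tissue_sd: dict[str, dict[str, float]]
    noise_scale: float = 0.05
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=default_schedule)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for sd in self.plasma_sd.values():
            if sd < 0:
                raise ValueError("SDs must be >= 0")

    @classmethod
    def from_reference(
        cls,
        fmt: str,
        regions: tuple[str, ...] = reference.REGIONS,
        n_subjects: int = 8,
        fus_applied: bool = True,
        noise_scale: float = 0.05,
        seed: int = 0,
        zero_variation: bool = False,
    ) -> "CohortSpec":
        """Cohort spec preloaded with the reference cohort means/SDs."""
        plasma_sd = reference.plasma_sds(fmt)
        tissue_mean = {r: reference.tissue_means(fmt, r) for r in regions}
        tissue_sd = {r: reference.tissue_sds(fmt, r) for r in regions}
        if zero_variation:
            plasma_sd = {k: 0.0 for k in plasma_sd}
            tissue_sd = {r: {k: 0.0 for k in d} for r, d in tissue_sd.items()}
        return cls(
            n_subjects=n_subjects,
            format=fmt,
            fus_applied=fus_applied,
            plasma_mean=reference.plasma_means(fmt),
            plasma_sd=plasma_sd,
            tissue_mean=tissue_mean,
            tissue_sd=tissue_sd,
            noise_scale=noise_scale,
            seed=seed,
        )


def lognormal_moment_matched(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a lognormal with the given arithmetic mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2, so positive
    support is guaranteed without truncation.  mean = 0 or sd = 0 return
    the mean deterministically.
    """
    if mean <= 0 or sd == 0:
        return float(mean)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2
    return float(rng.lognormal(mu, np.sqrt(s2)))


def _draw_plasma(rng, spec: CohortSpec) -> PlasmaParams:
    m = spec.plasma_mean
    sd = spec.plasma_sd
    return PlasmaParams(
        Vc=lognormal_moment_matched(rng, m.Vc, sd.get("Vc", 0.0)),
        k10=lognormal_moment_matched(rng, m.k10, sd.get("k10", 0.0)),
        k12=lognormal_moment_matched(rng, m.k12, sd.get("k12", 0.0)),
        k21=lognormal_moment_matched(rng, m.k21, sd.get("k21", 0.0)),
    )


def _draw_tissue(rng, mean: TissueParams, sd: dict[str, float]) -> TissueParams:
    return TissueParams(
        **{
            name: lognormal_moment_matched(rng, getattr(mean, name), sd.get(name, 0.0))
            for name in ("K_FUS", "t_FUS", "K1", "k2", "vB", "k3", "k4")
        }
    )


def _add_noise(rng, values: np.ndarray, schedule: FrameSchedule, noise_scale: float):
    """Zero-mean Gaussian noise with SD = scale * sqrt(value/duration)
    (Poisson-count heritage), floored at zero; returns (noisy, sd, n_floored)."""
    sd = noise_scale * np.sqrt(np.clip(values, 0, None) / schedule.duration)
    noisy = values + rng.normal(0.0, 1.0, size=len(values)) * sd
    n_floored = int(np.sum(noisy < 0))
    return np.clip(noisy, 0.0, None), sd, n_floored


def generate_subject(spec: CohortSpec, subject_index: int) -> SubjectDataset:
    """Draw one subject's parameters and simulate its blood + regional TACs.

    Deterministic given (spec.seed, subject_index).  Sham cohorts
    (fus_applied=False) are simulated with the entry window disabled:
    the influx clearance is K1 from t = 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, subject_index)))
    plasma = _draw_plasma(rng, spec)
    sched = spec.schedule
    dose = 100.0  # %ID units

    def plasma_at(tt):
        return plasma_concentration(plasma, dose, np.asarray(tt))

    blood_clean = BLOOD_TO_PLASMA_RATIO * _gl_average(plasma_at, sched.start, sched.end)
    blood_vals, blood_sd, n_floor = _add_noise(rng, blood_clean, sched, spec.noise_scale)
    blood_tac = TimeActivityCurve("blood", sched, blood_vals, blood_sd)

    region_tacs = {}
    tissue_truth = {}
    n_total = len(sched)
    for region, mean in spec.tissue_mean.items():
        tp = _draw_tissue(rng, mean, spec.tissue_sd.get(region, {}))
        tissue_truth[region] = tp
        clean = frame_averaged_total(plasma, dose, tp, sched, window=spec.fus_applied)
        vals, sd, nf = _add_noise(rng, clean, sched, spec.noise_scale)
        n_floor += nf
        n_total += len(sched)
        region_tacs[region] = TimeActivityCurve(region, sched, vals, sd)

    return SubjectDataset(
        subject_id=f"{spec.format}-{'fus' if spec.fus_applied else 'sham'}-{subject_index:02d}",
        dosing=reference.reference_dosing(spec.format),
        fus_applied=spec.fus_applied,
        blood_tac=blood_tac,
        region_tacs=region_tacs,
        true_params={
            "plasma": plasma,
            "tissue": tissue_truth,
            "flooring_rate": n_floor / n_total,
        },
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectDataset]:
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


_TISSUE_NAMES = ("K_FUS", "t_FUS", "K1", "k2", "vB", "k3", "k4")


@dataclass(frozen=True)
class RecoveryReport:
    """Per-subject truth vs estimate table with summary accessors."""

    records: pd.DataFrame  # subject, region, parameter, truth, estimate, rel_error
    n_failed: int
    fits: dict = field(default_factory=dict, compare=False, repr=False)

    def summary(self) -> pd.DataFrame:
        """Per (region, parameter): truth/estimate means, median relative
        bias, RMSE, over the subjects that converged."""
        def agg(grp):
            return pd.Series(
                {
                    "truth_mean": grp["truth"].mean(),
                    "estimate_mean": grp["estimate"].mean(),
                    "median_rel_bias": grp["rel_error"].median(),
                    "rmse": float(np.sqrt(np.mean((grp["estimate"] - grp["truth"]) ** 2))),
                    "n": len(grp),
                }
            )

        return (
            self.records.groupby(["region", "parameter"])[["truth", "estimate", "rel_error"]]
            .apply(agg)
            .reset_index()
        )


def recovery_experiment(
    spec: CohortSpec,
    model: str = "m2tcm",
    regions: tuple[str, ...] | None = None,
    n_starts: int = 8,
    plasma_n_starts: int = 8,
) -> RecoveryReport:
    """Generate a cohort, run the full fitting pipeline, report recovery.

    Per subject: fit the plasma model to the (noisy) blood curve, freeze
    it, fit the requested tissue model per region, and compare estimates
    with that subject's own generating parameters.  Relative error is
    (estimate - truth)/truth, NaN where the truth is zero.
    """
    if regions is None:
        regions = tuple(spec.tissue_mean)
    rows = []
    n_failed = 0
    fits: dict[tuple[int, str], FitResult] = {}
    for i, subject in enumerate(generate_cohort(spec)):
        plasma_hat, plasma_fit = fit_plasma(
            subject.blood_tac, n_starts=plasma_n_starts, seed=spec.seed + 1000 + i
        )
        if not np.isfinite(plasma_fit.aic):
            n_failed += 1
            continue
        truth_tissue = subject.true_params["tissue"]
        for region in regions:
            fit = fit_tissue(
                subject.region_tacs[region],
                plasma_hat,
                model=model,
                n_starts=n_starts,
                seed=spec.seed + 2000 + i,
                fus_window=subject.fus_applied,
            )
            fits[(i, region)] = fit
            if not fit.converged and "all_starts_failed" in fit.flags:
                n_failed += 1
                continue
            truth = truth_tissue[region]
            for name in _TISSUE_NAMES:
                if name not in fit.estimates:
                    continue
                tv = getattr(truth, name)
                ev = fit.estimates[name]
                rows.append(
                    {
                        "subject": i,
                        "region": region,
                        "parameter": name,
                        "truth": tv,
                        "estimate": ev,
                        "rel_error": (ev - tv) / tv if tv != 0 else np.nan,
                    }
                )
    return RecoveryReport(records=pd.DataFrame(rows), n_failed=n_failed, fits=fits)


def model_selection_experiment(
    fmt: str,
    region: str,
    generating_model: str,
    n_replicates: int = 50,
    noise_scale: float = 0.05,
    seed: int = 0,
    n_starts: int = 8,
) -> pd.DataFrame:
    """Repeatedly generate one subject at the reference means (no
    between-subject variation) and let AIC pick the tissue model.

    ``generating_model`` 'm1tcm' zeroes k3/k4 in the generating truth.
    Returns one row per replicate with both AICs and the selected model.
    """
    rows = []
    for r in range(n_replicates):
        spec = CohortSpec.from_reference(
            fmt,
            regions=(region,),
            n_subjects=1,
            noise_scale=noise_scale,
            seed=seed + r,
            zero_variation=True,
        )
        if generating_model == "m1tcm":
            tm = spec.tissue_mean[region]
            spec = replace(spec, tissue_mean={region: replace(tm, k3=0.0, k4=0.0)})
        subject = generate_subject(spec, 0)
        plasma_hat, _ = fit_plasma(subject.blood_tac, n_starts=n_starts, seed=seed + 5000 + r)
        tac = subject.region_tacs[region]
        fit1 = fit_tissue(tac, plasma_hat, model="m1tcm", n_starts=n_starts, seed=seed + 100 + r)
        fit2 = fit_tissue(tac, plasma_hat, model="m2tcm", n_starts=n_starts, seed=seed + 200 + r)
        sel = compare_models(fit1, fit2)
        rows.append(
            {
                "replicate": r,
                "aic_m1": sel.aic["m1tcm"],
                "aic_m2": sel.aic["m2tcm"],
                "selected": sel.selected,
            }
        )
    return pd.DataFrame(rows)
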