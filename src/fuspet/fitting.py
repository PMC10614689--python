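"""Shared least-squares machinery: weights, multistart, AIC, fit results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .data_model import FrameSchedule

__all__ = ["FitResult", "aic_least_squares", "frame_weights", "multistart_least_squares"]


def aic_least_squares(n: int, weighted_ssr: float, n_params: int) -> float:
    """AIC in its least-squares form, n*ln(wSSR/n) + 2p.

    The additive likelihood constant is dropped, so only differences
    between models fitted to the same data/weights are meaningful.
    """
    if weighted_ssr <= 0:
        weighted_ssr = np.finfo(float).tiny
    return n * np.log(weighted_ssr / n) + 2 * n_params


def frame_weights(
    schedule: FrameSchedule,
    scheme: str = "duration",
    sd: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame weights, normalised to mean 1.

    'duration' weights each frame by its length (longer frames average
    more counts, hence lower variance); the five late static scans share
    one duration so they are equally weighted among themselves.
    'uniform' weights every frame equally.  'ivar' is inverse-variance
    weighting from the curve's reported per-frame SDs (the efficient
    weighted-least-squares choice when measurement SDs are known); SDs
    are floored at half the 10th percentile so a lucky near-zero SD
    cannot dominate the fit.  'auto' resolves to 'ivar' when SDs are
    available and 'duration' otherwise.
    """
    if scheme == "auto":
        scheme = "ivar" if sd is not None else "duration"
    if scheme == "duration":
        w = schedule.duration.copy()
    elif scheme == "uniform":
        w = np.ones(len(schedule))
    elif scheme == "ivar":
        if sd is None:
            raise ValueError("'ivar' weighting needs per-frame SDs")
        floor = 0.5 * np.percentile(sd[sd > 0], 10) if np.any(sd > 0) else 1.0
        w = 1.0 / np.clip(sd, floor, None) ** 2
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return w / w.mean()


@dataclass(frozen=True)
class FitResult:
    """Outcome of one weighted least-squares fit."""

    model: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    aic: float
    residuals: np.ndarray  # unweighted, predicted - observed, per frame
    weighted_ssr: float
    converged: bool
    n_starts_used: int
    n_obs: int
    flags: tuple[str, ...] = ()
    predicted: np.ndarray | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "aic": float(self.aic),
            "residuals": [float(r) for r in self.residuals],
            "weighted_ssr": float(self.weighted_ssr),
            "converged": bool(self.converged),
            "n_starts_used": int(self.n_starts_used),
            "n_obs": int(self.n_obs),
            "flags": list(self.flags),
            "predicted": None if self.predicted is None else [float(p) for p in self.predicted],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=d["model"],
            estimates=dict(d["estimates"]),
            standard_errors=dict(d["standard_errors"]),
            aic=d["aic"],
            residuals=np.asarray(d["residuals"], dtype=float),
            weighted_ssr=d["weighted_ssr"],
            converged=d["converged"],
            n_starts_used=d["n_starts_used"],
            n_obs=d["n_obs"],
            flags=tuple(d.get("flags", ())),
            predicted=None if d.get("predicted") is None else np.asarray(d["predicted"], dtype=float),
        )


def _draw_starts(rng, lb, ub, n_starts):
    """Log-uniform starts inside the box (linear-uniform where lb is 0)."""
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    lo = np.where(lb > 0, lb, ub * 1e-3)
    starts = np.exp(rng.uniform(np.log(lo), np.log(ub), size=(n_starts, len(ub))))
    return np.clip(starts, lb + 1e-12, ub - 1e-12)


def multistart_least_squares(
    residual,
    lb,
    ub,
    n_starts: int,
    seed: int,
    first_start=None,
    **ls_kwargs,
):
    """Run scipy least_squares from several seeded starts, keep the best.

    Returns (best OptimizeResult or None, number of starts attempted).
    With identical data and parameter count, lowest weighted SSR is the
    same ordering as lowest AIC.
    """
    rng = np.random.default_rng(seed)
    n_random = n_starts - (1 if first_start is not None else 0)
    starts = _draw_starts(rng, lb, ub, max(n_random, 0))
    if first_start is not None:
        first = np.clip(np.asarray(first_start, float), lb + 1e-12, ub - 1e-12)
        starts = np.vstack([first[None, :], starts]) if len(starts) else first[None, :]
    best = None
    defaults = dict(method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=400)
    defaults.update(ls_kwargs)
    for x0 in starts[:n_starts]:
        try:
            res = least_squares(residual, x0, bounds=(lb, ub), **defaults)
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best, len(starts[:n_starts])


def standard_errors_from_jacobian(jac: np.ndarray, weighted_ssr: float, n: int) -> np.ndarray:
    """Asymptotic SEs from the local (weighted) Jacobian at the optimum."""
    p = jac.shape[1]
    dof = max(n - p, 1)
    s2 = weighted_ssr / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se
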