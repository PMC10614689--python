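"""Tissue compartment models with a transient ultrasound-opened entry window.

Focused ultrasound with microbubbles transiently permeabilises the
blood-brain barrier.  The entry clearance from plasma into the free /
non-specifically bound tissue compartment is therefore piecewise in time:
K_FUS while the barrier is open (t <= t_FUS) and K1 after it reseals
(piecewise replacement, not an additive bonus on K1).  Efflux k2 and, for
tumour regions, the exchange k3/k4 with the specifically (PD-L1-) bound
compartment are constant.

Two independent solution routes are provided:

* numeric: stiff-capable adaptive ODE integration with a hard restart at
  t_FUS so the discontinuous right-hand side is handled exactly
  (``simulate_m1tcm`` / ``simulate_m2tcm``);
* analytic: exact piecewise convolution of the biexponential plasma input
  with the tissue impulse response (``analytic_m1tcm`` for the one-tissue
  model, ``analytic_tissue_curve`` for both orders via eigendecomposition
  of the 2x2 tissue rate matrix).

The modeled PET signal is c_total = (1 - vB)(c_free + c_spec) + c_vasc
with c_vasc = vB x whole blood = vB x 0.55 x C_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .data_model import BLOOD_TO_PLASMA_RATIO, FrameSchedule, PlasmaParams, TissueParams
from .plasma import biexp_coefficients, plasma_concentration

__all__ = [
    "TissueSimulation",
    "influx_rate",
    "simulate_m1tcm",
    "simulate_m2tcm",
    "analytic_m1tcm",
    "analytic_tissue_curve",
    "frame_averaged_total",
]

_NEG_TOL = 1e-8


@dataclass(frozen=True)
class TissueSimulation:
    """Simulated tissue curves on a time grid (concentration units follow dose)."""

    time: np.ndarray
    c_free: np.ndarray
    c_spec: np.ndarray
    c_vasc: np.ndarray
    c_total: np.ndarray

    def signal(self, include_vascular: bool = False) -> np.ndarray:
        """Tissue PET signal: non-specific + specific, optionally + vascular."""
        if include_vascular:
            return self.c_total
        return self.c_free + self.c_spec


def influx_rate(t, params: TissueParams, window: bool = True):
    """Plasma->tissue entry clearance [mL/h/g] at time(s) t.

    K_FUS while the barrier is open (t <= t_FUS), K1 afterwards.  With
    ``window=False`` (sham: no ultrasound emitted) the open phase never
    exists and the rate is K1 throughout.
    """
    t = np.asarray(t, dtype=float)
    if not window:
        return np.full_like(t, params.K1)
    return np.where(t <= params.t_FUS, params.K_FUS, params.K1)


def _assemble(plasma, dose, tissue, t, cf, cs):
    cp = plasma_concentration(plasma, dose, t)
    c_vasc = tissue.vB * BLOOD_TO_PLASMA_RATIO * cp
    for name, arr in (("c_free", cf), ("c_spec", cs)):
        if np.any(arr < -_NEG_TOL):
            raise RuntimeError(f"{name} went negative beyond tolerance")
    cf = np.clip(cf, 0.0, None)
    cs = np.clip(cs, 0.0, None)
    c_total = (1.0 - tissue.vB) * (cf + cs) + c_vasc
    return TissueSimulation(t, cf, cs, c_vasc, c_total)


def _solve_piecewise_ode(plasma, dose, tissue, grid, window, rtol, atol):
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if grid[0] != 0.0:
        raise ValueError("grid must start at t = 0 (injection)")
    k2, k3, k4 = tissue.k2, tissue.k3, tissue.k4

    def rhs(t, y, kin):
        cf, cs = y
        cp = plasma_concentration(plasma, dose, t)
        return [kin * cp - (k2 + k3) * cf + k4 * cs, k3 * cf - k4 * cs]

    t_fus = tissue.t_FUS if window else 0.0
    segments = []
    if t_fus > 0.0 and t_fus < grid[-1]:
        segments = [(0.0, t_fus, tissue.K_FUS), (t_fus, grid[-1], tissue.K1)]
    elif t_fus >= grid[-1] and window:
        segments = [(0.0, grid[-1], tissue.K_FUS)]
    else:
        segments = [(0.0, grid[-1], tissue.K1)]

    y0 = [0.0, 0.0]
    cf = np.empty_like(grid)
    cs = np.empty_like(grid)
    cf[0], cs[0] = 0.0, 0.0
    for t0, t1, kin in segments:
        mask = (grid > t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[mask], [t1]]))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y0,
            args=(kin,),
            t_eval=t_eval,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"tissue ODE integration failed on [{t0}, {t1}]: {sol.message}")
        idx = np.searchsorted(t_eval, grid[mask])
        cf[mask] = sol.y[0][idx]
        cs[mask] = sol.y[1][idx]
        y0 = [sol.y[0][-1], sol.y[1][-1]]
    return cf, cs


def simulate_m1tcm(
    plasma: PlasmaParams,
    dose: float,
    tissue: TissueParams,
    grid,
    window: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TissueSimulation:
    """Numerically integrate the modified one-tissue model on ``grid``.

    dC_free/dt = k_in(t) C_p(t) - k2 C_free,  C_free(0) = 0,
    with a solver restart at t_FUS.  Requires k3 = k4 = 0.
    """
    if tissue.k3 != 0 or tissue.k4 != 0:
        raise ValueError("one-tissue model requires k3 = k4 = 0")
    cf, cs = _solve_piecewise_ode(plasma, dose, tissue, grid, window, rtol, atol)
    return _assemble(plasma, dose, tissue, np.asarray(grid, float), cf, cs)


def simulate_m2tcm(
    plasma: PlasmaParams,
    dose: float,
    tissue: TissueParams,
    grid,
    window: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TissueSimulation:
    """Numerically integrate the modified two-tissue model on ``grid``.

    dC_free/dt = k_in(t) C_p - (k2 + k3) C_free + k4 C_spec
    dC_spec/dt = k3 C_free - k4 C_spec
    with zero initial conditions and a solver restart at t_FUS.
    """
    cf, cs = _solve_piecewise_ode(plasma, dose, tissue, grid, window, rtol, atol)
    return _assemble(plasma, dose, tissue, np.asarray(grid, float), cf, cs)


# ---------------------------------------------------------------------------
# closed-form route


def _conv_exp(lam: float, m: float, t: np.ndarray, t0: float) -> np.ndarray:
    """Exact ∫_{t0}^{t} e^{-m (t-s)} e^{-lam s} ds for t >= t0 (vectorised)."""
    d = m - lam
    if abs(d) < 1e-9 * (1.0 + abs(m) + abs(lam)):
        # confluent limit lam -> m, first-order accurate in d
        return (t - t0) * np.exp(-m * t + 0.5 * d * (t + t0))
    return (np.exp(-lam * t) - np.exp(-lam * t0 - m * (t - t0))) / d


def analytic_m1tcm(
    plasma: PlasmaParams,
    dose: float,
    tissue: TissueParams,
    t,
    window: bool = True,
) -> np.ndarray:
    """Closed-form C_free(t) for the modified one-tissue model.

    Piecewise convolution of the biexponential input with e^{-k2 t}:
    rate K_FUS on [0, t_FUS], then K1 with continuity of C_free at t_FUS.
    Serves as the independent oracle for the numeric integrator.
    """
    if tissue.k3 != 0 or tissue.k4 != 0:
        raise ValueError("one-tissue model requires k3 = k4 = 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    terms = _input_terms(plasma, dose)
    k2 = tissue.k2
    t_fus = tissue.t_FUS if window else 0.0

    def stage(tt, t0, rate, cf0):
        out = cf0 * np.exp(-k2 * (tt - t0))
        for c, lam in terms:
            out = out + rate * c * _conv_exp(lam, k2, tt, t0)
        return out

    if t_fus == 0.0:
        return stage(t, 0.0, tissue.K1, 0.0)
    if not np.any(t > t_fus):
        return stage(t, 0.0, tissue.K_FUS, 0.0)
    early = t <= t_fus
    out = np.empty_like(t)
    out[early] = stage(t[early], 0.0, tissue.K_FUS, 0.0)
    cf_at_fus = float(stage(np.array([t_fus]), 0.0, tissue.K_FUS, 0.0)[0])
    out[~early] = stage(t[~early], t_fus, tissue.K1, cf_at_fus)
    return out


def _input_terms(plasma: PlasmaParams, dose: float) -> list[tuple[float, float]]:
    """Biexponential plasma input as [(coef, rate), ...]."""
    A, alpha, B, beta = biexp_coefficients(plasma, dose)
    terms = []
    if A != 0:
        terms.append((A, alpha))
    if B != 0:
        terms.append((B, beta))
    return terms


def _tissue_eigensystem(k2: float, k3: float, k4: float):
    """Eigendecomposition of M = [[-(k2+k3), k4], [k3, -k4]].

    The discriminant (k2-k4)^2 + k3^2 + 2 k3 (k2+k4) is non-negative, so
    both eigenvalues are real.  The (measure-zero) defective corner
    k3 = 0, k2 = k4 > 0 is broken by a relative 1e-9 nudge of k4.
    """
    if k3 == 0.0 and abs(k2 - k4) < 1e-9 * (1.0 + k2) and k4 > 0:
        k4 = k4 * (1.0 + 1e-9)
    M = np.array([[-(k2 + k3), k4], [k3, -k4]])
    mu, V = np.linalg.eig(M)
    mu = mu.real
    V = V.real
    return mu, V, np.linalg.solve(V, np.array([1.0, 0.0]))


def analytic_tissue_curve(
    plasma: PlasmaParams,
    dose: float,
    tissue: TissueParams,
    t,
    window: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (c_free, c_spec) at times t for either model order.

    Diagonalises the tissue rate matrix and convolves each mode with the
    biexponential input in closed form, piecewise across t_FUS.  This is
    the fast evaluator used inside estimation; the numeric integrators
    above are the independent route.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    terms = _input_terms(plasma, dose)
    mu, V, w = _tissue_eigensystem(tissue.k2, tissue.k3, tissue.k4)
    t_fus = tissue.t_FUS if window else 0.0

    def stage(tt, t0, rate, z0):
        # z modes evolve independently: z_i' = mu_i z_i + w_i * rate * Cp
        z = np.empty((2, len(tt)))
        for i in range(2):
            zi = z0[i] * np.exp(mu[i] * (tt - t0))
            for c, lam in terms:
                zi = zi + rate * w[i] * c * _conv_exp(lam, -mu[i], tt, t0)
            z[i] = zi
        return V @ z

    if t_fus <= 0.0:
        x = stage(t, 0.0, tissue.K1, np.zeros(2))
        return x[0], x[1]
    if not np.any(t > t_fus):
        x = stage(t, 0.0, tissue.K_FUS, np.zeros(2))
        return x[0], x[1]
    early = t <= t_fus
    x = np.empty((2, len(t)))
    x[:, early] = stage(t[early], 0.0, tissue.K_FUS, np.zeros(2))
    x_fus = stage(np.array([t_fus]), 0.0, tissue.K_FUS, np.zeros(2))[:, 0]
    z_fus = np.linalg.solve(V, x_fus)
    x[:, ~early] = stage(t[~early], t_fus, tissue.K1, z_fus)
    return x[0], x[1]


# ---------------------------------------------------------------------------
# frame-averaged observation model

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(5)


def _gl_average(fn_values_at, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gauss-Legendre mean of a curve over intervals [a, b] (vectorised).

    Zero-width intervals return the value at a (their weight is zero in
    the caller's combination).
    """
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = fn_values_at(nodes.ravel()).reshape(nodes.shape)
    return vals @ (0.5 * _GL_WEIGHTS)


def frame_averaged_total(
    plasma: PlasmaParams,
    dose: float,
    tissue: TissueParams,
    schedule: FrameSchedule,
    window: bool = True,
) -> np.ndarray:
    """Frame-averaged modeled PET signal c_total for each frame.

    The prediction compared with an observed TAC value is the mean of the
    model over the frame interval (not the mid-time sample).  Frames that
    straddle t_FUS are split at the discontinuity so the average is exact
    for the piecewise-smooth curve.
    """

    def total_at(tt):
        tt = np.asarray(tt)
        order = np.argsort(tt, kind="stable")
        ts = tt[order]
        cf, cs = analytic_tissue_curve(plasma, dose, tissue, ts, window=window)
        cp = plasma_concentration(plasma, dose, ts)
        tot = (1.0 - tissue.vB) * (cf + cs) + tissue.vB * BLOOD_TO_PLASMA_RATIO * cp
        out = np.empty_like(tot)
        out[order] = tot
        return out

    a, b = schedule.start, schedule.end
    t_fus = tissue.t_FUS if window else 0.0
    # split each frame at t_FUS where it falls inside
    cut1 = np.minimum(b, np.maximum(a, t_fus))
    w1 = cut1 - a
    w2 = b - cut1
    avg1 = _gl_average(total_at, a, cut1)
    avg2 = _gl_average(total_at, cut1, b)
    return (w1 * avg1 + w2 * avg2) / (w1 + w2)
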