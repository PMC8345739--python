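"""Dynamic FMISO PET: image-based input function, irreversible two-tissue
compartment model with a blood-volume component, and static uptake metrics.

Kinetic model
-------------
One-plasma, two-tissue irreversible model:

    dC1/dt = K1 Cp - (k2 + k3) C1
    dC2/dt = k3 C1
    C_tissue = (1 - vb) (C1 + C2) + vb Cwb

K1 (delivery/perfusion), k2 (washout) and k3 (irreversible trapping, the
hypoxia surrogate) are in 1/min; vb is the fractional blood volume.  The
distribution volume of unbound tracer is DV = K1/k2.  The whole-blood curve
Cwb is taken equal to the image-derived input function (jugular, whole blood)
up to a configurable scale.

The input function is a "triphasic exponential": zero before bolus arrival, a
linear rise to the peak, then a sum of three decaying exponentials that is
continuous at the peak.  Solutions are evaluated by exact convolution
recursions for a piecewise-linear Cp on a uniform grid; frame values are exact
time-averages of the instantaneous model over each frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import TimeSeries
from .dce import expconv_plinear

__all__ = [
    "InputFunction",
    "FMISOParams",
    "default_input_function",
    "fit_input_function",
    "simulate_2tc",
    "simulate_2tc_frames",
    "fit_2tc",
    "lean_body_mass",
    "static_uptake_metrics",
    "K1_BOUNDS",
    "K2_BOUNDS",
    "K3_BOUNDS",
    "VB_BOUNDS",
]

K1_BOUNDS = (1e-3, 2.0)   # 1/min
K2_BOUNDS = (1e-3, 2.0)   # 1/min
K3_BOUNDS = (0.0, 0.05)   # 1/min
VB_BOUNDS = (0.0, 0.2)


# --------------------------------------------------------------------------
# input function
# --------------------------------------------------------------------------

@dataclass
class InputFunction:
    """Triphasic-exponential blood activity model (kBq/mL).

    Zero before ``bolus_arrival_s``, linear rise to the peak at
    ``peak_time_s``, then ``sum_i A_i exp(-lambda_i (t - peak_time))``.  The
    peak value is ``sum(amplitudes)`` so the curve is continuous at the peak.
    A sampled fallback (``form="measured"``) interpolates a stored series.
    """

    bolus_arrival_s: float = 30.0
    peak_time_s: float = 50.0
    amplitudes: tuple[float, float, float] = (15.0, 6.0, 4.0)
    decay_rates_per_s: tuple[float, float, float] = (0.02, 0.002, 1.0e-5)
    form: str = "triphasic"
    times_s: np.ndarray | None = None
    values: np.ndarray | None = None
    residual_norm: float = float("nan")
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.form == "triphasic":
            if self.peak_time_s <= self.bolus_arrival_s:
                raise ValueError("peak must come after bolus arrival")
            if min(self.amplitudes) < 0 or min(self.decay_rates_per_s) < 0:
                raise ValueError("amplitudes and decay rates must be nonnegative")

    @property
    def peak(self) -> float:
        return float(sum(self.amplitudes))

    def cp(self, times_s: np.ndarray) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        if self.form == "measured":
            if self.times_s is None or self.values is None:
                raise ValueError("measured input function requires sampled data")
            if t.max() > self.times_s.max() + 1e-9:
                raise ValueError("requested times fall outside the input-function support")
            return np.interp(t, self.times_s, self.values, left=0.0)
        t0, tp = self.bolus_arrival_s, self.peak_time_s
        rise = self.peak * (t - t0) / (tp - t0)
        decay = np.zeros_like(t)
        for a, lam in zip(self.amplitudes, self.decay_rates_per_s):
            decay += a * np.exp(-lam * np.clip(t - tp, 0.0, None))
        return np.where(t < t0, 0.0, np.where(t < tp, rise, decay))

    def frame_means(self, starts_s: np.ndarray, durations_s: np.ndarray, n_sub: int = 33) -> np.ndarray:
        """Time-averages of Cp over frames, by per-frame composite trapezoid."""
        starts = np.asarray(starts_s, dtype=float)
        durs = np.asarray(durations_s, dtype=float)
        frac = np.linspace(0.0, 1.0, n_sub)
        grid = starts[:, None] + durs[:, None] * frac[None, :]
        return np.trapezoid(self.cp(grid), grid, axis=1) / durs


def default_input_function() -> InputFunction:
    return InputFunction()


def fit_input_function(blood_tac: TimeSeries, n_sub: int = 33) -> InputFunction:
    """Fit the triphasic-exponential model to a frame-averaged blood TAC.

    The model prediction is the frame-average of the analytic curve, so a
    noiseless round trip through frame binning is exact.  Raises on fewer than
    6 frames; an all-zero TAC returns ``flag="empty_tac"``.
    """
    if blood_tac.durations is None:
        raise ValueError("blood TAC needs frame durations")
    if len(blood_tac.times) < 6:
        raise ValueError("input-function fit needs at least 6 frames")
    y = blood_tac.values
    starts, durs = blood_tac.times, blood_tac.durations
    if np.all(np.abs(y) < 1e-12):
        return InputFunction(flag="empty_tac", residual_norm=0.0)

    mids = starts + 0.5 * durs
    k_peak = int(np.argmax(y))
    tp0 = float(mids[k_peak])
    t00 = max(0.0, tp0 - max(durs[k_peak], 10.0))
    peak0 = float(y[k_peak])

    def unpack(p: np.ndarray) -> InputFunction:
        t0, dtp, a1, a2, a3, l1, l2, l3 = p
        return InputFunction(
            bolus_arrival_s=t0,
            peak_time_s=t0 + dtp,
            amplitudes=(a1, a2, a3),
            decay_rates_per_s=(l1, l2, l3),
        )

    def resid(p: np.ndarray) -> np.ndarray:
        return unpack(p).frame_means(starts, durs, n_sub) - y

    x0 = [t00, max(tp0 - t00, 5.0), 0.6 * peak0, 0.25 * peak0, 0.15 * peak0,
          0.03, 0.002, 2e-5]
    lo = [0.0, 1.0, 0.0, 0.0, 0.0, 1e-4, 1e-5, 0.0]
    hi = [tp0 + 1.0, 300.0, 10 * peak0, 10 * peak0, 10 * peak0, 1.0, 0.1, 1e-3]
    sol = least_squares(resid, x0=np.clip(x0, lo, hi), bounds=(lo, hi), method="trf")
    out = unpack(sol.x)
    out.residual_norm = float(np.linalg.norm(sol.fun))
    out.flag = "ok" if sol.success else "no_convergence"
    return out


# --------------------------------------------------------------------------
# compartment model
# --------------------------------------------------------------------------

@dataclass
class FMISOParams:
    """Irreversible 2-tissue-compartment parameters (rates in 1/min)."""

    k1: float
    k2: float
    k3: float
    vb: float
    wb_scale: float = 1.0
    residual_norm: float = float("nan")
    converged: bool = True
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rates must be nonnegative")
        if not (0 <= self.vb <= VB_BOUNDS[1]):
            raise ValueError(f"vb must lie in [0, {VB_BOUNDS[1]}]")

    @property
    def dv(self) -> float:
        """Distribution volume K1/k2 of the reversible compartment."""
        return self.k1 / self.k2


def _grid_with_boundaries(t_end: float, dt_s: float) -> np.ndarray:
    n = int(round(t_end / dt_s))
    if abs(n * dt_s - t_end) > 1e-9:
        raise ValueError("dt must divide the requested end time")
    return np.linspace(0.0, t_end, n + 1)


def _compartment_curves(
    params: FMISOParams, cp: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C1, C2 and cumulative integral of Cp at the grid nodes (exact for
    piecewise-linear Cp)."""
    k1s = params.k1 / 60.0
    alpha = (params.k2 + params.k3) / 60.0
    k3s = params.k3 / 60.0
    h = np.diff(grid)
    p_incr = 0.5 * h * (cp[:-1] + cp[1:])
    P = np.concatenate([[0.0], np.cumsum(p_incr)])
    if alpha > 0:
        c1 = k1s * expconv_plinear(grid, cp, alpha)
        int_c1 = (k1s * P - c1) / alpha
    else:
        c1 = k1s * P
        # integral of C1 when there is no washout: int of K1*P, P pw-quadratic
        a, c = cp[:-1], (cp[1:] - cp[:-1]) / h
        q_incr = P[:-1] * h + 0.5 * a * h**2 + c * h**3 / 6.0
        int_c1 = k1s * np.concatenate([[0.0], np.cumsum(q_incr)])
    c2 = k3s * int_c1
    return c1, c2, P


def simulate_2tc(
    params: FMISOParams,
    if_model: InputFunction,
    times_s: np.ndarray,
    dt_s: float = 0.5,
) -> np.ndarray:
    """Instantaneous tissue activity at ``times_s`` (kBq/mL)."""
    t = np.asarray(times_s, dtype=float)
    t_end = float(np.ceil(t.max() / dt_s)) * dt_s
    grid = _grid_with_boundaries(t_end, dt_s)
    cp = if_model.cp(grid)
    c1, c2, _ = _compartment_curves(params, cp, grid)
    tissue = (1.0 - params.vb) * (c1 + c2) + params.vb * params.wb_scale * cp
    return np.interp(t, grid, tissue)


def simulate_2tc_frames(
    params: FMISOParams,
    if_model: InputFunction,
    frame_schedule: np.ndarray,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Exact frame-averaged tissue activity over ``(start, duration)`` rows.

    All frame boundaries must be multiples of ``dt_s``; the average is the
    analytic time integral of the piecewise-linear-input solution, not a
    sub-sampled approximation.
    """
    sched = np.asarray(frame_schedule, dtype=float)
    starts, durs = sched[:, 0], sched[:, 1]
    ends = starts + durs
    t_end = float(ends.max())
    grid = _grid_with_boundaries(t_end, dt_s)
    idx_s = np.rint(starts / dt_s).astype(int)
    idx_e = np.rint(ends / dt_s).astype(int)
    if np.any(np.abs(idx_s * dt_s - starts) > 1e-6) or np.any(np.abs(idx_e * dt_s - ends) > 1e-6):
        raise ValueError("frame boundaries must be multiples of dt_s")
    cp = if_model.cp(grid)
    c1, c2, P = _compartment_curves(params, cp, grid)
    h = np.diff(grid)
    a, c = cp[:-1], (cp[1:] - cp[:-1]) / h
    # Q = int P dt, exact since P is piecewise quadratic
    q_incr = P[:-1] * h + 0.5 * a * h**2 + c * h**3 / 6.0
    Q = np.concatenate([[0.0], np.cumsum(q_incr)])
    k1s = params.k1 / 60.0
    alpha = (params.k2 + params.k3) / 60.0
    k3s = params.k3 / 60.0
    if alpha > 0:
        int_c1 = (k1s * P - c1) / alpha          # cumulative int of C1
        int_int_c1 = (k1s * Q - int_c1) / alpha  # cumulative int of int C1
    else:
        int_c1 = k1s * Q
        # alpha = 0 implies k3 = 0, so the trapped compartment never fills
        int_int_c1 = np.zeros_like(int_c1)
    int_c2 = k3s * int_int_c1
    frame_vals = np.empty(len(starts))
    for i, (s, e) in enumerate(zip(idx_s, idx_e)):
        ti = (int_c1[e] - int_c1[s]) + (int_c2[e] - int_c2[s])
        bl = P[e] - P[s]
        frame_vals[i] = ((1.0 - params.vb) * ti + params.vb * params.wb_scale * bl) / durs[i]
    return frame_vals


def fit_2tc(
    tac: TimeSeries,
    if_model: InputFunction,
    dt_s: float = 1.0,
    wb_scale: float = 1.0,
) -> FMISOParams:
    """Weighted NLLS fit of the irreversible 2TC model to a frame-averaged TAC.

    Inverse-variance weighting for proportional frame noise: the residual of
    frame i is scaled by 1/activity_i (activity floored at 2% of the peak to
    keep weights finite on empty early frames).  DV follows as K1/k2.  A TAC
    carrying no tissue signal drives K1 to its lower bound and is flagged.
    """
    if tac.durations is None:
        raise ValueError("TAC needs frame durations")
    sched = np.column_stack([tac.times, tac.durations])
    y = tac.values
    w = 1.0 / np.maximum(np.abs(y), 0.02 * np.abs(y).max())
    w /= w.mean()

    def resid(p: np.ndarray) -> np.ndarray:
        model = simulate_2tc_frames(
            FMISOParams(p[0], p[1], p[2], p[3], wb_scale=wb_scale), if_model, sched, dt_s
        )
        return w * (model - y)

    lo = [K1_BOUNDS[0], K2_BOUNDS[0], K3_BOUNDS[0], VB_BOUNDS[0]]
    hi = [K1_BOUNDS[1], K2_BOUNDS[1], K3_BOUNDS[1], VB_BOUNDS[1]]
    starts = [
        (0.3, 0.35, 0.005, 0.05),
        (0.6, 0.7, 0.02, 0.1),
        (0.1, 0.1, 0.001, 0.02),
    ]
    best = None
    any_success = False
    for x0 in starts:
        sol = least_squares(
            resid, x0=np.clip(x0, lo, hi), bounds=(lo, hi),
            method="trf", x_scale=[0.3, 0.3, 0.01, 0.05],
        )
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    k1, k2, k3, vb = (float(v) for v in best.x)
    flag = "ok"
    if k1 <= K1_BOUNDS[0] * 1.01:
        flag = "k1_at_lower_bound"
    elif not any_success:  # pragma: no cover
        flag = "no_convergence"
    return FMISOParams(
        k1=k1, k2=k2, k3=k3, vb=vb, wb_scale=wb_scale,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=any_success, flag=flag,
    )


# --------------------------------------------------------------------------
# static uptake metrics
# --------------------------------------------------------------------------

def lean_body_mass(weight_kg: float, height_cm: float, sex: str) -> float:
    """James-formula lean body mass (kg)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    if sex.lower().startswith("m"):
        return 1.10 * weight_kg - 128.0 * (weight_kg / height_cm) ** 2
    if sex.lower().startswith("f"):
        return 1.07 * weight_kg - 148.0 * (weight_kg / height_cm) ** 2
    raise ValueError("sex must be 'male' or 'female'")


def static_uptake_metrics(
    tissue_late_kbq_ml: float,
    blood_late_kbq_ml: float,
    injected_activity_mbq: float,
    weight_kg: float,
    height_cm: float,
    sex: str,
) -> tuple[float, float]:
    """Late-static tumor-to-blood ratio and SUL.

    TBR is the tissue/blood activity ratio at the late static time.  SUL is
    the standardized uptake value normalized by James lean body mass,
    ``SUL = C_tissue [kBq/mL] * LBM [g] / injected [kBq]`` (1 g ~ 1 mL).
    """
    if blood_late_kbq_ml <= 0:
        raise ValueError("late blood activity must be positive")
    if injected_activity_mbq <= 0:
        raise ValueError("injected activity must be positive")
    tbr = tissue_late_kbq_ml / blood_late_kbq_ml
    lbm_g = 1000.0 * lean_body_mass(weight_kg, height_cm, sex)
    sul = tissue_late_kbq_ml * lbm_g / (injected_activity_mbq * 1000.0)
    return float(tbr), float(sul)
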