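"""Diffusion-weighted MRI: monoexponential (ADC) and IVIM biexponential fits.

The signal models are

    S(b) = S0 * exp(-b * ADC)                                (monoexponential)
    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ] (IVIM)

with the true diffusion coefficient D, pseudo-diffusion coefficient D* (both
mm^2/s) and perfusion fraction f.  Fitting is ordinary nonlinear least squares
on magnitude signal; the IVIM fit is initialized by the standard segmented
scheme (high-b monoexponential for D, intercept gap for f) and then refined by
a bounded 4-parameter fit, which prevents the D/D* compartment swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import TimeSeries

__all__ = [
    "IVIMFit",
    "ivim_signal",
    "adc_signal",
    "fit_adc",
    "fit_ivim",
    "IVIM_SEGMENTATION_B",
    "D_BOUNDS",
    "DSTAR_BOUNDS",
]

#: b-value threshold (s/mm^2) above which perfusion decay is assumed complete;
#: used for the segmented initialization stage.
IVIM_SEGMENTATION_B = 200.0

#: Box bounds (mm^2/s); D* box sits above the D box so the compartments
#: cannot swap.
D_BOUNDS = (1e-5, 4e-3)
DSTAR_BOUNDS = (3e-3, 0.1)


def adc_signal(b: np.ndarray, s0: float, adc: float) -> np.ndarray:
    return s0 * np.exp(-np.asarray(b, dtype=float) * adc)


def ivim_signal(b: np.ndarray, s0: float, f: float, d: float, d_star: float) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return s0 * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d))


@dataclass
class IVIMFit:
    """Voxel-level result of the monoexponential and IVIM fits."""

    adc: float
    s0_mono: float
    d_true: float
    d_star: float
    f: float
    s0_ivim: float
    residual_mono: float
    residual_ivim: float
    converged: bool
    flag: str = "ok"


def _loglinear_adc(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Weighted log-linear ADC estimate.  Weights ~ S^2 undo the variance
    distortion of the log transform."""
    w = s**2
    x = np.vstack([np.ones_like(b), -b]).T
    y = np.log(s)
    wx = x * w[:, None]
    beta = np.linalg.solve(wx.T @ x, wx.T @ y)
    return float(np.exp(beta[0])), float(beta[1])


def fit_adc(
    signal: TimeSeries,
    b_subset: np.ndarray | None = None,
) -> tuple[float, float, str]:
    """Fit the monoexponential model; returns ``(adc, s0, flag)``.

    Non-positive samples are excluded (log transform); fewer than two valid
    points yields ``flag="too_few_points"`` with NaN estimates.  A non-decaying
    signal is clamped at the ``adc = 0`` boundary and flagged.
    """
    b = signal.times if b_subset is None else np.asarray(b_subset, dtype=float)
    s = signal.values if b_subset is None else np.interp(b, signal.times, signal.values)
    valid = s > 0
    b, s = b[valid], s[valid]
    if len(np.unique(b)) < 2:
        return float("nan"), float("nan"), "too_few_points"
    s0_init, adc_init = _loglinear_adc(b, s)
    if adc_init <= 0:
        # constant or rising signal: boundary solution
        return 0.0, float(np.mean(s)), "adc_at_zero_bound"

    def resid(p: np.ndarray) -> np.ndarray:
        return adc_signal(b, p[0], p[1]) - s

    sol = least_squares(
        resid,
        x0=[s0_init, adc_init],
        bounds=([0.0, 0.0], [np.inf, 0.05]),
        method="trf",
    )
    adc, s0 = float(sol.x[1]), float(sol.x[0])
    flag = "ok" if sol.success else "no_convergence"
    if adc <= 1e-10:
        adc, flag = 0.0, "adc_at_zero_bound"
    return adc, s0, flag


def fit_ivim(signal: TimeSeries) -> IVIMFit:
    """Segmented-initialized, bounded 4-parameter IVIM fit of one voxel curve.

    Requires b-values both below and above the segmentation threshold.  If the
    full fit does not converge the segmented estimates are returned with
    ``converged=False``.
    """
    b = signal.times
    s = np.asarray(signal.values, dtype=float)
    valid = s > 0
    b, s = b[valid], s[valid]
    high = b >= IVIM_SEGMENTATION_B
    if high.sum() < 2 or (~high).sum() < 1 or len(b) < 5:
        raise ValueError(
            "IVIM fit needs >=5 positive samples spanning the "
            f"b={IVIM_SEGMENTATION_B:g} s/mm^2 segmentation threshold"
        )

    adc, s0_mono, adc_flag = fit_adc(TimeSeries(b, s, kind="dwi"))
    res_mono = float(np.linalg.norm(adc_signal(b, s0_mono, adc) - s)) if np.isfinite(adc) else float("nan")

    # segmented stage: D and the perfusion-free intercept from high b-values
    s0_high, d_seg = _loglinear_adc(b[high], s[high])
    d_seg = float(np.clip(d_seg, *D_BOUNDS))
    s_b0 = float(s[b == b.min()].mean())
    f_seg = float(np.clip(1.0 - s0_high / s_b0, 0.0, 0.6)) if s_b0 > 0 else 0.0
    s0_seg = s_b0
    dstar_seg = float(np.clip(10.0 * d_seg, *DSTAR_BOUNDS))

    def resid(p: np.ndarray) -> np.ndarray:
        return ivim_signal(b, p[0], p[1], p[2], p[3]) - s

    lower = [0.0, 0.0, D_BOUNDS[0], DSTAR_BOUNDS[0]]
    upper = [np.inf, 1.0, D_BOUNDS[1], DSTAR_BOUNDS[1]]
    x0 = np.clip(
        [s0_seg, f_seg, d_seg, dstar_seg],
        np.asarray(lower) + 1e-12,
        [s0_seg * 10 + 1.0, 1.0 - 1e-12, D_BOUNDS[1] - 1e-12, DSTAR_BOUNDS[1] - 1e-12],
    )
    sol = least_squares(resid, x0=x0, bounds=(lower, upper), method="trf")
    if sol.success:
        s0_ivim, f_hat, d_hat, dstar_hat = (float(v) for v in sol.x)
        res_ivim = float(np.linalg.norm(sol.fun))
        converged, flag = True, "ok"
    else:  # pragma: no cover - trf essentially always reports success
        s0_ivim, f_hat, d_hat, dstar_hat = s0_seg, f_seg, d_seg, dstar_seg
        res_ivim = float(np.linalg.norm(resid(np.array([s0_seg, f_seg, d_seg, dstar_seg]))))
        converged, flag = False, "segmented_fallback"
    if adc_flag != "ok":
        flag = adc_flag
    return IVIMFit(
        adc=adc,
        s0_mono=s0_mono,
        d_true=d_hat,
        d_star=dstar_hat,
        f=f_hat,
        s0_ivim=s0_ivim,
        residual_mono=res_mono,
        residual_ivim=res_ivim,
        converged=converged,
        flag=flag,
    )
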