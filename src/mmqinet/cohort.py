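"""Synthetic lesion cohort with a prescribed rank-correlation structure.

The generator draws per-lesion ground-truth physiology whose Spearman
correlation matrix approaches a prescribed target (by default the published
lesion-cohort pattern) and emits noisy raw signals for all three modalities,
so that every downstream fitting stage can be validated by parameter
recovery.

Rank structure is imposed with a Gaussian copula: a target Spearman rho_S is
converted to the latent Pearson correlation r = 2 sin(pi rho_S / 6), a
multivariate normal sample is pushed through the standard-normal CDF, and the
uniform scores are mapped through the marginal quantile functions.  Marginals
are log-normal for strictly positive rates and volumes and logit-normal for
fractions, moment-matched to the published per-metric mean +/- SD.

Self-consistency of the ground truth with the forward models is preserved by
*deriving* (rather than sampling) every metric the models determine: ADC from
a noiseless monoexponential fit of the lesion's biexponential decay, kep =
Ktrans/ve, k2 = K1/DV, and the late-static TBRs from the noiseless PET
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    AcquisitionProtocol,
    FRACTION_METRICS,
    TABLE1_MARGINALS,
    TimeSeries,
    default_dwi_protocol,
    default_pet_protocol,
    rng_for,
)
from .dce import AIFModel, FXRParams, default_aif, forward_fxr_signal, spgr_signal
from .dwi import fit_adc, ivim_signal
from .pet import FMISOParams, InputFunction, default_input_function, simulate_2tc_frames

__all__ = [
    "CorrelationSpec",
    "LesionGroundTruth",
    "COHORT_SAMPLED_METRICS",
    "spearman_to_latent",
    "repair_correlation",
    "lognormal_params",
    "logitnormal_params",
    "default_correlation_spec",
    "sample_metric_table",
    "sample_ground_truth",
    "ground_truth_table",
    "generate_dwi_signal",
    "generate_vfa_signals",
    "generate_dce_signal",
    "generate_fmiso_tac",
    "DEFAULT_COHORT_SEED",
    "DEFAULT_N_LESIONS",
    "DEFAULT_VOXELS_PER_LESION",
]

DEFAULT_COHORT_SEED = 20210803
DEFAULT_N_LESIONS = 27
DEFAULT_VOXELS_PER_LESION = 100

#: Metrics drawn by the copula in the default cohort; the remaining canonical
#: metrics (ADC, kep, TBRmax, TBRmean) are derived from these.
COHORT_SAMPLED_METRICS: tuple[str, ...] = (
    "Vt-PET", "Vt-MRI", "D", "D*", "f", "Ktrans", "ve", "tau_i",
    "SULmax", "SULmean", "K1", "k3max", "k3mean", "DV",
)


# --------------------------------------------------------------------------
# copula machinery
# --------------------------------------------------------------------------

def spearman_to_latent(rho_s: np.ndarray) -> np.ndarray:
    """Latent Pearson correlation reproducing a target Spearman rho for a
    Gaussian copula: r = 2 sin(pi rho / 6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def repair_correlation(matrix: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Nearest-PSD repair by eigenvalue clipping plus diagonal renormalization.

    A matrix whose smallest eigenvalue is below -0.1 is rejected (the target
    is too inconsistent for clipping to be an honest repair).
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    if w.min() < -0.1:
        raise ValueError(
            f"target correlation matrix is far from PSD (eigenvalue {w.min():.4f})"
        )
    if w.min() >= clip:
        return m
    w = np.clip(w, clip, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("log-normal moment matching needs positive mean and SD")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - 0.5 * sigma2), float(np.sqrt(sigma2))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(96)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _logitnormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    p = 1.0 / (1.0 + np.exp(-(mu + sigma * _GH_NODES)))
    m = float(np.sum(_GH_WEIGHTS * p))
    v = float(np.sum(_GH_WEIGHTS * (p - m) ** 2))
    return m, v


def logitnormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a logit-normal with the given mean and SD (numeric
    moment matching by Gauss-Hermite quadrature)."""
    if not (0 < mean < 1):
        raise ValueError("logit-normal mean must lie in (0, 1)")

    def eqs(p: np.ndarray) -> np.ndarray:
        m, v = _logitnormal_moments(p[0], abs(p[1]))
        return np.array([m - mean, np.sqrt(v) - sd])

    x0 = np.array([np.log(mean / (1.0 - mean)), sd / (mean * (1.0 - mean))])
    sol = optimize.root(eqs, x0, method="hybr")
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"logit-normal moment matching failed for mean={mean}, sd={sd}")
    return float(sol.x[0]), float(abs(sol.x[1]))


def _marginal_ppf(name: str, mean: float, sd: float):
    if name in FRACTION_METRICS:
        mu, sigma = logitnormal_params(mean, sd)
        return lambda u: 1.0 / (1.0 + np.exp(-(mu + sigma * stats.norm.ppf(u))))
    mu, sigma = lognormal_params(mean, sd)
    return lambda u: np.exp(mu + sigma * stats.norm.ppf(u))


@dataclass
class CorrelationSpec:
    """Target rank-correlation structure and marginals for cohort sampling."""

    metric_names: tuple[str, ...]
    target_rank_corr: np.ndarray
    marginal_means: np.ndarray
    marginal_sds: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.metric_names)
        self.target_rank_corr = np.asarray(self.target_rank_corr, dtype=float)
        self.marginal_means = np.asarray(self.marginal_means, dtype=float)
        self.marginal_sds = np.asarray(self.marginal_sds, dtype=float)
        if self.target_rank_corr.shape != (k, k):
            raise ValueError("target matrix shape does not match metric count")
        if not np.allclose(np.diag(self.target_rank_corr), 1.0):
            raise ValueError("target matrix must have unit diagonal")
        if np.abs(self.target_rank_corr).max() > 1.0 + 1e-12:
            raise ValueError("rank correlations must lie in [-1, 1]")

    @property
    def latent_corr(self) -> np.ndarray:
        """PSD-repaired latent Pearson matrix for the Gaussian copula."""
        return repair_correlation(spearman_to_latent(self.target_rank_corr))


def default_correlation_spec(
    metrics: tuple[str, ...] = COHORT_SAMPLED_METRICS,
) -> CorrelationSpec:
    """Cohort spec with the published rank-correlation pattern and marginals."""
    from .network import load_published_spearman  # deferred: no import cycle

    rho, _, _ = load_published_spearman()
    missing = [m for m in metrics if m not in rho.index]
    if missing:
        raise KeyError(f"metrics absent from the published matrix: {missing}")
    target = rho.loc[list(metrics), list(metrics)].to_numpy()
    means = np.array([TABLE1_MARGINALS[m][0] for m in metrics])
    sds = np.array([TABLE1_MARGINALS[m][1] for m in metrics])
    return CorrelationSpec(tuple(metrics), target, means, sds)


def sample_metric_table(spec: CorrelationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` rows with the spec's rank structure and marginals."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = rng_for(seed, "copula")
    latent = spec.latent_corr
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(latent)))
    z = rng.standard_normal((n, len(latent))) @ chol.T
    u = stats.norm.cdf(z)
    cols = {}
    for j, name in enumerate(spec.metric_names):
        ppf = _marginal_ppf(name, spec.marginal_means[j], spec.marginal_sds[j])
        cols[name] = ppf(u[:, j])
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# lesion ground truth
# --------------------------------------------------------------------------

@dataclass
class LesionGroundTruth:
    """Ground-truth physiology of one synthetic lesion.

    Diffusivities in mm^2/s; Ktrans/kep/K1/k2/k3 in 1/min; tau_i in s;
    volumes in cm^3; everything else dimensionless.
    """

    lesion_id: str
    adc: float
    d_true: float
    d_star: float
    f: float
    ktrans: float
    ve: float
    tau_i: float
    k1: float
    k2: float
    k3: float
    k3_mean: float
    vb: float
    dv: float
    tbr: float
    tbr_mean: float
    sul_mean: float
    sul_max: float
    vol_mri: float
    vol_pet: float

    def __post_init__(self) -> None:
        for name in ("adc", "d_true", "d_star", "ktrans", "tau_i", "k1", "k2",
                     "k3", "k3_mean", "dv", "tbr", "tbr_mean", "sul_mean",
                     "sul_max", "vol_mri", "vol_pet"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.ve < 1):
            raise ValueError("ve must lie in (0, 1)")
        if not (0 <= self.f < 1):
            raise ValueError("f must lie in [0, 1)")
        if not (0 <= self.vb <= 0.2):
            raise ValueError("vb must lie in [0, 0.2]")
        if self.d_star <= self.d_true:
            raise ValueError("d_star must exceed d_true")
        if abs(self.dv - self.k1 / self.k2) > 1e-12 * max(1.0, self.dv):
            raise ValueError("dv must equal k1/k2")

    @property
    def kep(self) -> float:
        return self.ktrans / self.ve


def _noiseless_adc(truth_d: float, truth_dstar: float, truth_f: float,
                   protocol: AcquisitionProtocol) -> float:
    b = protocol.b_values
    s = ivim_signal(b, 1000.0, truth_f, truth_d, truth_dstar)
    adc, _, _ = fit_adc(TimeSeries(b, s, kind="dwi"))
    return adc


def _noiseless_tbr(k1: float, k2: float, k3: float, vb: float,
                   if_model: InputFunction, protocol: AcquisitionProtocol) -> float:
    sched = protocol.pet_frame_schedule
    tissue = simulate_2tc_frames(FMISOParams(k1, k2, k3, vb), if_model, sched)[-1]
    blood = if_model.frame_means(sched[-1:, 0], sched[-1:, 1])[0]
    return tissue / blood


def sample_ground_truth(
    n_lesions: int = DEFAULT_N_LESIONS,
    spec: CorrelationSpec | None = None,
    seed: int = DEFAULT_COHORT_SEED,
    dwi_protocol: AcquisitionProtocol | None = None,
    pet_protocol: AcquisitionProtocol | None = None,
    if_model: InputFunction | None = None,
    vb_mean_sd: tuple[float, float] = (0.05, 0.02),
) -> list[LesionGroundTruth]:
    """Sample a lesion cohort with the prescribed rank-correlation structure.

    Metrics not covered by ``spec`` fall back to independent draws from the
    published marginals; ADC, kep, k2 and the TBRs are derived from the
    sampled physiology (see module docstring).  Deterministic given ``seed``.
    """
    if n_lesions < 3:
        raise ValueError("need at least 3 lesions")
    if spec is None:
        spec = default_correlation_spec()
    dwi_protocol = dwi_protocol or default_dwi_protocol()
    pet_protocol = pet_protocol or default_pet_protocol()
    if_model = if_model or default_input_function()

    table = sample_metric_table(spec, n_lesions, seed)
    rng = rng_for(seed, "marginal-fallback")
    for name in COHORT_SAMPLED_METRICS:
        if name not in table.columns:
            mean, sd = TABLE1_MARGINALS[name]
            ppf = _marginal_ppf(name, mean, sd)
            table[name] = ppf(rng.uniform(size=n_lesions))
    vb_ppf = _marginal_ppf("vb", *vb_mean_sd)
    vb = vb_ppf(rng_for(seed, "vb").uniform(size=n_lesions))

    lesions: list[LesionGroundTruth] = []
    for i in range(n_lesions):
        row = table.iloc[i]
        d, dstar = float(row["D"]), float(row["D*"])
        dstar = max(dstar, 1.01 * d)  # rank-preserving guard; ~never triggers
        k1, dv = float(row["K1"]), float(row["DV"])
        k2 = k1 / dv
        k3, k3_mean = float(row["k3max"]), float(row["k3mean"])
        k3, k3_mean = max(k3, k3_mean), min(k3, k3_mean)
        lesions.append(
            LesionGroundTruth(
                lesion_id=f"L{i + 1:03d}",
                adc=_noiseless_adc(d, dstar, float(row["f"]), dwi_protocol),
                d_true=d,
                d_star=dstar,
                f=float(row["f"]),
                ktrans=float(row["Ktrans"]),
                ve=float(row["ve"]),
                tau_i=float(row["tau_i"]),
                k1=k1,
                k2=k2,
                k3=k3,
                k3_mean=k3_mean,
                vb=float(vb[i]),
                dv=dv,
                tbr=_noiseless_tbr(k1, k2, k3, float(vb[i]), if_model, pet_protocol),
                tbr_mean=_noiseless_tbr(k1, k2, k3_mean, float(vb[i]), if_model, pet_protocol),
                sul_mean=float(row["SULmean"]),
                sul_max=float(row["SULmax"]),
                vol_mri=float(row["Vt-MRI"]),
                vol_pet=float(row["Vt-PET"]),
            )
        )
    return lesions


def ground_truth_table(lesions: list[LesionGroundTruth]) -> pd.DataFrame:
    """Lesion x metric table (canonical column names) of the ground truth."""
    rows = []
    for les in lesions:
        rows.append({
            "lesion_id": les.lesion_id,
            "Vt-PET": les.vol_pet, "Vt-MRI": les.vol_mri,
            "ADC": les.adc, "D": les.d_true, "D*": les.d_star, "f": les.f,
            "Ktrans": les.ktrans, "ve": les.ve, "tau_i": les.tau_i,
            "kep": les.kep,
            "SULmax": les.sul_max, "SULmean": les.sul_mean,
            "K1": les.k1, "k3max": les.k3, "k3mean": les.k3_mean,
            "DV": les.dv, "TBRmax": les.tbr, "TBRmean": les.tbr_mean,
        })
    return pd.DataFrame(rows).set_index("lesion_id")


# --------------------------------------------------------------------------
# raw-signal generators
# --------------------------------------------------------------------------

def generate_dwi_signal(
    truth: LesionGroundTruth,
    protocol: AcquisitionProtocol,
    n_voxels: int,
    snr: float,
    seed: int,
    s0: float = 1000.0,
) -> TimeSeries:
    """Per-voxel DW signal over the protocol b-values with Rician noise.

    SNR is the noiseless b=0 signal divided by the per-excitation Gaussian
    channel noise SD; the returned signal is the magnitude average over the
    protocol's ``n_averages`` excitations (NA), as acquired.  ``snr=inf``
    returns the noiseless biexponential decay.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    b = protocol.b_values
    clean = ivim_signal(b, s0, truth.f, truth.d_true, truth.d_star)
    clean = np.broadcast_to(clean, (n_voxels, len(b))).copy()
    if np.isinf(snr):
        return TimeSeries(b, clean, kind="dwi")
    rng = rng_for(seed, "dwi", truth.lesion_id)
    sigma = s0 / snr
    na = max(1, int(protocol.n_averages))
    shape = (na, n_voxels, len(b))
    re = clean[None] + sigma * rng.standard_normal(shape)
    im = sigma * rng.standard_normal(shape)
    return TimeSeries(b, np.sqrt(re**2 + im**2).mean(axis=0), kind="dwi")


def generate_vfa_signals(
    t10_s: float,
    m0: float,
    protocol: AcquisitionProtocol,
    snr: float,
    seed: int,
    n_voxels: int = 1,
) -> np.ndarray:
    """Variable-flip-angle SPGR signals (n_voxels x n_angles), Gaussian noise
    scaled to the largest noiseless signal."""
    clean = np.array([
        spgr_signal(1.0 / t10_s, m0, a, protocol.tr_ms) for a in protocol.flip_angles_deg
    ])
    out = np.broadcast_to(clean, (n_voxels, len(clean))).copy()
    if np.isinf(snr):
        return out
    rng = rng_for(seed, "vfa")
    return out + (clean.max() / snr) * rng.standard_normal(out.shape)


def generate_dce_signal(
    truth: LesionGroundTruth,
    protocol: AcquisitionProtocol,
    aif: AIFModel | None = None,
    snr: float = np.inf,
    seed: int = 0,
    t10_s: float = 1.4,
    m0: float = 1000.0,
    dt_sim_s: float = 1.0,
) -> TimeSeries:
    """Dynamic SPGR signal-time series of the FXR forward chain.

    Gaussian noise with SD = (pre-contrast signal)/snr.  Pre-contrast frames
    are constant in expectation; enhancement is nonnegative for a nonnegative
    AIF.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    aif = aif or default_aif(protocol.n_precontrast * protocol.dt_dynamic_s)
    params = FXRParams(truth.ktrans, truth.ve, truth.tau_i, r10=1.0 / t10_s)
    clean = forward_fxr_signal(params, aif, m0, protocol, dt_sim_s)
    t = protocol.dynamic_times_s
    if np.isinf(snr):
        return TimeSeries(t, clean, kind="dce")
    s_pre = float(np.mean(clean[: protocol.n_precontrast]))
    rng = rng_for(seed, "dce", truth.lesion_id)
    return TimeSeries(t, clean + (s_pre / snr) * rng.standard_normal(clean.shape), kind="dce")


def generate_fmiso_tac(
    truth: LesionGroundTruth,
    if_model: InputFunction | None = None,
    protocol: AcquisitionProtocol | None = None,
    snr: float = np.inf,
    seed: int = 0,
    k3_choice: str = "max",
    dt_s: float = 1.0,
) -> TimeSeries:
    """Frame-averaged FMISO tissue TAC with count-scaled Gaussian noise.

    Frame values are exact time-averages of the compartment model.  Noise is
    proportional Gaussian with SD = activity/snr per frame (fixed relative
    precision, a standard convention for simulated ROI-mean TACs); frames with
    zero activity stay noiseless.  ``k3_choice`` selects the lesion's
    hottest-voxel ("max") or ROI-mean ("mean") trapping rate.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    protocol = protocol or default_pet_protocol()
    if_model = if_model or default_input_function()
    k3 = truth.k3 if k3_choice == "max" else truth.k3_mean
    params = FMISOParams(truth.k1, truth.k2, k3, truth.vb)
    sched = protocol.pet_frame_schedule
    clean = simulate_2tc_frames(params, if_model, sched, dt_s)
    ts = TimeSeries(sched[:, 0], clean, durations=sched[:, 1], kind="pet")
    if np.isinf(snr):
        return ts
    rng = rng_for(seed, "pet", truth.lesion_id, k3_choice)
    sigma = clean / snr
    return TimeSeries(
        sched[:, 0], clean + sigma * rng.standard_normal(clean.shape),
        durations=sched[:, 1], kind="pet",
    )
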