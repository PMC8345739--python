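"""End-to-end orchestration: simulate -> fit -> tabulate -> correlate -> detect.

``run_pipeline`` generates a synthetic lesion cohort, recovers every kinetic
metric by fitting the raw signals (never by copying ground truth), assembles
the lesion x metric table, builds the Spearman significance network, and runs
the spin-glass consensus community detection.  All outputs are plain-text
(CSV/TSV/GraphML/JSON) and fully reproducible from (config, seed).

Only the FDG uptake values (SUL) and tumor volumes, which have no kinetic
forward model in this package, enter the fitted table as direct measurements:
ground truth with multiplicative log-normal measurement noise.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from .core import (
    TimeSeries,
    child_seed,
    default_dce_protocol,
    default_dwi_protocol,
    default_pet_protocol,
    rng_for,
)
from .dce import default_aif, estimate_t10, fit_fxr
from .dwi import fit_ivim
from .network import (
    MetricTable,
    NETWORK_METRICS,
    build_significance_network,
    compare_volumes,
    spearman_matrix,
    write_edge_list,
    write_graphml,
)
from .pet import default_input_function, fit_2tc, fit_input_function
from .spinglass import AnnealingConfig, Partition, consensus_partition

log = logging.getLogger("mmqinet")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "partition_to_dict"]


@dataclass
class PipelineConfig:
    """Cohort, noise, fitting, and analysis settings of the full pipeline."""

    n_lesions: int = ch.DEFAULT_N_LESIONS
    seed: int = ch.DEFAULT_COHORT_SEED
    voxels_per_lesion: int = ch.DEFAULT_VOXELS_PER_LESION
    dce_curves_per_lesion: int = 9
    snr_dwi: float = 50.0
    snr_dce: float = 50.0
    snr_vfa: float = 100.0
    pet_noise_pct: float = 5.0          # peak-frame noise, percent
    t10_s: float = 1.4
    m0: float = 1000.0
    sul_noise_pct: float = 5.0          # direct-measurement jitter for SUL
    volume_noise_pct: float = 3.0
    alpha: float = 0.05
    fdr: bool = False
    include: tuple[str, ...] = NETWORK_METRICS
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)
    output_dir: str = "mmqinet-output"

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["include"] = list(self.include)
        d["annealing"]["seeds"] = (
            list(self.annealing.seeds) if self.annealing.seeds is not None else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ann = d.pop("annealing", {})
        if ann.get("seeds") is not None:
            ann["seeds"] = tuple(ann["seeds"])
        d["include"] = tuple(d.get("include", NETWORK_METRICS))
        return cls(annealing=AnnealingConfig(**ann), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineReport:
    """Everything the pipeline computed, plus per-stage timing."""

    config: PipelineConfig
    truth: pd.DataFrame
    fitted: pd.DataFrame
    rho: pd.DataFrame
    p: pd.DataFrame
    volume_test: dict
    network: object
    partition: Partition
    recovery: pd.DataFrame
    timings_s: dict
    failures: dict


#: metric -> ground-truth column used for the recovery summary
_RECOVERY_PAIRS = [
    ("ADC", "ADC"), ("D", "D"), ("D*", "D*"), ("f", "f"),
    ("Ktrans", "Ktrans"), ("ve", "ve"), ("tau_i", "tau_i"),
    ("K1", "K1"), ("k3max", "k3max"), ("k3mean", "k3mean"), ("DV", "DV"),
]


def _recovery_summary(truth: pd.DataFrame, fitted: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for m, tcol in _RECOVERY_PAIRS:
        t = truth[tcol].to_numpy(float)
        f = fitted[m].to_numpy(float)
        rel = (f - t) / t
        rows.append({
            "metric": m,
            "median_rel_error": float(np.median(np.abs(rel))),
            "bias": float(np.mean(rel)),
            "n": len(t),
        })
    return pd.DataFrame(rows).set_index("metric")


def run_pipeline(config: PipelineConfig | None = None, write: bool = True) -> PipelineReport:
    """Run the full chain; optionally write all outputs to ``output_dir``."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    failures: dict[str, int] = {"dwi": 0, "dce": 0, "pet": 0, "t10": 0}

    dwi_prot = default_dwi_protocol()
    dce_prot = default_dce_protocol()
    pet_prot = default_pet_protocol()
    if_true = default_input_function()
    aif = default_aif(dce_prot.n_precontrast * dce_prot.dt_dynamic_s)
    sched = pet_prot.pet_frame_schedule

    t0 = time.perf_counter()
    lesions = ch.sample_ground_truth(config.n_lesions, seed=config.seed)
    truth = ch.ground_truth_table(lesions)
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulated %d lesions in %.2fs", len(lesions), timings["simulate"])

    # image-based input function: fit the triphasic model to a noisy blood TAC
    t0 = time.perf_counter()
    blood_clean = if_true.frame_means(sched[:, 0], sched[:, 1])
    if np.isinf(config.pet_noise_pct) or config.pet_noise_pct == 0:
        blood_noisy = blood_clean.copy()
    else:
        rngb = rng_for(config.seed, "blood-tac")
        i_pk = int(np.argmax(blood_clean))
        sig0 = blood_clean[i_pk] * config.pet_noise_pct / 100.0
        blood_noisy = blood_clean + sig0 * np.sqrt(sched[i_pk, 1] / sched[:, 1]) * rngb.standard_normal(len(blood_clean))
    if_fit = fit_input_function(TimeSeries(sched[:, 0], blood_noisy, durations=sched[:, 1]))
    pet_snr = np.inf if config.pet_noise_pct == 0 else 100.0 / config.pet_noise_pct

    rows = []
    for les in lesions:
        # ---- DWI: voxelwise mono + IVIM fits, ROI means ------------------
        dwi_sig = ch.generate_dwi_signal(
            les, dwi_prot, config.voxels_per_lesion, config.snr_dwi,
            seed=config.seed,
        )
        fits = []
        for v in range(config.voxels_per_lesion):
            fit = fit_ivim(TimeSeries(dwi_prot.b_values, dwi_sig.values[v], kind="dwi"))
            if not fit.converged:
                failures["dwi"] += 1
            fits.append(fit)
        adc = float(np.mean([f.adc for f in fits]))
        d = float(np.mean([f.d_true for f in fits]))
        dstar = float(np.mean([f.d_star for f in fits]))
        fperf = float(np.mean([f.f for f in fits]))

        # ---- DCE: per-lesion T10 then FXR fits of replicate curves -------
        vfa = ch.generate_vfa_signals(
            config.t10_s, config.m0, dce_prot, config.snr_vfa,
            seed=child_seed(config.seed, "vfa", les.lesion_id),
        )[0]
        t10_hat, _, t10_flag = estimate_t10(vfa, dce_prot.tr_ms, np.array(dce_prot.flip_angles_deg))
        if t10_flag != "ok":
            failures["t10"] += 1
            t10_hat = config.t10_s
        kts, ves, tis = [], [], []
        for v in range(config.dce_curves_per_lesion):
            sig = ch.generate_dce_signal(
                les, dce_prot, aif, config.snr_dce,
                seed=child_seed(config.seed, "dce", les.lesion_id, v),
                t10_s=config.t10_s, m0=config.m0,
            )
            fx = fit_fxr(sig, aif, t10_hat, dce_prot)
            if not fx.converged:
                failures["dce"] += 1
            kts.append(fx.ktrans)
            ves.append(fx.ve)
            tis.append(fx.tau_i)
        ktrans, ve, tau_i = float(np.mean(kts)), float(np.mean(ves)), float(np.mean(tis))

        # ---- PET: ROI-mean and hottest-voxel TACs ------------------------
        tac_mean = ch.generate_fmiso_tac(les, if_true, pet_prot, pet_snr,
                                         seed=config.seed, k3_choice="mean")
        tac_max = ch.generate_fmiso_tac(les, if_true, pet_prot, pet_snr,
                                        seed=config.seed, k3_choice="max")
        fit_mean = fit_2tc(tac_mean, if_fit)
        fit_max = fit_2tc(tac_max, if_fit)
        failures["pet"] += int(not fit_mean.converged) + int(not fit_max.converged)
        blood_late = blood_noisy[-1]
        tbr_mean = float(tac_mean.values[-1] / blood_late)
        tbr_max = float(tac_max.values[-1] / blood_late)

        # ---- direct measurements (no kinetic model): SUL, volumes --------
        rng = rng_for(config.seed, "direct", les.lesion_id)
        jit = lambda x, pct: float(x * np.exp((pct / 100.0) * rng.standard_normal()))
        rows.append({
            "lesion_id": les.lesion_id,
            "Vt-PET": jit(les.vol_pet, config.volume_noise_pct),
            "Vt-MRI": jit(les.vol_mri, config.volume_noise_pct),
            "ADC": adc, "D": d, "D*": dstar, "f": fperf,
            "Ktrans": ktrans, "ve": ve, "tau_i": tau_i,
            "kep": ktrans / ve,
            "SULmax": jit(les.sul_max, config.sul_noise_pct),
            "SULmean": jit(les.sul_mean, config.sul_noise_pct),
            "K1": fit_mean.k1, "k3max": fit_max.k3, "k3mean": fit_mean.k3,
            "DV": fit_mean.dv, "TBRmax": tbr_max, "TBRmean": tbr_mean,
        })
    timings["fit"] = time.perf_counter() - t0
    log.info("fitted cohort in %.2fs (failures: %s)", timings["fit"], failures)

    fitted = pd.DataFrame(rows).set_index("lesion_id")
    table = MetricTable(fitted)

    t0 = time.perf_counter()
    rho, p, _ = spearman_matrix(table)
    w_stat, w_p, w_flag = compare_volumes(
        fitted["Vt-PET"].to_numpy(), fitted["Vt-MRI"].to_numpy()
    )
    net = build_significance_network(rho, p, config.include, config.alpha, fdr=config.fdr)
    timings["correlate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    part = consensus_partition(net, config.annealing)
    timings["detect"] = time.perf_counter() - t0
    log.info("network: %d edges; partition: %d communities (H=%.4f)",
             net.number_of_edges(), part.n_communities, part.hamiltonian)

    recovery = _recovery_summary(truth, fitted)
    report = PipelineReport(
        config=config, truth=truth, fitted=fitted, rho=rho, p=p,
        volume_test={"statistic": w_stat, "p": w_p, "flag": w_flag},
        network=net, partition=part, recovery=recovery,
        timings_s=timings, failures=failures,
    )
    if write:
        _write_report(report)
    return report


def partition_to_dict(part: Partition) -> dict:
    d = {
        "assignment": part.assignment,
        "n_communities": part.n_communities,
        "hamiltonian": part.hamiltonian,
        "seed": part.seed,
    }
    if part.stability is not None:
        d["stability"] = [[round(float(v), 6) for v in row] for row in part.stability]
        d["stability_nodes"] = list(part.nodes)
    return d


def _write_report(report: PipelineReport) -> None:
    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.config.to_yaml(out / "config.yaml")
    report.truth.to_csv(out / "ground_truth.csv", float_format="%.10g")
    report.fitted.to_csv(out / "metrics_fitted.csv", float_format="%.10g")
    report.rho.to_csv(out / "spearman_rho.csv", float_format="%.10g")
    report.p.to_csv(out / "spearman_p.csv", float_format="%.10g")
    write_graphml(report.network, out / "network.graphml")
    write_edge_list(report.network, out / "network_edges.tsv")
    (out / "partition.json").write_text(
        json.dumps(partition_to_dict(report.partition), indent=2, sort_keys=True) + "\n"
    )
    report.recovery.to_csv(out / "recovery.csv", float_format="%.6g")
    summary = {
        "volume_wilcoxon": report.volume_test,
        "n_edges": report.network.number_of_edges(),
        "n_communities": report.partition.n_communities,
        "hamiltonian": report.partition.hamiltonian,
        "failures": report.failures,
        
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
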