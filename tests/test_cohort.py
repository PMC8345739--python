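"""Synthetic-cohort generator: copula calibration, marginals, determinism,
and the three forward signal models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmqinet import cohort, core, dce, pet
from mmqinet.core import TABLE1_MARGINALS

from conftest import reference_lesion


# --------------------------------------------------------------------------
# copula machinery
# --------------------------------------------------------------------------

def _pair_spec(rho: float) -> cohort.CorrelationSpec:
    return cohort.CorrelationSpec(
        ("ADC", "D"), np.array([[1.0, rho], [rho, 1.0]]),
        np.array([0.93e-3, 0.67e-3]), np.array([0.14e-3, 0.13e-3]),
    )


def test_identity_spec_gives_independent_metrics():
    names = ("ADC", "D", "f", "Ktrans", "ve", "K1")
    spec = cohort.CorrelationSpec(
        names, np.eye(6),
        np.array([TABLE1_MARGINALS[m][0] for m in names]),
        np.array([TABLE1_MARGINALS[m][1] for m in names]),
    )
    t = cohort.sample_metric_table(spec, 10_000, seed=7)
    emp = stats.spearmanr(t.values).statistic
    assert np.abs(emp - np.eye(6)).max() < 0.05


@pytest.mark.parametrize("target", [-0.6, 0.3, 0.95])
def test_copula_calibration_recovers_target_spearman(target):
    """Monte-Carlo check of the 2 sin(pi rho/6) latent calibration."""
    t = cohort.sample_metric_table(_pair_spec(target), 5_000, seed=42)
    emp = stats.spearmanr(t["ADC"], t["D"]).statistic
    assert abs(emp - target) < 0.02


def test_marginals_match_published_summary():
    spec = cohort.default_correlation_spec()
    t = cohort.sample_metric_table(spec, 5_000, seed=11)
    # log-normal positive rate: mean within 3 SE
    m, s = TABLE1_MARGINALS["Ktrans"]
    assert abs(t["Ktrans"].mean() - m) < 3 * s / np.sqrt(5_000)
    # logit-normal fractions: mean and SD both moment-matched
    for name in ("f", "ve"):
        m, s = TABLE1_MARGINALS[name]
        assert abs(t[name].mean() - m) < 3 * s / np.sqrt(5_000)
        assert abs(t[name].std() - s) < 0.1 * s
        assert t[name].between(0, 1).all()


def test_psd_repair_handles_full_published_matrix():
    """The full 18-metric latent matrix is mildly non-PSD; repair keeps the
    sampled rank structure close to target."""
    from mmqinet.network import load_published_spearman

    rho, _, _ = load_published_spearman()
    names = tuple(rho.index)
    means = np.array([TABLE1_MARGINALS.get(m, (1.0, 0.3))[0] for m in names])
    sds = np.array([TABLE1_MARGINALS.get(m, (1.0, 0.3))[1] for m in names])
    latent = cohort.spearman_to_latent(rho.to_numpy())
    assert np.linalg.eigvalsh(latent).min() < 0  # repair path is exercised
    spec = cohort.CorrelationSpec(names, rho.to_numpy(), means, sds)
    t = cohort.sample_metric_table(spec, 4_000, seed=3)
    emp = stats.spearmanr(t.values).statistic
    iu = np.triu_indices(len(names), 1)
    assert np.abs(emp - rho.to_numpy())[iu].max() < 0.06


def test_grossly_non_psd_target_raises_with_eigenvalue():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    with pytest.raises(ValueError, match="eigenvalue"):
        cohort.repair_correlation(cohort.spearman_to_latent(bad))


def test_cohort_is_deterministic_and_respects_invariants():
    a = cohort.sample_ground_truth(12, seed=99)
    b = cohort.sample_ground_truth(12, seed=99)
    ta, tb = cohort.ground_truth_table(a), cohort.ground_truth_table(b)
    pd.testing.assert_frame_equal(ta, tb)
    for les in a:
        assert les.d_star > les.d_true
        assert les.dv == pytest.approx(les.k1 / les.k2, rel=1e-14)
        assert 0 < les.ve < 1 and 0 <= les.f < 1 and 0 <= les.vb <= 0.2
    assert not ta.equals(cohort.ground_truth_table(cohort.sample_ground_truth(12, seed=100)))


# --------------------------------------------------------------------------
# DW signal generator
# --------------------------------------------------------------------------

def test_dwi_generator_noiseless_matches_models(lesion, dwi_protocol):
    b = dwi_protocol.b_values
    # f -> 0 degenerates to the monoexponential decay
    mono = reference_lesion(d_true=0.93e-3, f=1e-15)
    s = cohort.generate_dwi_signal(mono, dwi_protocol, 1, np.inf, 0).values[0]
    assert s == pytest.approx(1000.0 * np.exp(-b * 0.93e-3), rel=1e-12)
    # biexponential attenuation at b=2000 equals the closed form
    s = cohort.generate_dwi_signal(lesion, dwi_protocol, 1, np.inf, 0).values[0]
    expected = 0.16 * np.exp(-2000 * 9.02e-3) + 0.84 * np.exp(-2000 * 0.67e-3)
    assert s[-1] / s[0] == pytest.approx(expected, rel=1e-12)


def test_dwi_noise_calibration_single_average(lesion):
    """Per-excitation semantics: b=0 SD relative to S0 equals 1/snr (NA=1)."""
    prot = core.AcquisitionProtocol(b_values=core.DWI_B_VALUES, n_averages=1)
    sig = cohort.generate_dwi_signal(lesion, prot, 2000, 50.0, seed=5)
    sd = sig.values[:, 0].std() / 1000.0
    assert abs(sd - 1 / 50) < 0.1 * (1 / 50)


def test_dwi_two_averages_reduce_noise(lesion, dwi_protocol):
    assert dwi_protocol.n_averages == 2
    sig = cohort.generate_dwi_signal(lesion, dwi_protocol, 2000, 50.0, seed=5)
    sd = sig.values[:, 0].std() / 1000.0
    assert abs(sd - 1 / (50 * np.sqrt(2))) < 0.1 / (50 * np.sqrt(2))


# --------------------------------------------------------------------------
# DCE signal generator
# --------------------------------------------------------------------------

def test_dce_zero_aif_gives_flat_precontrast_signal(lesion, dce_protocol):
    zero = dce.AIFModel(form="measured",
                        times_s=np.array([0.0, 1e4]), cp_mm=np.array([0.0, 0.0]))
    sig = cohort.generate_dce_signal(lesion, dce_protocol, zero, np.inf, 0)
    assert np.ptp(sig.values) < 1e-9 * sig.values[0]


def test_dce_fxr_reduces_to_fxl_at_fast_exchange(dce_protocol):
    """tau_i -> 0: the water-exchange signal converges to the Tofts/FXL
    forward model to better than 1e-6 relative."""
    fast = reference_lesion(tau_i=1e-6)
    aif = dce.default_aif(48.0)
    p_fxr = dce.FXRParams(fast.ktrans, fast.ve, fast.tau_i, r10=1 / 1.4)
    s_fxr = dce.forward_fxr_signal(p_fxr, aif, 1000.0, dce_protocol)
    s_fxl = dce.forward_fxr_signal(p_fxr, aif, 1000.0, dce_protocol,
                                   fast_exchange_limit=True)
    assert np.max(np.abs(s_fxr - s_fxl) / s_fxl) < 1e-6


def test_dce_enhancement_nonnegative(lesion, dce_protocol):
    sig = cohort.generate_dce_signal(lesion, dce_protocol, snr=np.inf)
    pre = sig.values[: dce_protocol.n_precontrast].mean()
    assert np.all(sig.values >= pre - 1e-9 * pre)


def test_dce_aif_timebase_mismatch_raises(lesion, dce_protocol):
    short = dce.AIFModel(form="measured",
                         times_s=np.array([0.0, 10.0]), cp_mm=np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="support"):
        cohort.generate_dce_signal(lesion, dce_protocol, short, np.inf, 0)


# --------------------------------------------------------------------------
# PET TAC generator
# --------------------------------------------------------------------------

def test_tac_with_no_extraction_is_blood_volume_only(pet_protocol):
    les = reference_lesion()
    params = pet.FMISOParams(0.0, 0.1, 0.0, les.vb)
    if_model = pet.default_input_function()
    sched = pet_protocol.pet_frame_schedule
    frames = pet.simulate_2tc_frames(params, if_model, sched)
    blood = if_model.frame_means(sched[:, 0], sched[:, 1])
    # the two blood-integral quadratures differ only at the grid level
    assert frames == pytest.approx(les.vb * blood, rel=1e-4, abs=1e-12)


def test_tac_noise_is_proportional(lesion):
    tacs = np.array([
        cohort.generate_fmiso_tac(lesion, snr=20.0, seed=s).values
        for s in range(700)
    ])
    clean = cohort.generate_fmiso_tac(lesion, snr=np.inf).values
    # relative SD at the peak frame matches the requested 5%
    i = int(np.argmax(clean))
    assert abs(tacs[:, i].std() / clean[i] - 0.05) < 0.005
    # pre-bolus zero-activity frames carry no noise
    assert np.all(tacs[:, 0] == 0.0)


def test_tac_determinism(lesion):
    a = cohort.generate_fmiso_tac(lesion, snr=20.0, seed=12).values
    b = cohort.generate_fmiso_tac(lesion, snr=20.0, seed=12).values
    assert np.array_equal(a, b)
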