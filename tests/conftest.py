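"""Shared fixtures: a reference lesion at the published cohort-mean
physiology, and session-scoped Monte-Carlo recovery experiments reused by the
per-module tests and the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

from mmqinet import cohort, core, dce, dwi, pet
from mmqinet.core import TimeSeries


def reference_lesion(**overrides) -> cohort.LesionGroundTruth:
    """Lesion at the published per-metric cohort means."""
    kw = dict(
        lesion_id="REF", adc=0.93e-3, d_true=0.67e-3, d_star=9.02e-3, f=0.16,
        ktrans=0.18, ve=0.32, tau_i=0.670, k1=0.33, k2=0.33 / 0.89,
        k3=0.0087, k3_mean=0.0034, vb=0.05, dv=0.89, tbr=2.0, tbr_mean=1.4,
        sul_mean=5.26, sul_max=8.91, vol_mri=11.41, vol_pet=13.59,
    )
    kw.update(overrides)
    return cohort.LesionGroundTruth(**kw)


@pytest.fixture(scope="session")
def lesion():
    return reference_lesion()


@pytest.fixture(scope="session")
def dwi_protocol():
    return core.default_dwi_protocol()


@pytest.fixture(scope="session")
def dce_protocol():
    return core.default_dce_protocol()


@pytest.fixture(scope="session")
def pet_protocol():
    return core.default_pet_protocol()


def _median_rel(estimates, truth) -> float:
    e = np.asarray(estimates, dtype=float)
    return float(np.median(np.abs((e - truth) / truth)))


# --------------------------------------------------------------------------
# session-scoped recovery experiments (the heavy Monte-Carlo runs)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def adc_recovery(dwi_protocol):
    """500 voxels of monoexponential decay at ADC=0.93e-3, SNR 50."""
    mono = reference_lesion(d_true=0.93e-3, f=1e-12)
    sig = cohort.generate_dwi_signal(mono, dwi_protocol, 500, 50.0, seed=301)
    est = [dwi.fit_adc(TimeSeries(dwi_protocol.b_values, sig.values[v]))[0]
           for v in range(500)]
    return {"median_rel": _median_rel(est, 0.93e-3)}


@pytest.fixture(scope="session")
def ivim_recovery(lesion, dwi_protocol):
    """500 voxels of the biexponential decay at the published truth, SNR 50."""
    sig = cohort.generate_dwi_signal(lesion, dwi_protocol, 500, 50.0, seed=302)
    fits = [dwi.fit_ivim(TimeSeries(dwi_protocol.b_values, sig.values[v]))
            for v in range(500)]
    return {
        "D": _median_rel([f.d_true for f in fits], lesion.d_true),
        "f": _median_rel([f.f for f in fits], lesion.f),
        "D*": _median_rel([f.d_star for f in fits], lesion.d_star),
        "n_flagged": sum(f.flag != "ok" for f in fits),
    }


@pytest.fixture(scope="session")
def t10_recovery(dce_protocol):
    """500 repeats of variable-flip-angle T10 estimation at SNR 100."""
    vfa = cohort.generate_vfa_signals(1.4, 1000.0, dce_protocol, 100.0,
                                      seed=303, n_voxels=500)
    flips = np.array(dce_protocol.flip_angles_deg)
    est = [dce.estimate_t10(vfa[i], dce_protocol.tr_ms, flips)[0] for i in range(500)]
    return {"median_rel": _median_rel(est, 1.4)}


@pytest.fixture(scope="session")
def fxr_recovery(lesion, dce_protocol):
    """200 dynamic curves at the published truth, SNR 50, known T10/AIF."""
    aif = dce.default_aif(dce_protocol.n_precontrast * dce_protocol.dt_dynamic_s)
    kts, ves, tis = [], [], []
    for i in range(200):
        sig = cohort.generate_dce_signal(lesion, dce_protocol, aif, 50.0, seed=400 + i)
        fx = dce.fit_fxr(sig, aif, 1.4, dce_protocol)
        kts.append(fx.ktrans)
        ves.append(fx.ve)
        tis.append(fx.tau_i)
    return {
        "Ktrans": _median_rel(kts, lesion.ktrans),
        "ve": _median_rel(ves, lesion.ve),
        "tau_i": _median_rel(tis, lesion.tau_i),
    }


@pytest.fixture(scope="session")
def pet_recovery(lesion):
    """200 TACs at the published truth, 5% proportional frame noise."""
    if_model = pet.default_input_function()
    k1s, dvs, k3s = [], [], []
    for i in range(200):
        tac = cohort.generate_fmiso_tac(lesion, if_model, snr=20.0,
                                        seed=600 + i, k3_choice="max")
        fit = pet.fit_2tc(tac, if_model)
        k1s.append(fit.k1)
        dvs.append(fit.dv)
        k3s.append(fit.k3)
    return {
        "K1": _median_rel(k1s, lesion.k1),
        "DV": _median_rel(dvs, lesion.dv),
        "k3": _median_rel(k3s, lesion.k3),
    }
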