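# Methods

This note documents the models implemented in `mmqinet`, the assumptions and
default parameters behind the synthetic cohort, the numerical choices in the
fitting and optimization code, and the limits of what the test suite
demonstrates.

## The analysis in one paragraph

Each lesion carries up to 18 quantitative imaging (QI) metrics: PET and MRI
tumor volumes; ADC and the IVIM triplet (D, D*, f) from DW-MRI; Ktrans, ve,
τi and kep from FXR DCE-MRI; SULmax/SULmean from static FDG PET; and K1,
k3max/k3mean, DV, TBRmax/TBRmean from dynamic FMISO PET.  Lesion-level
metric values are correlated pairwise (Spearman, pairwise-complete,
two-sided t-approximation p-values), pairs with p < 0.05 become signed,
ρ-weighted edges of an undirected network over a 16-metric inclusion list
(kep and the PET volume are excluded), and a signed spin-glass Hamiltonian
minimized by simulated annealing partitions the network into communities of
co-varying metrics.

## Kinetic models

### DW-MRI

Monoexponential: `S(b) = S0 exp(-b·ADC)`; IVIM:
`S(b) = S0[f exp(-b·D*) + (1-f) exp(-b·D)]`, with D the true (tissue)
diffusion coefficient, D* the pseudo-diffusion coefficient of capillary
blood, and f the perfusion fraction.  ADC is reported from a fit to all ten
b-values.  The IVIM fit is segmented-initialized: a weighted log-linear fit
of b ≥ 200 s/mm² gives D and the perfusion-free intercept, f follows from
the intercept gap at b = 0, then all four parameters are refined by bounded
nonlinear least squares on the magnitude signal (no Rician likelihood —
plain least squares is the fitting convention this pipeline mirrors).
Bounds D ∈ [1e-5, 4e-3], D* ∈ [3e-3, 0.1] mm²/s place the two boxes apart
so the compartments cannot swap; f ∈ [0, 1].  The b ≥ 200 s/mm² threshold
is standard IVIM practice.  Non-positive samples are excluded before the log
transform; constant signal is clamped at the ADC = 0 boundary and flagged.

### DCE-MRI (FXR / shutter-speed)

T10 is estimated per voxel from the three-flip-angle SPGR series
(5°/15°/30°, TR 7 ms) via the linearized S/sin α vs S/tan α regression,
refined by nonlinear least squares; angle-independent signals and
non-physical slopes are flagged rather than fitted.

The tissue concentration follows the standard Tofts model (convolution of
the AIF with `Ktrans·exp(-kep t)`, kep = Ktrans/ve).  Water exchange enters
through the two-site exchange system between the intracellular space (ICS)
and the extravascular extracellular space (EES), assuming a negligible
vascular water pool: the observed longitudinal rate is the smaller
eigenvalue

    R1t = ½[(R1i + kie + R1e + kei) − √((R1i + kie − R1e − kei)² + 4 kie kei)]

with R1e = R10e + r1·Ct/ve, kie = 1/τi, and kei = kie(1−ve)/ve from
population balance of the two water pools.  R1i and R10e are both set to
the pre-contrast tissue rate R10 (the EES pre-contrast rate is not
separately identifiable); r1 = 3.7 s⁻¹mM⁻¹ is a standard Gd-chelate
relaxivity at 3 T and is configurable.  As τi → 0 this reduces to the
fast-exchange limit R1t = R10 + r1·Ct, which is exactly the Tofts/FXL
signal model — the fit uses that limit as its seed.

The dynamic signal is SPGR, `S = M0 sin α (1−E1)/(1−E1 cos α)`,
E1 = exp(−TR·R1t).  M0 is calibrated per curve from the pre-contrast frames
given T10, so the fit estimates exactly (Ktrans, ve, τi) with bounds
Ktrans ∈ [1e-4, 2] min⁻¹, ve ∈ [0.01, 0.99], τi ∈ [0.05, 3] s, from three
starts (FXL seed plus two perturbations); the best residual wins.  Zero
enhancement drives Ktrans to its lower bound and is flagged.

**AIF.** The default synthetic AIF is biexponential with a dominant fast
component — dose 0.1 mmol/kg, amplitudes (24, 4.8) kg/L, decay rates
(3.0, 0.0111) min⁻¹, bolus arrival at the end of the pre-contrast block —
i.e. a carotid-like curve peaking near 2.9 mM.  A realistic first-pass
concentration matters scientifically: the water-exchange attenuation that
makes τi identifiable is only appreciable when r1·Ct/ve transiently rivals
the exchange rates, so a peakless washout-only AIF would render τi (and to
a lesser degree ve) practically unidentifiable at realistic noise.  A
sampled ("measured") AIF is accepted everywhere an analytic one is.

### Dynamic FMISO PET

Irreversible one-plasma two-tissue compartment model with blood volume:

    dC1/dt = K1 Cp − (k2+k3) C1,   dC2/dt = k3 C1,
    C_tissue = (1−vb)(C1+C2) + vb·Cwb

K1 is delivery (perfusion), k3 irreversible trapping (the hypoxia
surrogate), DV = K1/k2 the distribution volume of unbound tracer.  The
whole-blood curve equals the image-derived input function (a jugular ROI is
whole blood) up to a configurable scale.  The input function is triphasic:
zero before bolus arrival, linear rise to the peak, then three decaying
exponentials continuous at the peak; defaults peak at 25 kBq/mL at 50 s
with amplitudes (15, 6, 4) and rates (0.02, 0.002, 1e-5) s⁻¹.  Frame values
are exact time-averages of the model over each frame (see Numerics).
Rate bounds: K1, k2 ∈ [1e-3, 2] min⁻¹, k3 ∈ [0, 0.05] min⁻¹, vb ∈ [0, 0.2].
TBR is the tissue/blood activity ratio at the ~160-min static frame; the
max/mean variants arise from the hottest-voxel vs ROI-mean trapping rate.
SUL uses James lean body mass (male 1.10W − 128(W/H)², female
1.07W − 148(W/H)²; W kg, H cm).

## Synthetic cohort

The generator's purpose is parameter-recovery testing with a realistic
between-lesion correlation structure, not anatomical realism.

**Rank structure.** A Gaussian copula imposes a target Spearman matrix: the
target ρS is mapped to the latent Pearson r = 2 sin(πρS/6), the latent
matrix is repaired to PSD by eigenvalue clipping at 1e-8 plus diagonal
renormalization (targets with eigenvalues below −0.1 are rejected as
inconsistent rather than silently repaired), and uniform scores are pushed
through the marginal quantile functions.  Spearman correlations survive the
monotone marginal transforms exactly, so the calibration is checked directly
by Monte Carlo (±0.02 at n = 5000).

**Marginals.** Log-normal for strictly positive rates, times and volumes;
logit-normal for fractions (f, ve, vb); both moment-matched to the
published per-metric mean ± SD (log-normal in closed form, logit-normal by
Gauss–Hermite quadrature and root finding).  Default cohort: 27 lesions,
100 voxels per lesion, seed 20210803.

**Derived vs sampled metrics.** The copula samples the 14 metrics that are
free physiology (volumes, D, D*, f, Ktrans, ve, τi, SUL, K1, k3max, k3mean,
DV); everything the forward models determine is *derived* so the ground
truth stays self-consistent: ADC from a noiseless monoexponential fit of
the lesion's biexponential decay, kep = Ktrans/ve, k2 = K1/DV, and the TBRs
from the noiseless PET forward model.  Consequences worth knowing: the
ADC–D correlation (~0.95) emerges from the physics rather than the copula,
and the derived TBR means sit somewhat above the published summary values —
an irreversible trapping model with the published rates cannot produce a
160-min TBRmean as low as 1.29, since the trapped integral alone contributes
more.  vb is sampled independently (logit-normal, 0.05 ± 0.02); it is not
part of the published correlation table.

**Noise models.**

- DWI: Rician (magnitude MRI), channel SD = S0/snr per excitation, averaged
  over the protocol's NA = 2 signal averages (part of the acquisition
  protocol).  snr therefore refers to a single excitation; the emitted
  image SNR is √2 higher.
- DCE: additive Gaussian on signal, SD = (pre-contrast signal)/snr.
- PET: proportional Gaussian per frame, SD = activity/snr ("5% noise" means
  5% of each frame value), zero-activity frames noiseless.  Fixed per-frame
  relative precision is a recognized convention for simulated ROI-mean TACs;
  the 2TC fit weights residuals by the matching inverse variance (1/activity,
  floored at 2% of the peak).  A count-limited model (variance ∝
  activity/duration) was considered and rejected: anchored at 5% peak-frame
  noise it makes the early 5-s frames so noisy that K1 becomes
  fundamentally imprecise (Cramér–Rao median error ≥ 10–13% regardless of
  estimator), which does not reflect the per-frame precision of ROI-mean
  TACs over hundreds of voxels.
- SUL and tumor volumes have no kinetic forward model in this package and
  enter the fitted table as direct measurements: truth times log-normal
  jitter (5% and 3% by default).

## Numerics

- **Convolutions.** All exponential-kernel convolutions use an exact
  recursion for piecewise-linear inputs (`expconv_plinear`): per-step
  integrals in closed form (expm1-guarded, with series fallbacks below
  κh = 1e-5), chained by a C-level IIR filter on uniform grids.  The only
  approximation anywhere is the linear interpolation of the input between
  grid nodes.  DCE forward/fit grids default to 1 s steps; PET to 1 s with
  all frame boundaries required to be grid multiples.  Oracle tests run at
  0.05 s against closed-form exponential-input solutions and agree to
  <1e-6 relative.
- **PET frame averages.** Exact integrals, not sub-sampling: with
  P = ∫Cp, the ODE identity ∫C1 = (K1·P − C1)/(k2+k3) and its second
  integral give frame averages of C1, C2 and the blood term in closed form
  at the grid nodes.
- **Spin-glass Hamiltonian.** Signed Reichardt–Bornholdt with separate
  configuration null models per sign layer, γ₊ = γ₋ = 1 by default;
  couplings include null-model terms on non-edges within each layer.  Edge
  weights are the signed ρ (an unweighted ±1 mode is a config flag).  The
  all-singleton partition scores exactly 0.
- **Annealing.** Single-spin-flip Metropolis over q_max = 25 Potts states,
  geometric cooling 1.0 → 0.01 at 0.99 with 50 sweeps per temperature,
  compiled with numba and seeded explicitly (bit-reproducible); the best
  state visited is kept and finished with a strict-improvement greedy
  polish, so the reported energy can never fall below the true minimum and
  never exceeds the initial state's energy.  Consensus runs 100 restarts
  (seeds 1..100 by default), returns the best-energy partition (ties break
  toward the lowest seed) plus the co-assignment frequency matrix.
  Communities are renumbered by smallest contained node index.  Graphs of
  ≤ 12 nodes can be solved exactly by set-partition enumeration
  (restricted-growth strings); the annealer is validated against that
  oracle on random signed 8-node graphs.
- **Statistics.** Spearman p-values use the two-sided t approximation
  t = ρ√((n−2)/(1−ρ²)) — the convention of mainstream software at n = 27
  — with an exact permutation option for n ≤ 9 used as a test oracle.  No
  multiple-testing correction by default (the analysis thresholds raw
  p < 0.05); Benjamini–Hochberg is available behind a flag.  Wilcoxon
  signed-rank drops zero differences and midranks ties.  Constant columns
  yield undefined ρ, are flagged, and never become network edges.

## Packaged fixture

`data/published_spearman_rho.csv` / `..._significant.csv` hold the published
18-metric lesion-cohort rank-correlation matrix (n = 27) and its
significance flags.  The flags coincide exactly with the n = 27
t-approximation thresholded at 0.05 (verified by a test).  Counting
significant entries among the 16 network metrics gives **37 edges** with
degree(DV) = 9, degree(Ktrans) = 7, degree(K1) = 6; the source text prints
"33 edges" and degree(DV) = 8 without stating a pruning rule.  The package
reports what the matrix itself implies; the Ktrans and K1 degrees are
consistent under both readings.  One further transcription note: the source
text quotes f–k3max as ρ = −0.40 while its table prints −0.45; the fixture
follows the table.

## Test-suite problem sizes

Monte-Carlo recovery experiments run at 500 voxels (DWI, T10) and 200
curves (DCE, PET) per condition; copula calibration at n = 5000–10000;
annealer-vs-enumeration at 50 random 8-node graphs; the full
simulate-and-fit chain at 27 lesions with reduced per-lesion voxel counts,
and the 50-seed sign-pattern property on sampled ground-truth tables.
These sizes make the suite complete in a couple of minutes on one CPU while
keeping Monte-Carlo error well below the tolerances tested.

## What passing tests do and do not show

The recovery tests demonstrate that the estimators are correct and
efficient *under the generator's assumptions*: single-compartment voxels,
a known (or well-fitted) input function shared by forward and inverse
models, Gaussian/Rician noise of the stated level, no motion, no partial
volume, no B1 inhomogeneity, rigid inter-modality alignment by
construction.  Real data violate all of these to varying degrees; in
particular the DCE fit inherits whatever error the AIF extraction carries,
and PET K1 precision depends strongly on the early-frame noise of the
actual scanner and ROI size.  The network and community stages are exact
graph/statistics computations and carry over to real tables directly.

## Known limitations

- No extended-Tofts vascular term in the DCE model (vp ≈ 0 is assumed both
  in the concentration model and in the water-exchange balance).
- The FMISO model is irreversible (no k4); DV is the reversible-compartment
  convention K1/k2.
- SUL/FDG has no kinetic model; it is treated as a measured quantity.
- The triphasic input-function parameterization (linear rise, shared peak
  time, continuity at the peak) is a documented convention; other equally
  valid parameterizations exist.
- Voxelwise parametric maps at clinical matrix sizes, image rendering,
  motion/partial-volume simulation and B1 correction are out of scope.
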