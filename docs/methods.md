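# Methods

## Model structure

The model is a three-state cohort model — stable disease (SD), progressed
disease (PD), death — evaluated on a 21-day cycle (the treatment
administration interval) over a 10-year horizon, i.e.
`ceil(10 × 365.25 / 21) = 174` cycles. State occupancy is obtained by
partitioned survival rather than an explicit transition matrix:

    occ_SD(t)   = S_PFS(t)
    occ_dead(t) = 1 − S_OS(t)
    occ_PD(t)   = S_OS(t) − S_PFS(t)

Two endpoint curves identify occupancy but not the SD→death vs SD→PD
split; the partition reproduces both curves exactly, which is the standard
resolution, and the per-cycle transition probabilities implied by the trace
(`p_leave_SD`, `p_die_overall`) are exposed separately for reporting. No
half-cycle correction is applied by default; state time accrues at
start-of-cycle occupancy, so a cohort absorbed after cycle 0 still accrues
exactly one cycle-length of time.

Because PFS and OS are adjusted by independent hazard ratios, the adjusted
curves can cross (PFS above OS), particularly in the extrapolated tail when
the two endpoints select families with different tail behaviour. Crossings
up to 0.05 in occupancy are clamped (PD floored at 0, the deficit absorbed
by SD) with a logged warning; larger violations raise a model-consistency
error, since they indicate inconsistent survival inputs rather than
digitization or extrapolation noise.

## Survival inputs

The reference (chemotherapy) arm is estimated from digitized KM
coordinates plus numbers-at-risk tables. Reconstruction of pseudo-IPD
follows the interval-allocation approach: within each risk-table interval
the number of censorings is guessed, spread uniformly, events are placed
at the digitized drops so that the running KM product tracks the curve,
and the guess is adjusted until the implied at-risk count matches the next
risk-table entry. One convention matters and is easy to get wrong: the
digitizer reads the step-function value *at* each grid time (so a drop
recorded at a risk time reflects events just before it), while at-risk
counts use `time ≥ risk_time`; event allocation therefore covers grid
points in `(risk_time_k, risk_time_{k+1}]`. Ties between an event and a
censoring at the same time place the censoring after the event. If the
risk table is absent, an events-only reconstruction (no censoring before
the last coordinate) is performed with a warning. On noise-free synthetic
input the KM curve of the reconstruction matches the digitized curve to
within 0.005 sup-norm; the advertised tolerance for trial-sized input
(n = 300) is 0.02.

Five parametric families are fitted to the reconstructed records by
right-censored maximum likelihood, with the parameterizations

| family       | S(t)                          | parameters |
|--------------|-------------------------------|------------|
| exponential  | exp(−λt)                      | λ > 0      |
| Weibull      | exp(−(t/σ)^k)                 | k, σ > 0   |
| log-normal   | 1 − Φ((ln t − μ)/σ)           | μ ∈ ℝ, σ > 0 |
| log-logistic | 1 / (1 + e^θ t^κ)             | θ ∈ ℝ, κ > 0 |
| Gompertz     | exp(−(a/b)(e^{bt} − 1))       | a > 0, b ∈ ℝ |

Time is in months throughout fitting (KM axes are in months); cycle
conversion happens in the Markov engine. Positive parameters are optimized
on the log scale (Nelder-Mead, 3 starts from moment-based heuristics,
likelihood tolerance 1e-8). A negative Gompertz shape (defective
distribution, survival plateau) is admitted, with the b→0 limit handled
via `expm1`. Selection is by minimal AIC, ties broken by BIC and then the
fixed family order above. Comparator arms apply `S_ref(t)^HR` to the
*selected parametric curve*, not the KM steps, with one HR per endpoint
over the whole horizon.

## Economics

Costs (2022 USD) per cycle: drug acquisition while in SD (treatment until
progression, per-agent caps on treated cycles), routine follow-up and BSC
while in SD, subsequent anticancer therapy and BSC while in PD, and a
one-time terminal-care cost weighted by the new deaths of each cycle
(discounted at the cycle of death). Dose-by-anthropometry uses the
sex-mix-weighted mean weight (69.6 kg male / 59.0 kg female, default mix
0.5) and BSA 1.72 m²; no vial rounding — doses price linearly. The grade
≥3 adverse-event burden (Σ freq × cost; Σ freq × disutility ×
duration/365.25) enters once, undiscounted, at model entry: the published
frequencies are whole-trial incidences, and at cycle 0 discounting is nil
anyway. QALYs weight SD/PD occupancy by `u_SD` (arm-specific) and
`u_PD = 0.70300`; both costs and effects discount at
`(1 + r)^(−k·21/365.25)` with r = 5 %/year.

ICERs are incremental cost over incremental QALYs, comparator minus
reference; dominance labels replace the ratio when ΔQALY and ΔC disagree
in the expected signs, and |ΔQALY| < 1e-12 is treated as indeterminate
rather than divided. An ICER exactly at a WTP bound counts as
cost-effective at that bound (≤ convention). ICER per life-year is also
reported but never used for verdicts. Subgroup analyses rebuild only the
comparator traces with subgroup HRs (falling back to the overall OS HR
when a subgroup reports PFS only), leaving the reference arm unchanged.

## Sensitivity analysis

The one-way DSA varies hazard ratios over their 95 % CIs, the discount
rate over 0–8 %, and every other input ±25 %, one scalar at a time, and
sorts parameters by ICER spread. Per-arm adverse-event cost and disutility
burdens vary through a common multiplier (one tornado bar per arm rather
than one per event). A variation that flips the sign of ΔQALY is flagged
as a dominance switch instead of reporting a ratio.

The PSA draws all parameters independently (no correlations are supplied):
beta for utilities and frequencies, gamma for costs and prices, lognormal
for HRs parameterized from the 95 % CI (μ = ln√(lo·hi),
σ = (ln hi − ln lo)/3.92), otherwise moment-matched to mean = base and
sd = 0.25 × base, aligning the default dispersion with the DSA width. The
discount rate is held fixed in the PSA, as are the fitted reference-curve
parameters (their sampling uncertainty is not propagated; the DSA covers
survival uncertainty through the HRs). Draws whose sampled HR pair pushes
adjusted PFS above adjusted OS beyond the 0.05 tolerance are rejected,
logged and resampled. Acceptability curves report, on a $0–200,000/QALY
grid in $1,000 steps, the fraction of draws in which each of the three
strategies attains the maximal net monetary benefit `QALY·WTP − cost`,
with exact ties split equally; the probabilities sum to one at every grid
point by construction.

## Synthetic study conditions

The generator emulates a second-line trial of the relevant design:
log-logistic reference PFS (θ = −1.896, κ = 1.3; median 4.3 months) and OS
(θ = −4.793, κ = 1.6; median 20 months — the reported magnitude for this
population), 150 patients/arm by default (300/arm where reconstruction
accuracy is being measured), uniform accrual over 12 months with a data
cutoff 30 months after accrual ends (≈ 29 % OS administrative censoring),
comparator arms with PFS HRs 0.72 (doublet) and 0.51 (triplet) and OS HRs
0.79 and 0.82 with log-symmetric 95 % CIs reaching the null (0.62–1.00,
0.67–1.00) — OS data in such interim analyses are immature. PFS and OS are
coupled comonotonically (one shared uniform per patient) and OS floored at
PFS, so progression never postdates death; the true joint dependence is
unidentified by the two marginal curves, and any coupling preserving the
marginals yields the same cohort model. Digitization uses a 1-month grid
and 3-month risk table, mirroring published figure conventions.

The synthetic workbook mirrors the structural layout of a full parameter
table with 2022-USD magnitudes typical of Chinese bid prices and the
published literature: sintilimab 200 mg flat ($1.57/mg), IBI305 15 mg/kg
($0.55/mg), pemetrexed 500 mg/m² / cisplatin 75 mg/m² (4 induction cycles,
pemetrexed maintenance, biologics capped at 35 cycles ≈ 24 months);
PD-state subsequent therapy $600/cycle, BSC $120/cycle, follow-up
$60/cycle, terminal care $1,800 once; u_SD 0.76/0.78/0.78 and u_PD
0.70300; per-arm grade ≥3 AE rows (haematological toxicity for all arms,
immune-related pneumonitis for the sintilimab arms, hypertension and
proteinuria for the bevacizumab-biosimilar arm). These values are
synthetic stand-ins with realistic structure, not the unpublished source
values; consequently the synthetic base case reproduces the *qualitative*
published findings (both comparators cost more and gain ≈ 0.4 QALYs; the
doublet is far cheaper than and marginally more effective than the
triplet; the SD utility and OS HR dominate the tornado; the doublet's
CEAC stays above the triplet's over the whole WTP grid) while its exact
ICERs differ from the published point values.

What passing tests on these conditions do **not** show: robustness to
digitization noise from real figure extraction (the synthetic digitizer is
noise-free on its grid), non-proportional hazards, informative censoring,
treatment discontinuation before progression, or parameter correlations in
the PSA.

## Numerical choices and limitations

- Occupancy conservation is exact by construction (SD defined as
  1 − dead − PD) and asserted to 1e-12.
- KM-reconstruction censoring guesses adjust by the observed at-risk
  mismatch and stop at the first exact match (≤ 50 iterations); an
  interval whose KM drop exceeds what the risk table allows even with zero
  censorings raises an error naming the interval.
- Degenerate PSA dispersions collapse to point masses; a beta request
  outside [0, 1] is a parameter error.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reruns are bit-identical.
- Problem sizes used by the test-suite property checks: n = 300/arm for
  reconstruction accuracy, n = 2000 for parameter recovery, 50 replicates
  of n = 500 for AIC family selection, 10,000 PSA draws.
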