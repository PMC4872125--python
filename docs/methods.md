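# Methods

This note documents the models and procedures implemented in `ebprkit`,
the choices made where the underlying science admits more than one
reasonable realisation, and what the synthetic-data generators do and do
not emulate.

## Batch-cycle stoichiometry

A batch cycle is summarised by endpoint transformation ratios. Deltas are
`|end − start|` of each phase, with liquid analytes (acetate, phosphate)
divided by the phase-mean VSS so that every quantity is per gram of
biomass. Endpoint differencing is the standard convention for EBPR batch
tests, where only initial and final states carry stoichiometric meaning; a
regression-slope alternative (`method="regression"`) is provided for
sensitivity analysis on noisy series. The anaerobic endpoint is the last
anaerobic sample — acetate need not be fully depleted, and ratios always
use the measured acetate delta. Duplicate reactors are averaged at the
ratio level (one ratio per reactor, then the mean), which preserves
per-cycle spread for resampling. Missing analytes propagate as NaN ratios,
never as zeros.

Epoch summaries are the arithmetic mean and (n−1) sample standard
deviation per ratio, skipping NaN cycle values. Full precision is kept
throughout; rounding happens only at report time. Report rounding resolves
exact decimal halves (which arise when averaging 2-decimal measurements,
e.g. a PHB/HAc mean of exactly 0.835) *toward zero*, after snapping the
float to a 9-decimal grid so binary representation error cannot flip a
tie. This matches the convention of the survey report whose table layout
the summary reproduces.

## Anaerobic metabolic models

Constant-prediction models are stored as data (`FIXED_MODELS`): the
TCA-only PAO model, the glycolysis-only PAO model, the published
glycolysis+full-TCA and split-TCA PAO rows, and the GAO model. The
glyoxylate-shunt model is parametric in (α_PAO, f_GLY):

    P/HAc   = α_PAO + (1 − 1/(2+f_GLY))/2
    Gly/HAc = 1/(2+f_GLY)
    PHB/HAc = 8/(6+3 f_GLY)
    PHV/HAc = 2.5/(6+3 f_GLY)

### The glycolysis + full-TCA flux fit

Per C-mol of acetate taken up, the anaerobic network is:

* acetate → acetyl-CoA (activation cost `atp_acetate_activation` +
  fitted transport cost α, ATP/C-mol);
* glycogen *g* → pyruvate (NADH `nadh_glycolysis`·g, ATP
  `atp_glycolysis`·g);
* pyruvate → acetyl-CoA + CO₂ (carbon yield `carbon_pdh`, NADH
  `nadh_pyruvate_ox`) or pyruvate → propionyl-CoA (consumes
  `nadh_propionyl`), the PHV precursor;
* acetyl-CoA → full TCA oxidation (CO₂ + `nadh_tca` reducing equivalents
  per C-mol) or polymerisation to PHB (consumes `nadh_phb`) / PHV
  (propionyl C-fraction `carbon_phv_propionyl`, additional reduction
  demand `nadh_phv`);
* polyphosphate hydrolysis supplies the remaining ATP, 1 ATP per P-mol,
  fixing the predicted P/HAc.

The reducing-equivalent balance is linear in the propionyl flux and is
solved exactly (the propionyl/PHV branch is the redox closure variable);
carbon is conserved identically by construction. The glycogen flux is
pinned to the observed Gly/HAc, since glycogen degradation is measured
directly. Free parameters are the TCA flux and the transport ATP cost α,
estimated by bounded least squares (`scipy.optimize.least_squares`, bounds
f∈[0,1], α∈[0,2], tolerances 1e-14) over the residuals of the four
anaerobic ratios with weights (1, 1, 1, 2) — PHV upweighted because its
magnitude is several-fold smaller than the other ratios. Five fixed
starting values for the TCA fraction make the optimisation deterministic
and multi-modal-safe.

Two headline quantities are reported, as integer percents:

* `f_tca` — C-mol of acetyl-CoA oxidised in the full TCA cycle per C-mol
  of acetate taken up;
* `nadh_share_tca` — TCA-derived reducing equivalents divided by total
  reducing equivalents produced (glycolysis + pyruvate oxidation + TCA).

**Coefficient calibration.** The coefficient table is data, not code, and
every entry is overridable. The defaults are an *effective* table of the
Smolders/Pereira lineage calibrated against two anchors: (i) with zero
TCA flux and the glycogen flux solving the redox balance in closed form
(`glycolysis_only_glycogen`, = 0.5 by default), the network reproduces the
canonical glycolysis-only predictions (P/HAc 0.5, Gly/HAc 0.5, PHB/HAc
4/3); and (ii) fitting the published tropical-plant epoch-mean ratios
reproduces the published TCA flux fractions (9% / 11%) and reducing-power
shares (36% / 53%). Anchor (ii) fixes the effective TCA reducing-
equivalent yield at 2.125 per C-mol acetyl-CoA and the PHV reduction
demand at 0.6 NADH per C-mol; the glycolytic coefficients are the textbook
values (2 NADH + 3 ATP per glucosyl unit to pyruvate, 1 NADH per pyruvate
oxidised, 2 NADH consumed per propionyl-CoA formed, 1 NADPH per PHB
monomer). Treating the TCA yield as effective absorbs bookkeeping
differences (FADH₂ weighting, NADPH-producing steps, unmodelled PH2MV)
that the published balance set resolves internally.

Jackknife standard errors leave one batch cycle out, recompute the epoch
mean and refit; `jackknife_se` implements the generic
`sqrt((n−1)/n · Σ(θ₋ᵢ − mean θ₋ᵢ)²)` estimator for any reduction.

## Community change-point analysis

Counts are rarefied to an even depth by a single multivariate-
hypergeometric draw per sample with a recorded seed (no averaging over
draws), then transformed as `log10(x + 1)`. Only OTUs with nonzero counts
in **all** samples are tested. The step statistic at the known (n1, n2)
split is the two-segment one-way ANOVA F with degrees of freedom
(1, n−2); the reported difference is the second-epoch mean minus the
first-epoch mean of the log-normalised series, so taxa that increase after
the perturbation carry positive differences. Searching over candidate
change points is out of scope — the split is fixed by the design. A
degenerate series (zero within-segment variance with a nonzero step) is
reported at the float tiny-value floor and flagged.

q-values follow the Storey–Tibshirani construction:
`π0(λ) = #{p > λ}/(m(1−λ))` over λ ∈ {0.05, …, 0.95}, smoothed with a
cubic polynomial and evaluated at λ = 0.95, clipped to (0, 1]; below 100
p-values the single-λ estimate at 0.5 is used instead (the smoother is
unstable at small m). `q(p_i) = min_{p_(j) ≥ p_i} π0·m·p_(j)/j`, which is
monotone along sorted p and reduces to Benjamini–Hochberg when π0 = 1.

Fold changes between epochs are ratios of epoch-mean *relative*
abundances (the pseudo-count is a log-domain device only and is never used
here); decreases are reported as factors > 1 with an explicit direction,
and a zero first-epoch mean is flagged undefined rather than reported as
infinite. Taxon aggregation matches the query as an exact rank token of
the lineage string, so unclassified ranks (`g__`) never match named
queries.

`simulate_error_rates` generates stationary AR(1) Gaussian series with an
optional mean step after n1 and reports the rejection rate per
(effect, ρ) cell, vectorised over replicates. At the (4, 6) design the
nominal 5% level is calibrated within ±0.01 at 10⁴ null replicates (the
statistic is exact-F under iid Gaussian noise, so this checks only the
implementation); positive ρ inflates the false-positive rate, which is
the behaviour the design simulations are meant to expose.

## Synthetic data

* **Batch cycles** are piecewise-linear in time within each phase: the
  published surveys report endpoint stoichiometry only, and ratios are
  endpoint-determined, so the within-phase shape is immaterial to every
  quantity this package computes. Defaults (acetate 1.25 C-mmol/L ≈ 15 mg
  C/L, VSS 1.65 g/L, 3 h phases, phosphate 1.3 P-mmol/L) mirror a typical
  lab-scale test on full-scale sludge. Noise is multiplicative Gaussian
  per measurement, clipped at zero. Infeasible targets (glycogen or
  phosphate driven negative) raise rather than silently truncate.
* **OTU tables**: log10 expected abundances are OTU-specific baselines
  (Normal across OTUs, spread `log_baseline_sd`) plus a step of
  `log10(step_factor)` after sample n1 plus stationary AR(1) noise with
  marginal scale `log_noise_sd` (default 0.25; the AR(1) process needs an
  innovation scale and the spec of the emulated survey leaves it free).
  Counts are one multinomial draw of `depth` reads per sample, so column
  sums are exact. Because abundances are renormalised per sample, a
  planted fold change on a *dominant* OTU is compositionally distorted —
  recovery tests use modest baseline spread for that reason, and the same
  caveat applies to real data.
* **Reads** are uniform-random background with concrete realisations of
  the planted IUPAC sites embedded without overlap (random offsets via
  random background splits, random strand). Reads are error-free by
  default; a uniform substitution rate exists to probe the brittleness of
  exact matching. No realistic error profiles, no phylogenetic structure.

Passing recovery tests on these generators demonstrates estimator
correctness under the stated noise models — not robustness to real-data
pathologies (chimeras, copy-number variation, compositional dominance,
primer bias), which are outside the generators' scope.

## In-silico FISH

A read is a carrier of a probe if the probe or its reverse complement
matches exactly (IUPAC degeneracies expanded; `N` in a read matches
nothing). Distinct carrier *reads* are counted — a read matching one
probe twice counts once; a read matching two probes counts for both; probe
mixes count distinct reads matching any member. Counts are normalised to
the designated universal probe per sample, and a zero universal count
flags the sample as undefined rather than producing silent zeros. The
normalised ratio is an abundance proxy uncorrected for 16S copy number;
this is documented, not modelled. A ≤1-mismatch mode exists but is off by
default and excluded from all quantitative checks.

## Problem sizes and determinism

All stochastic steps take explicit seeds and are pure functions of
(spec, seed). The test suite and the acceptance script use desk-scale
sizes chosen by the package: 10⁴ replicates for error-rate calibration,
2×10⁴ reads for planted-abundance recovery, 10³ random instances for the
statistic/oracle equivalence check, 100–300 seeds for Monte-Carlo
recovery of planted ratios. The metabolic-model fit is deterministic
(fixed multi-start grid), so its outputs do not depend on the seed.

## Known limitations

* Kinetic rate estimation (maximum specific uptake rates) is excluded:
  the estimation window is not identifiable from endpoint data.
* The split-TCA and glyoxylate models are predictors only; fitting is
  implemented for the glycolysis + full-TCA network.
* Multi-change-point detection, OTU clustering and phylogenetic metrics
  are out of scope; inputs are assumed already clustered and annotated.
* Probe oligo sequences are user-supplied inputs from probe databases;
  none are bundled.
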