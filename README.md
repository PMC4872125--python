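# ebprkit

Analysis toolkit for enhanced biological phosphorus removal (EBPR)
studies: batch-test stoichiometry, anaerobic PAO/GAO metabolic-model
comparison and flux-balance fitting, step-change statistics on OTU time
series with false-discovery-rate control, and in-silico FISH probe
quantification in shotgun reads.

## Who this is for

EBPR communities remove phosphorus through polyphosphate-accumulating
organisms (PAOs, canonically *Candidatus* Accumulibacter) that cycle
carbon and phosphate across alternating anaerobic/aerobic phases, in
competition with glycogen-accumulating organisms (GAOs, e.g.
Competibacter). Studies of such communities — full-scale plant surveys in
particular — combine three bespoke computations that this package
implements as a tested pipeline:

1. **Stoichiometry.** Anaerobic ratios P/HAc, Gly/HAc, PHB/HAc, PHV/HAc,
   PHA/HAc and aerobic P/PHA, Gly/PHA from batch-cycle time series,
   summarised per operating epoch (mean, s.d.).
2. **Metabolic modelling.** Comparison against the canonical anaerobic
   models (TCA-only, glycolysis-only, glycolysis+full-TCA, split-TCA,
   glyoxylate-shunt, GAO), and a bounded least-squares fit of the
   glycolysis+full-TCA network estimating the fraction *f*TCA of
   acetyl-CoA oxidised anaerobically in the full TCA cycle and the TCA
   share of reducing equivalents, with jackknife standard errors. The fit
   solves the carbon, reducing-equivalent (NADH) and ATP balances of the
   acetate + glycogen network; see `docs/methods.md`.
3. **Community dynamics.** Even-depth rarefaction, log10 pseudo-count
   normalisation, a two-segment ANOVA step-change statistic at the known
   epoch split, and Storey–Tibshirani q-values, plus the simulations that
   calibrate power and the autocorrelation sensitivity of the test.
4. **eFISH.** Exact IUPAC-aware matching of FISH probe / PCR primer
   sequences (and probe mixes) in shotgun reads, normalised to a
   universal probe.

A synthetic-data module generates batch cycles, OTU tables and reads with
planted, recorded truth, so every stage is testable without external
downloads.

## Worked example

The package bundles the per-cycle ratio sets of a ten-event survey of a
full-scale tropical EBPR plant (four cycles under high aeration, six
after an aeration reduction):

```python
from ebprkit.stoichiometry import reference_cycle_ratios, epoch_summary, StoichiometricRatios
from ebprkit.models import fit_pereira

cycles = reference_cycle_ratios()
high = epoch_summary(cycles, "high")
print(high.rounded().loc[["p_per_hac", "gly_per_hac", "phb_per_hac", "phv_per_hac"]])

mean = high.rounded()["mean"]
obs = StoichiometricRatios(p_per_hac=mean["p_per_hac"], gly_per_hac=mean["gly_per_hac"],
                           phb_per_hac=mean["phb_per_hac"], phv_per_hac=mean["phv_per_hac"])
fit = fit_pereira(obs, cycles=[c for c in cycles if c.epoch == "high"])
print(f"f_tca = {fit.f_tca_percent}%  (jackknife SE {fit.se_jackknife['f_tca']:.3f})")
print(f"TCA share of reducing power = {fit.nadh_share_percent}%")
```

prints

```
             mean    sd
p_per_hac    0.89  0.09
gly_per_hac  0.60  0.12
phb_per_hac  0.83  0.34
phv_per_hac  0.11  0.06
f_tca = 9%  (jackknife SE 0.012)
TCA share of reducing power = 36%
```

Read: under high aeration the community released 0.89 P-mol of phosphate
and degraded 0.60 C-mol of glycogen per C-mol of acetate taken up — a
higher P/HAc and lower Gly/HAc than the glycolysis-only PAO model (0.5
and 0.5) predicts. Fitting the glycolysis+full-TCA network attributes 9%
of the acetyl-CoA flux to full-TCA oxidation, supplying 36% of the
anaerobic reducing power; the same fit on the low-aeration epoch gives
11% and 53%. A `fit.predicted` attribute carries the model-side ratios
for comparison with the observations, and `fit.fluxes` the full flux map
(carbon is conserved to < 1e-8 by construction).

## Command line

Each stage is also a subcommand over the same library calls:

```bash
ebprkit simulate --kind otu --out otus.tsv          # synthetic inputs
ebprkit stoichiometry cycle1.csv --out ratios.tsv   # per-cycle ratios
ebprkit fit-models ratios.tsv --out models.tsv      # model comparison + fit
ebprkit changepoint otus.tsv --out table.tsv        # step test + q-values
ebprkit efish reads.fasta probes.fasta --out efish.tsv
```

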