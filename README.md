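# quenchfit

Transient-state kinetic analysis of RNA polymerase transcription elongation:
simulation and global fitting of multi-nucleotide-addition quench-flow time
courses under competing kinetic schemes, kinetic model selection, and
elongation-complex (EC) stability analysis.

## The problem

Eukaryotes express three nuclear RNA polymerases (Pols I, II, III).  Because
Pol I transcription of the rDNA is the rate-limiting step of ribosome
biogenesis, selective Pol I inhibitors such as the small molecule BMH-21 are
candidate anti-cancer agents — but selectivity must be demonstrated
mechanistically.  The sharpest in-vitro readout is transient-state kinetics:
stalled elongation complexes carrying a radiolabeled 10-mer RNA are rapidly
mixed with saturating NTPs in a chemical quenched-flow, quenched at times
from 5 ms to 10 s, and the fraction of signal in each RNA band (10-mer …
19-mer) is followed as the RNA is extended by nine nucleotides.

`quenchfit` is a tested, reusable implementation of the full analysis for
this kind of experiment, aimed at enzymologists working with multi-band
time-course data:

* **Kinetic schemes** — declarative, JSON-serializable first-order networks:
  the irreversible Pol I chain with an intrinsic-nuclease branch (`S1`), its
  extension with off-pathway paused species at the 11-/12-mer (`S2`, the
  BMH-21 mechanism), the reversible Pol II chain with pyrophosphorolysis
  (`S3`), and the Pol III chain with an inactive-subpopulation activation
  step (`S4`).
* **Exact forward model** — the band fractions solve `dp/dt = K p` by matrix
  exponentiation, with a spectral fast path, a stiff-integrator cross-check,
  and the closed-form sequential-decay (Bateman) solution as an independent
  analytic oracle.
* **Global fitting** — one shared parameter set fitted simultaneously to the
  nine product bands with a hybrid genetic-algorithm / damped-least-squares
  optimizer (rates in log space, box bounds, deterministic given a seed);
  replicates are fitted individually and reported as mean ± SD.
* **Model selection** — small-sample-corrected AIC (AICc) between competing
  schemes, plus the diagnostic that historically motivated the pause scheme:
  systematic late-time positive residuals on the 11-/12-mer bands.
* **EC stability** — RNase-protection collapse fractions
  (7-mer / (7-mer + 10-mer)), replicate-averaged curves, an optional
  exponential rise-to-plateau fit, and a condition contrast with an
  "unaffected" verdict.
* **Synthetic data** — a first-class generator reproducing the assay's
  statistical structure (20 log-spaced times over 0.005–10 s, 3 replicates,
  clipped Gaussian band-fraction noise), with scenario truths anchored to
  the reported condition-level features (e.g. mean Pol III addition rate
  49 → 39 s⁻¹ under treatment; > 2-fold slowing of the 13-/14-mer steps of
  Pol I).

The estimators follow the scikit-learn contract
(`GlobalKineticFitter`, `StabilityDecayFitter`: `fit` / `predict` /
`get_params`, fitted attributes with trailing underscores), and module-level
functions (`fit_global`, `compare_schemes`, `analyze_stability`, …) wrap
them.  See `docs/methods.md` for the model, optimizer, and noise-model
details.

## The model in brief

For a scheme with species set S and transitions `i → j` at rate `k_ij`, the
state fraction vector evolves as `dp/dt = K p` with `K[j,i] = k_ij`,
`K[i,i] = −Σ_j k_ij` (columns sum to zero; the nuclease product is an
explicit sink species, so mass is conserved).  A gel band of length L is
`Σ_{species of length L} p` — paused and active complexes co-migrate.  Each
observed rate constant `k_obs,n` is the pseudo-first-order composite rate of
the n-th nucleotide addition at saturating NTP.  Fits minimize the
unweighted squared deviation between observed and modeled band fractions
over bands 11–19 and all time points; schemes are compared by

    AICc = n ln(SSR/n) + 2p + 2p(p+1)/(n−p−1).

## Worked example

Simulate the two Pol III conditions, fit each replicate globally under the
activation scheme, and summarize:

```python
import quenchfit as qf

vehicle = qf.generate_dataset(qf.get_scenario("pol3_vehicle"), seed=1)
treated = qf.generate_dataset(qf.get_scenario("pol3_bmh21"), seed=2)

fit_v = qf.fit_replicates(vehicle.replicates, "S4", qf.FitConfig(seed=0))
fit_t = qf.fit_replicates(treated.replicates, "S4", qf.FitConfig(seed=0))

summary = qf.summarize_kinetics(fit_t, reference=fit_v)
print(f"mean k_obs (vehicle): {qf.summarize_kinetics(fit_v).mean_kobs:.1f} s^-1")
print(f"mean k_obs (BMH-21):  {summary.mean_kobs:.1f} s^-1")
print(f"relative reduction:   {100 * summary.relative_reduction:.1f} %")
print(f"k3 mean +/- SD (vehicle): {fit_v.mean['k3']:.1f} +/- {fit_v.sd['k3']:.1f} s^-1")
```

Output:

```
mean k_obs (vehicle): 49.2 s^-1
mean k_obs (BMH-21):  40.0 s^-1
relative reduction:   18.7 %
k3 mean +/- SD (vehicle): 54.9 +/- 0.7 s^-1
```

The fitted mean addition rate drops from ~49 to ~40 s⁻¹ under treatment
(the generating truths are 49 and 39 s⁻¹, a ~20% reduction): the fit
recovers the modest Pol III inhibition from noisy three-replicate data.
The per-parameter mean ± SD line shows the replicate-aggregation convention
used for every reported rate constant.

The same pipeline is available from the shell:

```sh
quenchfit scenarios
quenchfit simulate --scenario pol1_bmh21 --seed 1 --out data.tsv
quenchfit fit --data data.tsv --scheme S2 --seed 0 --out results/
quenchfit compare --data data.tsv --schemes S1,S2 --seed 0 --out results/
quenchfit stability --data stability.tsv --fit-decay --out results/
```

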