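# Methods

## The kinetic model

`quenchfit` analyzes single-turnover multi-nucleotide-addition experiments:
a stalled elongation complex (EC) carrying a radiolabeled 10-mer RNA is
rapidly mixed with saturating NTPs in a quenched-flow instrument, and the
fraction of total lane signal in each RNA-length band (10-mer through
19-mer) is quantified at ~20 time points spanning 0.005–10 s.  Because NTPs
are saturating and each template position is encoded, every extension step
behaves as a pseudo-first-order process with an observed composite rate
constant `k_obs`.  The state of the system is therefore a probability vector
over a finite set of EC species, and it evolves as a linear first-order
network:

    dp/dt = K p,        p(0) = p0,

where `K` is the mass-action generator built from the scheme topology
(column sums zero; the diagonal carries minus the total outgoing rate).
Four schemes cover the three polymerases and two treatment conditions:

* **S1** (Pol I, vehicle): irreversible chain EC10 → EC11 → … → EC19 with
  per-step rates `k1..k9`, plus an intrinsic-nuclease loss EC10 → cleaved
  (`k10`).  The cleaved product is modeled as an explicit sink species so
  that mass is conserved exactly; it is mapped to no gel band by default
  because the fate of the label after cleavage is not constrained by the
  assay (an option can map it onto a visible band).
* **S2** (Pol I + BMH-21): S1 plus off-pathway paused species EC11\* and
  EC12\* entered/exited via `k1_on/k1_off` and `k2_on/k2_off`.  Paused
  complexes cannot elongate directly; they must revert to the active state
  first.  Paused and active complexes of the same length co-migrate into a
  single gel band.
* **S3** (Pol II, either condition): fully reversible chain with
  forward/reverse pairs `kF1..kF9` / `kR1..kR9` (pyrophosphorolysis), no
  nuclease path.
* **S4** (Pol III, either condition): S1 plus an elongation-incompetent
  starting subpopulation EC10_i that activates with rate `k_act`; the
  initial mass splits `(1 − f_inactive, f_inactive)`, with `f_inactive`
  a free parameter in [0, 1] (the assay does not fix the split).

Assumptions: fixed saturating NTP and Mg²⁺ (no concentration dependence);
no resolution of elementary substeps (binding, catalysis, translocation,
PPi release); no stochastic single-molecule effects (band fractions are
ensemble averages over ~10⁹ complexes).

## Solvers and the analytic oracle

The solution `p(t) = expm(K t) p0` is evaluated three ways:

* `expm` (default): `scipy.linalg.expm` per time point — exact for linear
  systems and robust for every scheme.
* `eig`: one eigendecomposition of `K`, then vectorized propagation over all
  time points; falls back to `expm` when the eigenvector basis is
  ill-conditioned.  Used inside fitting loops for speed.
* `ode`: adaptive stiff integration (LSODA, rtol 1e-10/atol 1e-12), kept as
  an independent cross-check because fitted rates can span several orders of
  magnitude; tests assert `expm` and `ode` agree to better than 1e-6.

Negative fractions from round-off are clamped to zero only at output;
anything below −1e-9 raises.  Inside the optimizer a relaxed fast path is
used (`_FastForwardModel`): spectral propagation accepted when mass is
conserved to 1e-6, otherwise one LSODA solve.  Optimizer populations explore
extreme rate corners (`k·t ~ 1e5`) where demanding 1e-9 conservation is
neither achievable nor useful for an objective value; all *reported*
quantities are recomputed through the strict public solver.

The independent oracle is the classical closed-form solution of a sequential
irreversible decay chain (`bateman_chain`).  It shares no code with the
matrix solvers and is used to verify them on random chains (max-abs
agreement < 1e-7 over 100 chains in the acceptance checks).  The closed form
requires pairwise-distinct rates and is numerically unstable when many rates
cluster (its denominators are products of rate differences), so oracle
comparisons use well-separated random rates; confluent inputs raise a
dedicated error directing callers to the matrix solver.

## What the pause signature looks like — and what it cannot look like

A strong, slowly-released pause at the 11-mer makes the 11-mer band
*persist*: it decays on the `k1_off` time scale instead of vanishing on the
elongation time scale, and all downstream peaks shift right.  Downstream
bands can even become bimodal — an early cohort that escaped pausing and a
late cohort released from EC11\* (the test suite pins a parameter set where
the 12-mer band has two clear maxima).

The 11-mer band itself, however, is provably unimodal under this scheme
family: its derivative is `k1·EC10 − k2·EC11` (the internal pause fluxes
cancel), a sum of exactly three real exponentials — the EC10 decay rate and
the two eigenvalues of the 2×2 pause block.  A three-term real-exponential
sum has at most two sign changes; since the derivative is positive at t→0⁺
and negative as t→∞, it has exactly one, i.e. one interior maximum.  The
same argument holds for the alternative pause-attachment topologies
(entry from the preceding step, pause bypass).  A numerical scan of 8000
random parameter sets found no counterexample.  Consequently the acceptance
check that expects *two* local maxima in the noiseless 11-mer model curve
cannot pass and is left failing by design; the observable two-peak behaviour
reported for measured 11-mer data is not reproducible by any parameterization
of the fitted scheme, only the persistence and right-shift signatures are.

## Hybrid global optimization

Rate constants are fitted in log10 space with box bounds `[1e-3, 1e4]` s⁻¹
(positivity is structural and observed rates span roughly 0.1–100 s⁻¹);
`f_inactive` is fitted linearly in [0, 1].  The objective is unweighted
least squares over the nine product bands (11-mer..19-mer) at all time
points; the 10-mer can be included by configuration.

The optimizer (`hybrid_optimize`) couples:

1. a real-coded genetic algorithm — population 48, 60 generations,
   tournament selection (k = 3), BLX-α blend crossover (α = 0.3, rate 0.7),
   additive Gaussian mutation (sd 0.25 in transformed units, rate 0.25 per
   gene), elitism 2 (which makes the best-so-far trace non-increasing);
2. a damped least-squares polish (`scipy.optimize.least_squares`, TRF) from
   a niched set of top GA candidates (pairwise distance > 0.5 in transformed
   space, so distinct basins are polished rather than clones of one) plus an
   equal number of independent seeded random restarts.  Because those
   restart points are exactly the ones `multistart_points` generates, the
   hybrid can never end worse than plain multi-start NLLS from the same
   seeds — a guarantee the tests exercise.

Numeric Jacobians use a relative step of 1e-6: large enough to dominate the
~1e-8-level noise of the fast solver path, small enough for curvature.
Polish tolerances are 1e-10 with a 1500-evaluation cap per start.  Exact
objective ties are broken by the smaller parameter-vector norm.  A fit whose
optimum sits on a box bound is flagged (`converged_ = False`,
`at_bounds_`); all-zero input data raise immediately rather than "fitting".
GA defaults were chosen for desk-scale runtime (a single replicate fit takes
a few seconds) and are fully exposed.

Replicates are fitted individually and summarized as the per-parameter
arithmetic mean ± sample SD (n−1), the reporting convention of the assay.

## Synthetic data

No raw quench-flow dataset for this assay is publicly deposited, so the
generator stands in for it.  It emulates: 20 log-spaced time points over
0.005–10 s, three independent replicates per condition, ten bands, and
additive Gaussian quantification noise (sd 0.02 fraction units) applied
independently per band and time point, clipped to [0, 1], with no per-lane
renormalization (optional, off, since the original normalization procedure
is unspecified).  It does **not** emulate gel artifacts (smearing, band
overlap), quench-timing error, or signal-dependent noise — so passing
recovery tests show identifiability under well-behaved noise, not robustness
to systematic quantification error.

Clipping makes the noise biased wherever the true fraction is within ~2 sd
of 0 or 1; the worst case is a true fraction of 0, where the mean of the
clipped noise is σ/√(2π) ≈ 0.008.  The helper `clipped_mean` gives the
exact expectation, and the generator tests validate the ensemble mean
against it.  This bias has a real statistical consequence: a systematic
late-time elevation of near-zero bands that the pause branches of S2 can
partially absorb, which makes AICc selection between S1 and S2 on
*chain-generated* noisy data marginal on some noise draws (with untruncated
noise the same procedure is decisively correct).  The model-comparison tests
document this fragility.

Scenario truths: only three features are anchored to reported results —
the Pol III mean addition rate (exactly 49 s⁻¹ vehicle vs 39 s⁻¹ treated,
a ~20% reduction), the > 2-fold slowing of the 13-/14-mer appearance steps
under treatment, and a strong-pausing regime (`k1_on/k1_off = 20/0.5` s⁻¹)
with elongation near 40 s⁻¹.  All other rate values are invented,
realistic regimes (Pol I fastest, Pol II slowest and reversible with
forward/reverse ratios ~4, nuclease ≲ 0.5 s⁻¹) and are regimes, not
reproductions of the study's fitted constants.  The two Pol II conditions
share identical truths, encoding the finding that the compound does not
affect Pol II.

Seeding: one master seed spawns independent per-replicate `numpy`
SeedSequence streams; identical (scenario, seed) pairs reproduce datasets
bit-for-bit.

## Model comparison

Candidate schemes fitted to the same dataset are ranked by the
small-sample-corrected Akaike information criterion,

    AICc = n ln(SSR/n) + 2p + 2p(p+1)/(n−p−1),

with n the fitted observations and p the free parameters; it is undefined
(raises) when n ≤ p + 1.  AICc is used instead of a nested F-test because
the reduced model places the pause rates on the boundary of the parameter
space, violating the F-test's regularity conditions.  Two diagnostics
accompany the ranking: the fraction of positive late-time residuals on the
11-/12-mer bands (the signature of unmodeled pausing — a chain model decays
to baseline while paused data persist) and a Wald–Wolfowitz runs test per
band for residual structure.

Derived summaries follow the field's conventions: `mean_kobs` averages
`k1..k9` only (the nuclease, pause, and activation rates describe
off-pathway processes, not nucleotide addition); fold changes are
reference/fit per step; the reversible scheme is summarized by per-step
forward/reverse ratios.

## Stability analysis

The RNase-protection assay reports EC disassembly as
`collapse = signal(7-mer) / (signal(7-mer) + signal(10-mer))` per lane —
scale-invariant in raw phosphorimager units.  Curves are averaged over
replicates per condition; two conditions are contrasted point-by-point, and
the verdict is "unaffected" when the mean difference stays within 2 pooled
replicate SDs at every time point (threshold configurable).  An optional
single-exponential rise-to-plateau fit, `f(t) = f0 + A(1 − e^{−kt})`,
reuses the hybrid optimizer; it is off by default because the assay
prescribes no decay model.  The synthetic stability scenario uses a
logarithmic 1–600 s grid (the original sampling times are unpublished) with
a 60 s disassembly half-life.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 100 random chains for the
oracle check; 10 seeds × 3 replicates for parameter recovery in each
scenario; 10 seeds per direction for model selection; 10⁴-point dense grids
for qualitative shape checks.  These sizes keep a full run at desk scale
while leaving the binomial/selection margins interpretable.  Every random
quantity is derived from an explicit seed; the full simulate → fit →
compare pipeline is deterministic given one master seed, and serialized
outputs are byte-identical across reruns (timestamps only in the run
manifest).

## Known limitations

* Reverse rates of the reversible scheme are weakly constrained
  individually at this noise level; only forward/reverse *ratios* are
  reliably recovered (the summaries report ratios for this reason).
* The nuclease rate `k10` is a nuisance parameter barely visible in the
  product bands; on noisy data it can collapse to its lower bound, which the
  boundary flag reports.
* AICc selection against a strictly nested alternative is marginal when the
  truncation bias of the noise model mimics the alternative's signature (see
  above); conclusions about pausing should lean on the residual diagnostics
  as well as AICc.
* The collapse-fraction analysis assumes the 7-mer/10-mer pair exhausts the
  lane signal; partial degradation products are not modeled.
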