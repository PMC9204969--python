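# Methods

## Model overview

`grnsim` generates synthetic single-cell RNA-seq data whose gene–gene
dependence structure comes from a known, generated regulatory network, so
that network-inference algorithms can be benchmarked against an exact
ground truth. The generator couples three layers:

1. **Stochastic gene expression per cell.** Each gene is a two-stage
   birth–death system: transcription at rate `k1·V·R` (molecules/h; `V`
   the cell volume, `R` the regulation factor), translation at `k2` per
   mRNA per hour, first-order mRNA decay `dm` and protein decay `dp`.
   Copy numbers are integers; dynamics are advanced by exact Gillespie
   SSA or by tau-leaping (Poisson counts per channel with rates frozen at
   the window start, negative excursions truncated at zero).
2. **Cell growth and division.** Volumes grow exponentially,
   `dV/dt = µV` with `µ = ln2 / doubling_time` (50 h by default). Size
   control is an adder: the division target follows the noisy linear map
   `V_F = a·V_I + b` with `a = b = 1` and no target noise by default, so
   each cycle adds one volume unit. At division the split fraction
   `η2 ~ N(0.5, 0.05)`, clamped to (0.05, 0.95), fixes both daughter
   volumes and the binomial partition probability of every molecular
   species; molecule and volume totals are conserved exactly. The
   population size is capped: one daughter keeps the parent's slot and
   the other overwrites a uniformly chosen different slot.
3. **Sequencing noise.** Each cell observes a binomial thinning of its
   true counts with capture efficiency `β_j` drawn from a log-normal
   whose arithmetic mean is the experiment's `β` (log-variance 0.2,
   draws above 1 resampled). The scaling correction divides cell `j`'s
   noisy counts by `θ_j = β_j·V_j/V_max`.

The two layers are coupled by operator splitting with window
`τ = 0.1 h`: reactions for `τ` at fixed volume, then growth, then
division checks. Only the final snapshot is used downstream, mirroring
the single-time-point nature of scRNA-seq.

## Regulation

Activation and inhibition are Hill functions,
`f_act(x) = xⁿ/(Kⁿ+xⁿ)` and `f_inh(x) = Kⁿ/(Kⁿ+xⁿ)`. A gene with
several regulators combines their Hill terms either multiplicatively
(product) or additively (sum), globally per network. Genes with two or
more regulators are "combination reactions": combined activation (all
activating), combined inhibition (all inhibiting) or combined action
(mixed).

Two modelling choices here deserve explanation because both were
genuinely open and both are load-bearing:

* **The Hill input is the regulator's mRNA concentration** (copy number
  divided by cell volume), and `K` is a concentration anchored to the
  regulator's unregulated steady-state concentration `k1/dm`
  (configurable proportionality `K_scale`, default 1). Concentration is
  the physically standard input for binding kinetics, and it makes
  regulation invariant to cell-cycle position: copy numbers scale with
  volume, concentrations do not. With raw copy numbers and a fixed `K`,
  every regulated gene would instead track the cell cycle, and the
  strongest dependencies in a snapshot would be spurious target–target
  pairs rather than true links.
* **mRNA rather than protein as the regulatory species.** With
  mammalian-scale protein half-lives (tens of hours), a regulator's
  protein level is a long-window average of its expression history; its
  fluctuations are nearly uncorrelated with its own current mRNA and far
  too slow to imprint on the targets' fast-decaying mRNA. A
  single-snapshot mRNA matrix then carries essentially no pairwise
  signal and no inference method can recover the network from it.
  Regulation through the mRNA level keeps regulator and target on
  comparable hour-scale timescales, which is the regime in which a
  snapshot benchmark is informative at all. Protein copies are still
  simulated and exported; they simply do not enter the transcription
  propensity.

## Kinetic parameters

Rates are drawn per gene from a multivariate log-normal over
`(dp, dm, k1, k2)`. The shipped default has log-scale medians
`(0.03, 0.1, 2, 10)` — protein half-life ≈ 23 h, mRNA half-life ≈ 7 h,
≈ 2 transcripts/h, ≈ 10 proteins per mRNA per hour — log-standard
deviations (0.6, 0.6, 0.8, 0.8) and a diagonal covariance, giving
positively skewed marginals, steady states of roughly 5–100 mRNAs and
10²–10⁵ proteins per cell at unit volume, and weak inter-rate
correlation. Parameter sets whose unregulated steady-state protein
exceeds 100,000 at unit volume are rejected (a few percent of draws).
Users can instead supply a rate table (CSV) and fit their own
distribution with `fit_rate_distribution` (log-scale MLE: mean and
population covariance of the log rates).

Hill coefficients are log-uniform on [1, 10] and are kept continuous.

## Initialisation and numerical choices

* Cells start de-synchronized: volumes uniform on [1, 2), division
  targets at 2, copy numbers at the rounded unregulated steady-state
  means for the cell's volume. Simulating 500 h (10 doublings) makes the
  snapshot independent of this choice; the de-synchronization only
  avoids transient division waves.
* In growing cells the stationary mRNA concentration is
  `k1/(dm+µ)` — dilution adds to degradation — about 3% below `k1/dm`
  at a 50 h doubling time. Tests use the dilution-corrected form.
* One tau-leap window has first-order bias (`1−dm·τ` vs `e^(−dm·τ)`);
  at the operating resolution `dm·τ ≈ 0.01` the stationary law is
  indistinguishable from the exact one at the tested precision. SSA is
  available as the exact method throughout.
* `η2` is clamped (not resampled) to (0.05, 0.95) to avoid zero-volume
  daughters; `β_j > 1` draws are resampled (not clamped) to keep the
  capture-efficiency distribution smooth.
* Ranked edge lists break score ties by the canonical pair index, so
  all rankings are deterministic under a fixed seed.

## Inference and evaluation

* **PIDC-style:** pairwise plug-in mutual information (bits) on
  per-gene binned data (uniform-width bins, `⌈√n_cells⌉` capped at 10;
  equal-frequency binning available). For each pair (X, Y) the
  proportional unique contribution sums, over every context gene Z, the
  unique information X carries about Y beyond Z plus the reverse —
  partial information decomposition with the Williams–Beer
  minimal-specific-information redundancy — divided by I(X;Y); pairs
  with zero MI get 0. Edge confidence is the sum of the two genes'
  empirical-CDF values of the pair's score.
* **CLR:** each pair's MI z-scored (negatives floored at 0) against
  both genes' background MI distributions, combined as √(z_i²+z_j²).
* **GENIE3-style:** per-target random-forest regressions (1000 trees by
  default, √p feature subsampling, genes standardised); the undirected
  pair score is the larger of the two directed importance totals.
* **RAND:** i.i.d. uniform pair scores.

Evaluation is undirected. At the matched threshold (top-N with N the
true link count) precision equals recall, so it reads directly as the
fraction of true links recovered. AUROC and AUPR are trapezoidal areas
over the ranking sweep with tied-score blocks contributing single
segments; AUROC then equals the Mann–Whitney statistic. Note the
trapezoidal PR area is slightly above the prevalence on random rankings
at low prevalence; this is a property of the estimator, not a bug.
Correlation preservation is quantified as the mean squared deviation of
pairwise Pearson correlations against the volume-scaled ground truth,
reported per reaction class (activation, inhibition, non-reaction, all),
with pairs touching zero-variance genes excluded and counted.

## Benchmark presets and problem sizes

The full-scale layout (100 networks, 2000–3000 cells each, five capture
efficiencies, 1000-tree forests) takes hours on one CPU. The package
therefore treats scaled-down presets as first-class: the shipped
`scaled_down_preset` runs 20 networks of 300–500 cells for 500 simulated
hours with tau-leaping (τ = 0.1 h) and 100-tree forests, completing in
minutes while preserving every other study condition (sign coin-flip,
steady-state-anchored K, adder division, 50 h doubling). The five-gene
exemplar (`make_fixture("toy5")`) uses fixed, documented kinetics —
about 100 mRNAs per cell, Hill n = 3, K at the regulators' working
point — rather than sampled rates, so its designed phenomenology (raw
correlations dominated by cell volume; volume scaling revealing the
activation/inhibition signs; full recovery by PIDC; collapse under 20%
capture) is stable across fixture seeds.

## What the generator does and does not emulate

The synthetic data reproduce: integer molecule noise, cell-size scaling
of transcription and the resulting global positive correlations,
partitioning noise at division, lineage structure through a capped
population, and capture-efficiency dropout. They do not include:
amplification or batch effects, UMI collisions, ambient RNA or doublets,
cell types or differentiation trajectories, extrinsic growth-rate
variability between cells, transcriptional bursting beyond the
birth–death model, or directed-edge information in the evaluation.
Passing benchmarks here therefore speak to an algorithm's behaviour
under dropout and size scaling with a known topology — not to its
robustness against the full error structure of real scRNA-seq.

## Known limitations

* Tau-leaping uses plain truncation at zero rather than a
  non-negativity-preserving variant; SSA is the exact fallback.
* The in-degree cap (4) for scale-free topologies is enforced by
  rejection, which at high densities distorts the degree distribution's
  tail.
* The imputation adapters only load externally produced matrices; no
  imputation algorithm is re-implemented.
* Empirical-Bayes-style smoothing of the PIDC confidence distributions
  is not implemented.
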