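# Methods

## Models

### Generalized TASEP

The stochastic model is a totally asymmetric simple exclusion process
with extended particles and site-dependent rates. An mRNA of N codons
carries ribosomes of footprint ℓ (odd, default 11 codons — the low end
of the measured 11–18-codon footprint range); the codon under
translation sits at the ribosome's middle, so a ribosome "on" codon i
covers codons i ± (ℓ−1)/2. Initiation places a ribosome on codon 1 at
rate λ provided the first (ℓ+1)/2 codons are uncovered; a ribosome on
codon i jumps to i+1 at rate λ_i provided the spacing to the next
ribosome stays ≥ ℓ; once its leading edge passes the 3′ end it "bulges"
and is never blocked; the jump off codon N is a termination. Events are
drawn with the Gillespie direct method, which is distributionally
identical to taking the minimum of the competing exponential clocks;
blocked attempts advance time without changing the configuration, so an
"event" count includes failures. The production rate is terminations
divided by elapsed time over the measurement phase (default 1,000,000
events after a 250,000-event burn-in from an empty strand; quadrupling
these changes the rate by less than the Monte-Carlo error). Per-codon
occupancy is accumulated time-weighted over the same phase. A
deterministic-dwell variant replaces each exponential dwell by its exact
mean 1/λ_i; the event schedule is then a priority queue of expiry times,
initiation keeps its exponential clock (the model statement fixes only
the codon times), and a blocked ribosome is rescheduled after one
further full dwell.

### Ribosome flow model

Coarse-graining into n sites of C codons and neglecting inter-site
correlations (mean field) yields the ODE in the README. The site rate
λ_i is the reciprocal of the summed codon dwell times of site i; sites
are consecutive chunks starting at codon 1, the last chunk may be
shorter (keeping it conserves total dwell time), and stop codons are
removed beforehand — termination is represented by the last site's exit
rate, not a dwell. C defaults to 25 codons, the value at which predicted
rates correlate best with protein abundance and which matches ribosome
length scales; density-profile work conventionally uses C = 15.

Steady states are computed two independent ways:

* **Time integration** (`solve_steady_state_ode`): LSODA from an empty
  strand over geometrically growing horizons until the max-norm of the
  right-hand side falls below 10⁻⁹ (the convergence criterion is a
  design choice; the contract is the steady state, not the path).
* **Spectral** (`solve_steady_state_algebraic`): unrolling the
  steady-state balance as a continued fraction shows 1/√R is the largest
  eigenvalue of the (n+2)-dimensional symmetric tridiagonal matrix with
  zero diagonal and off-diagonals λ^−½, λ_1^−½ … λ_n^−½; occupancies are
  ratios of consecutive Perron-eigenvector components,
  p_i = √R · λ_i^−½ · v_{i+1}/v_i. A scalar root search on R with
  one-directional back-substitution of the balance equations was tried
  first and recovers R to machine precision, but reconstructing the
  occupancies that way is exponentially unstable (each recursion
  direction contracts only on one side of a density transition), so the
  spectral route is used. Where the eigenvector decays below ~10⁻¹³ of
  its peak its components are noise; those stretches are refilled by the
  locally stable substitution direction (backward in dilute tails,
  forward in dense heads) and a Newton polish reduces the final balance
  residual to ~10⁻¹³. The two solvers agree to better than 10⁻⁶
  relative on random chains up to n = 500 and serve as mutual oracles in
  the tests.

The elongation capacity — the λ → ∞ limit of R — is computed exactly by
deleting the initiation entry from the spectral matrix, and verified
reachable by a finite-λ solve. The capacity is a transcript-specific
maximum: for a long homogeneous chain it approaches the mean-field
maximal current λ_codon/4.

**Abortion variant.** With probability γ a ribosome–ribosome collision
detaches both partners; this subtracts γ·λ_i·p_i·p_{i+1} from sites i
and i+1. γ defaults to 0, the regime the abundance correlations favor.

**Finite horizon.** When an mRNA's half-life is short relative to the
relaxation time, the mean rate over [0, T] from an empty strand
(integrating the exit flux alongside the occupancies) replaces the
steady-state R.

## Codon dwell times

The tRNA-adaptation weighting follows the tAI: W_i = Σ_j (1 − S_ij)
tCGN_ij over the n_i tRNA species recognizing codon i, with S_ij the
wobble-class selective constraint (a codon↔tRNA table plus an S-vector
config are the inputs); p_i = W_i/max(W), τ_i = 1/p_i. Codons with no
recognition get the smallest positive p (simpler and monotone-safe
relative to geometric-mean imputation; logged when it triggers). CGA is
uniquely S-sensitive — its decoding runs almost entirely through I:A
wobble — so its weight is replaced by the mean of W over all ±0.5
perturbations of the S entries affecting it, each clamped to [0, 1].
Time units are arbitrary: λ and the λ_i are commensurate only within
one table.

## Derived analyses

* **DTCO/DPCO**: shuffle the codon order uniformly (whole codons,
  unconstrained — synonymous-only shuffling would mask part of the
  order effect being measured) n_perm = 10 times; DTCO is 100 × the
  sample standard deviation (n−1 denominator) of the shuffled rates over
  the unshuffled rate. DPCO maps each rate through a log-log linear
  regressor of protein abundance on rate before taking the same ratio.
* **Working point**: globally, λ* maximizes the Spearman correlation
  between predicted rates and abundance over a λ grid; Q% is the mean
  rate at λ* as a percentage of the mean capacity. Per gene, the working
  point is the λ at which the gene reaches Q% of its own capacity
  (bracketed root search on the monotone R(λ)).
* **Translation cost**: rate divided by mean density — proteins per unit
  time per working ribosome.
* **Fold change**: mean ratio of variant to native rate over 41 equally
  spaced λ in [0.0002, 0.0094], the initiation-limited range relevant to
  heterologous expression; Spearman correlations get empirical p-values
  from 100 label permutations (fraction with strictly higher
  correlation).
* **Site-size jackknife**: 100 draws of 80% of the genes; per draw the
  candidate C with the best rate–abundance Spearman correlation wins;
  the report is the win count per candidate.
* **Profiles**: per-gene occupancy vectors are aligned at the 5′ end and
  averaged position-wise over the genes covering each position,
  optionally rescaled to a common mean; two predicted profiles are
  compared against an observed one by a two-sided paired Wilcoxon
  signed-rank test on per-position absolute distances.

Correlations against abundance use Spearman throughout; the
RFM-vs-TASEP comparison reports both Pearson and Spearman.

## Synthetic data

`generate_fixture_transcripts` draws a codon alphabet (≤ 61 sense
codons) with expected times log-uniform over a configurable range,
realizes them as a one-tRNA-per-codon pool with integer copy numbers
∝ 1/τ at 10⁶ resolution (so pool-derived times match the draw to
rounding), and samples transcripts i.i.d. uniformly over the alphabet.
This emulates the dwell-time heterogeneity of real coding sequences but
**not** their gene-level codon-usage bias: real genes differ
systematically in codon content (highly expressed genes are enriched in
fast codons), which spreads per-gene rates over a wide dynamic range,
whereas i.i.d. transcripts of equal length differ only by
central-limit-theorem fluctuations (a few percent). Tests passing on
these fixtures therefore validate the machinery — solvers, simulator,
estimators, recovery of planted truths — not the genome-scale effect
sizes, which depend on that real-data spread. In particular, the
RFM↔TASEP rate correlation on 20 i.i.d. transcripts of 150 codons is
bounded near ~0.4–0.8 (the across-transcript rate spread is comparable
to the per-transcript scatter of the coarse-graining approximation, as
a common-random-numbers decomposition shows), while the same comparison
on transcripts with realistic gene-level codon-usage heterogeneity
rises above 0.9.

## Problem sizes and numerical choices

The bundled benchmark and tests run at deliberately small scale — tens
of genes, 150 codons, 10⁶-event simulations — chosen so the full suite
solves in minutes while keeping Monte-Carlo errors near 1% of the rate.
The "mid-response" initiation rate used for model comparisons is defined
as the median per-gene working point at Q = 50%, the midpoint of the
rising branch of R(λ) between the initiation-limited (R ≈ λ) and
saturated (R ≈ capacity) regimes. Fixed seeds make every stochastic
result bit-reproducible; every CLI output carries a JSON sidecar with
the full configuration and seed. Codon indices in outputs are 1-based.

## Known limitations

* Mean-field and coarse-graining bias: the flow model's absolute rates
  deviate from the exclusion process by O(10%) in congested regimes;
  rankings are far more stable than absolute values.
* The deterministic-dwell variant's blocked-ribosome rescheduling (one
  further full dwell) is one of several defensible conventions; at low
  densities they coincide.
* No time-dependent initiation, ribosome drop-off beyond the collision
  term, or circularization/recycling effects.
* The tAI machinery assumes a fixed tRNA pool; condition-specific pools
  are supported only by supplying a different table.
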