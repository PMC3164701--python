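# riboflow

Models of ribosome traffic during mRNA translation elongation, for
quantitative biologists who want to predict translation rates, ribosome
densities and codon-order effects directly from coding sequences and a
tRNA pool.

## The models

**TASEP.** Translation is a totally asymmetric simple exclusion process:
ribosomes initiate at the 5′ end at rate λ, cover ℓ codons (the codon
under translation at their middle), hop codon-by-codon with
codon-specific exponential (or deterministic) dwell times, never
overlap, and release a protein on terminating past the last codon.
`riboflow.tasep` implements an event-driven (Gillespie) simulator of
this process, with a numba-compiled core.

**Ribosome flow model (RFM).** Coarse-graining the mRNA into n sites of
C codons (default C = 25) and taking a mean-field average gives a
deterministic ODE for the site occupancies p_i(t):

    dp_1/dt = λ(1 − p_1)              − λ_1 p_1 (1 − p_2)
    dp_i/dt = λ_{i−1} p_{i−1} (1 − p_i) − λ_i p_i (1 − p_{i+1})
    dp_n/dt = λ_{n−1} p_{n−1} (1 − p_n) − λ_n p_n

where λ_i is the reciprocal of the summed expected dwell times of the
codons in site i. At steady state every junction carries the same flow —
the protein production rate R = λ_n p̄_n — and R ≤ min(λ, λ_1 … λ_n).
`riboflow.rfm_core` solves the steady state two independent ways (time
integration, and an exact tridiagonal-eigenvalue formulation) and exposes
the elongation capacity (the λ → ∞ limit of R), abortion and
finite-horizon variants.

**Codon dwell times** come from tRNA adaptation (`riboflow.codon_rates`):
each codon's absolute adaptiveness W_i = Σ_j (1 − S_ij)·tCGN_ij sums the
gene copy numbers of its recognizing tRNAs, discounted by the wobble
selective constraint S_ij; p_i = W_i / max(W) is the tRNA-coupling
probability and τ_i = 1/p_i the expected dwell time.

On top of these sit content-only baseline predictors (gene tAI,
bottleneck, mean speed — `riboflow.predictors`) and derived analyses
(`riboflow.analysis`): DTCO/DPCO codon-order dependence indices,
working-point and initiation-rate inference, translation cost,
variant-vs-native fold change, and a site-size jackknife.

## Worked example

Generate a small synthetic fixture (3 genes × 60 codons over a 20-codon
alphabet with a matching synthetic tRNA pool) and solve the flow model:

```sh
riboflow fixtures --n-genes 3 --length 60 --alphabet 20 --seed 7 --out-prefix demo/fix
riboflow solve --fasta demo/fix.fasta --trna demo/fix.trna.tsv \
    --svec demo/fix.svec.yaml --site-size 10 --lam 0.004 --out demo/solve.tsv
```

`demo/solve.tsv`:

```text
gene	lambda	R	mean_density	capacity	n_sites
synth0001	0.004	0.00325268	0.17842	0.00609264	6
synth0002	0.004	0.00333941	0.197886	0.00586636	6
synth0003	0.004	0.00342347	0.188195	0.00612731	6
```

At this initiation rate each gene runs at roughly half of its elongation
capacity (`R`/`capacity`), with about 0.18–0.20 of sites occupied by a
ribosome. The codon-order dependence of the same genes:

```sh
riboflow dpco --fasta demo/fix.fasta --trna demo/fix.trna.tsv \
    --svec demo/fix.svec.yaml --site-size 10 --lam 0.004 \
    --n-perm 10 --seed 1 --out demo/dtco.tsv
```

```text
gene	rate	dtco_percent	n_perm	seed
synth0001	0.00325268	3.09105	10	1
synth0002	0.00333941	2.79626	10	2
synth0003	0.00342347	2.2798	10	3
```

i.e. merely reshuffling the codon order of `synth0001` moves its
predicted translation rate by ~3% (standard deviation over 10 random
shuffles) — a signal invisible to content-only indices such as the tAI,
which these permutations leave exactly unchanged.

Other subcommands: `rates` (site transition rates), `simulate`
(stochastic TASEP runs), `predict` (RFM rate alongside tAI, bottleneck
and mean speed), `workingpoint`, `foldchange`.

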