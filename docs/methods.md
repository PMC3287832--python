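# Methods

## Model and procedure

`bnsnp` treats a case-control resequencing panel as one joint discrete
distribution. Variables are the SNP dosages (3-level categorical: 0, 1 or
2 alternate alleles — no additive collapsing, so the network can express
non-additive genotype effects), the binary covariates Sex and Smoke, Age
reduced to its sample-quartile bin, and the binary outcome Affected. A
Bayesian network over these variables is a DAG plus per-node conditional
probability tables; the analysis pipeline is:

1. **Preprocess.** Pool the replicate datasets under analysis by row
   concatenation (genotypes repeat verbatim across replicates; outcomes
   are independent re-draws). Drop SNPs monomorphic in the pooled sample
   — a SNP with a single observed dosage value carries no information and
   breaks LD/regression arithmetic. The retained SNP count N and retained
   causal count m fix the enrichment reference. Bin Age by the 25/50/75
   empirical percentiles (linear-interpolation quantiles; values ≤ Q1 →
   bin 0, ≤ Q2 → 1, ≤ Q3 → 2, else 3; an all-equal input collapses to
   bin 0).
2. **Learn.** Score-based hill climbing (below) returns one best network.
3. **Select.** DA = SNP-role descendants of Affected; MBA = SNP-role
   Markov blanket; CA = SNP-role children. Covariate and outcome nodes
   are excluded from all three sets, since the reported counts are SNP
   counts.
4. **Evaluate.** Exact hypergeometric upper tail P(X ≥ k) for each subset,
   and the same statistic for the Bonferroni-selected set of a per-SNP
   logistic scan.

### Scores

All scores are decomposable sums of per-family local scores computed from
the family's contingency counts (natural logs; 0·ln 0 = 0):

* `loglik` — maximised multinomial log-likelihood Σ N_ijk ln(N_ijk/N_ij).
  Zero-count parent configurations contribute 0.
* `aic` = loglik − q and `bic` = loglik − (ln N / 2) q with
  q = (r − 1)·Π r_parents. The parent-configuration count uses the full
  state-space product, not just configurations observed in the data; this
  is the standard dimension convention and penalises large families even
  when sparsely observed.
* `bde` — BDeu Dirichlet marginal likelihood with imaginary sample size
  `iss` (default 1; per-cell hyperparameter iss/(q·r)).
* `k2` — Dirichlet marginal with every hyperparameter 1; identical to
  `bde` when iss = q·r, which the tests exploit.

Pure log-likelihood never decreases when a parent is added (the gain is
n × empirical conditional mutual information), so unconstrained loglik
search densifies toward complete graphs with exponentially large tables.
The `max_parents` cap (default 3) bounds family size; it is exposed in
`SearchConfig` and logged, since how density is bounded materially changes
which graphs are reachable.

### Search

Best-improvement hill climbing: every legal add/delete/reverse of a single
arc is scored via its (at most two) changed families, and the move with
the largest positive delta is taken; ties break deterministically
(delete < reverse < add, then lexicographic arc order). Moves that would
create a cycle or exceed `max_parents` are rejected during enumeration —
rejection is an ordinary search signal, not an exception. Restart 0
climbs from the empty graph; each of `restarts` further rounds perturbs
the incumbent best with `perturbations` uniformly random arc-operation
attempts (cycle-creating attempts skipped) and climbs again, keeping the
best score seen. The benchmark protocol this mirrors used 1,000 restarts
and 2,400 perturbations, which are the defaults; the perturbation count is
read as a per-restart attempt budget. Perturb-the-incumbent is the restart
semantics; `restart_mode="fresh_random"` instead perturbs the empty graph
each round for users who want independent random starts. An optional
`forbidden_arcs` blacklist exists (e.g. to forbid SNPs as parents of Sex);
it is empty by default. Everything is driven by one integer seed and is
bit-reproducible.

### Subset definitions and a caveat

CA is implemented directly as children(Affected), not as DA ∩ MBA. The
two definitions coincide on most graphs but diverge whenever a strict
descendant of the outcome also co-parents one of its children (a
"descendant-spouse"): such a node is in both DA and MBA yet is not a
child. The test suite constructs the counterexample explicitly. CA ⊆ DA
and CA ⊆ MBA always hold.

### Enrichment statistic

The hypergeometric pmf is evaluated in log-gamma space and the upper tail
summed term by term starting from the far (smallest) end of the support,
so that large-N tails lose no precision; P(X ≥ k) = 1 identically for
k at or below max(0, n + m − N). Report tables display 3 significant
figures next to a full-precision column. No multiple-testing correction
is applied across methods or populations — the reported values are
nominal by design.

The bundled benchmark table (`bnsnp.benchmark`) stores the published
counts verbatim. One published cell (European replicates 1–20, CA,
"0/1 0.711") prints the point mass P(X = 0) = 138/194 rather than the
k = 0 tail, which is identically 1; the package reports the tail and
documents the identity.

### Logistic comparison arm

Each SNP is fit one at a time as `Affected ~ intercept + dosage + Age +
Sex` (additive 0/1/2 coding, raw Age in years — the network, by contrast,
sees quartile-binned Age, since its scores require discrete variables).
Fitting is IRLS via statsmodels' binomial GLM (tolerance 1e-8, 50
iterations); Wald two-sided p-values use the normal approximation.
Complete or quasi-complete separation — the norm for rare variants — is
detected via the solver's separation signals plus a divergence guard
(|β| > 15) and reported as `converged = False` with p = 1, a conservative
convention; Firth-type penalisation is deliberately out of scope. The
selected set is `{p < alpha / #SNPs}` with strict inequality, and is
scored with the same hypergeometric tail.

### Linkage-disequilibrium diagnostics

`ld_pairwise` estimates two-locus haplotype frequencies from unphased
dosages by EM (only the double heterozygote is phase-ambiguous; 100
iterations max, tolerance 1e-8), then reports r² = D²/(pA pa pB pb) and
|D′| = |D|/Dmax. These diagnostics exist to separate true causal hits
from r² proxies: a rare allele observed on a single chromosome has an
obligate zero cell in the 2×2 haplotype table, forcing |D′| = 1 against
every other SNP while r² stays near 0, so r² is the relevant measure.

## The synthetic study generator

GAW17-like data are emulated, not reproduced: one genotype matrix with
per-SNP minor-allele frequencies from Beta(0.2, 2.0) truncated to
[1/(2n), 0.5] (median MAF well under 0.05 — the many-rare-causal-variants
regime), Hardy–Weinberg genotype draws, and `n_causal` flagged SNPs;
phenotypes per replicate from a logistic liability:
logit P(affected) = intercept + Σ β_j·dosage_j + 0.3·sex + 0.5·smoke +
0.02·age. Defaults — 400 individuals, 300 SNPs, 30% causal, per-allele
log-odds 0.5, intercept −2.2 (≈30% prevalence once covariates act, and
exactly ≈10% when all effects are zeroed) — mirror the Asian-pool scale
of the benchmark so the (N, m) enrichment arithmetic is exercised at
realistic magnitudes. Sex and Age (and Smoke, by the `smoke_fixed`
default) are fixed per individual across replicates, like genotypes;
Affected is re-drawn. Randomness flows from one root seed through fixed
per-purpose `SeedSequence` streams, so replicate k is reproducible in
isolation.

What the generator does **not** emulate: the benchmark's unpublished
effect sizes and phenotype model, population structure and admixture,
LD between SNPs (loci are drawn independently), and sequencing error.
Passing tests therefore demonstrate that the machinery is correct and
calibrated under the stated study structure, not that the method would
recover the benchmark's specific SNP subsets — which its own negative
result suggests it largely would not.

## Numerical and design choices

* Genotypes are 3-level categoricals in the network even when a dosage
  level is unobserved; declared cardinalities (3/2/4/2 for
  SNP/binary/Age-bin/outcome) feed the dimension penalty.
* Exact float equality is used for search tie detection; ties are real
  (e.g. the loglik gain of u→v equals that of v→u on an empty graph) and
  the fixed operation/arc order resolves them.
* Scores are cached per (child, parent set, score type, iss); cache hits
  are bit-identical to recomputation by construction.
* Degenerate inputs: empty selections score p = 1 (k = 0 convention);
  empty data, monomorphic SNPs in LD, and misaligned tables are errors.
* Problem sizes in the test suite (hundreds of individuals, tens of SNPs,
  ≤ 60 restarts) are chosen so the full suite exercises every stage —
  including 50-trial brute-force oracle comparisons over all 543
  four-node DAGs — in seconds; the defaults users get
  (1,000 restarts × 2,400 perturbations) match the benchmark protocol.

## Known limitations

* Hill climbing returns a local optimum of a single DAG, not an
  equivalence class; no CPDAG/constraint-based machinery is provided.
* Separation handling (p = 1) makes the scan conservative for the rarest
  variants; this mirrors how such SNPs are effectively untestable by
  single-variant regression at these sample sizes.
* The enrichment statistic conditions on the selected-set size n; it says
  nothing about absolute false-positive burden when the baseline causal
  rate is low.
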