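# Methods

## Positional statistics

Each residue of a protein receives its 1-based rank from the position
coded by the initiation codon (rank 1) to the last coded position k;
the stop signal is never a position. The initiator methionine is always
included at position 1, also for sequences that may use alternative
start codons. Per amino-acid species the mean rank is divided by k (the
size-standardized mean position, `std_mean`), which makes proteins of
different lengths comparable; under random placement its expectation is
(k + 1)/(2k), slightly above 0.5 for finite k.

Non-standard residues (X, U, O, B, Z, ...) occupy positions and count
toward k but are excluded from the 20 species profiles; this keeps
`std_mean` comparable across proteins while preserving the rank-sum
conservation Σ count × mean_rank = k(k + 1)/2 over all residue classes.
Species absent from a protein are flagged missing, never stored as 0.

The per-protein "ro" statistic is the Pearson correlation between
inclusion rank and `std_mean` over the species present (≥ 1 residue, no
minimum count). `std_mean` rather than the raw mean rank is used so
that multi-protein aggregation is length-independent. All computation
is full precision; the ×100 presentation scaling seen in tabular
reports is applied only in report writers.

## Inclusion-order hypotheses

The built-in consensus table (G1 A2 D3 V4 P5 S6 E7 T8 L8 R10 I11 Q11
N12 H14 K15 C16 F17 Y18 M19 W20) is the average of 40 published
inclusion-order hypotheses. Q and I tie at rank 11 and both fall on the
"recent" side of the early/recent split (rank < 11 vs > 10), giving an
exact 10/10 partition. Other hypotheses are user-supplied two-column
TSV files; ties are allowed, all 20 amino acids are required.

## Statistical kernel

* **Sign test** — exact binomial tail at p = 1/2. The one-tailed value
  is always the upper tail P(X ≥ s | n, 1/2); the two-tailed value is
  the doubled smaller tail capped at 1. Some published analyses of this
  kind report roughly half the exact tail for certain counts (e.g.
  0.0273 for 8 of 10, where the exact tail is 0.0547); that convention
  is internally inconsistent and is deliberately not emulated here.
* **Fisher combination** — χ² = −2 Σ ln P_i with 2k degrees of freedom;
  requires P values in (0, 1] and assumes independence of the combined
  tests. Dependence is addressed separately via the mean-FDR critical
  value α(k + 1)/(2k).
* **Pearson/Spearman** — P values from the exact t transformation with
  n − 2 df (sample sizes here are small, so exactness matters over
  permutation); Spearman is rank-transformed Pearson. Fewer than 3
  pairs or a constant vector yields a flagged missing result (`None`),
  not NaN propagation.

## Group aggregation

Per species and group: the number of proteins containing the species
(denominators shrink when a species is absent, e.g. W in short
proteins), the number with `std_mean` < 0.5 (strict inequality — a
value exactly at the midpoint is conservatively non-conforming), the
exact sign test on that count, and the two group-level correlations
R_n (rank vs fraction below 0.5; predicted direction positive, since
5′-ward recent species raise the fraction) and R_m (rank vs group mean
`std_mean`; predicted direction negative).

Cross-group grand means average group means unweighted by group size
(size-weighted averaging is an option), with an optional
leave-species-out exclusion for the correlation only. The epoch
majority test counts species whose grand mean lies strictly on the
predicted side of 0.5 (early > 0.5, recent < 0.5) and applies the exact
sign test at n = 20. The accompanying Fisher combinations use
per-species one-tailed sign tests in the predicted direction on protein
counts pooled across groups, combined separately within the early and
the recent decade (k = 10 each); the pooling choice is ours — the
per-species inputs to the published combined values are not printed.

The covariate analysis pairs per-protein ro values with any per-protein
covariate by id (proteins missing either value are dropped and
counted) and reports Pearson and Spearman with one-tailed P in the
negative direction, the direction expected when gradient strength
grows with mutation load.

## Contact-energy analyses

Contact matrices are labeled symmetric 20×20 TSV tables; asymmetries
beyond 1e-6 are rejected, those between 1e-9 and 1e-6 symmetrized by
averaging with a warning. Focal correlations pair, for each amino acid,
its 19 contact energies e(focal, other) with the rank differences
|k₁ − k₂| (self-pair excluded; two-tailed P reported, one-tailed where a
direction is predicted). They are invariant under adding a constant or
positive rescaling of the energies and flip sign under negation. The
delta matrix is the entrywise difference of the hydrophobic-core and
polar-surface matrices. Whole-matrix correlations default to the 210
upper-triangle-plus-diagonal entries; 190 (no diagonal) and 400 (full)
are flags, since published matrix-to-matrix values do not state the
choice. Published matrices are not bundled (provenance/licensing);
synthetic matrices with controllable coupling to |k₁ − k₂| stand in for
tests and are labeled synthetic in name and file.

## Synthetic-sequence generator

The residue at relative position t = pos/k is drawn from frequencies
proportional to f_a · exp(−β · z_a · (t − 0.5)), with z_a the inclusion
ranks centered and scaled to unit variance over the 20 species. This
log-linear position-by-rank interaction is the simplest model producing
monotone `std_mean` shifts; centering decouples β from overall
composition (base frequencies are preserved in expectation at
mid-sequence). β > 0 enriches recent species 5′-ward; β = 0 with μ = 0
gives exchangeable positions. Substitution noise replaces each site
independently with probability μ by a uniform draw over the 20 species —
uniform rather than directional substitution suffices to demonstrate
gradient attenuation under mutation load; a directional substitution
matrix is a natural extension point. Generation is fully deterministic
given the seed.

Defaults: uniform base frequencies, consensus ranks, k = 300,
100 proteins, β and μ 0 — a neutral baseline; analyses of gradient
recovery use β = 1, which produces group-level R_m near −1 at that
sample size. What the generator emulates is the positional-gradient
structure only: real proteomes add compositional biases, domain
architecture, length/function covariation and phylogenetic dependence
among proteins, so passing recovery tests demonstrates correctness of
the estimators, not effect sizes expected on real data.

## Numerical and testing choices

* Exact worked-example and closed-form quantities are asserted at
  printed precision; stochastic checks use fixed seeds.
* Parameter recovery is checked at β = 1 with 100 replicates of 100
  proteins × 300 residues; type-I calibration of the epoch majority
  test uses 200 null replicates of 4 groups × 10 proteins × 150
  residues. These sizes give Monte-Carlo error small enough for the
  stated bounds while keeping the default suite fast.
* The n = 20 sign test is discrete: its attainable level at α = 0.05 is
  P(X ≥ 15) ≈ 0.0207, and the calibration test compares the empirical
  rejection rate to that exact attainable level (within binomial
  error), not to the nominal 0.05.
* Under sequence reversal `std_mean` maps to (k + 1)/k − m and ro flips
  sign; aggregation order can shift floating-point results by ~1 ulp,
  so invariance checks use 1e-12 tolerances.

## Known limitations

* Single-strandedness durations, divergence proxies and the 39
  non-consensus hypothesis rank lists are user-supplied inputs, not
  computed.
* The pipeline operates on protein sequences; codon-level mechanics
  (translation, replication strand asymmetry) are out of scope.
* Fisher combination assumes independent tests; the mean-FDR adjustment
  is a coarse correction for dependence, not a replacement for a
  dependence-aware combination.
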