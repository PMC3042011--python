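# Methods

## Model and assumptions

Every line of a doubled-haploid population is treated as one recombinant
gamete: loci are homozygous, allele A marks the female parent and B the
male parent, and the expected segregation is 1:1.  Two-point estimation
(r̂ = R/N; LOD = R·log10 r̂ + (N−R)·log10(1−r̂) + N·log10 2, with
zero-count terms contributing zero so that R = 0 attains LOD = N·log10 2)
assumes independent meioses and no scoring correlation between lines.
Distances use the Kosambi map function throughout, which tolerates
moderate crossover interference but is not additive under arbitrary
crossover processes (see "Known biases").

Segregation distortion is a one-degree-of-freedom chi-square on the
non-missing counts, χ² = (n_A − n_B)²/(n_A + n_B); per-LG skew pools
counts over loci before the test rather than averaging per-locus
statistics.  No multiple-testing correction is applied anywhere; all
order and block tests are two-sided at α = 0.05, matching how such
per-LG and per-block significances are conventionally reported.

## Pipeline

1. **Source merging.**  Where a marker was scored in several genotype
   sources for the same population, the source with the most non-missing
   calls wins; ties keep the earlier-listed source (deterministic and
   auditable).  Line sets are unioned.
2. **Ordering.**  Minimum total adjacent map length is used as the
   ordering objective — a standard surrogate for the multipoint ML order
   on DH data.  The chain is seeded with the highest-LOD pair, extended by
   the nearest unplaced marker at its cheapest insertion slot, and
   polished by ripple passes combining windowed 2-opt reversals and
   segment relocations (window 5) until no move shortens the chain.
   Co-segregating markers share a position, ordered by name.
3. **Masking.**  A non-missing call is masked when its nearest
   non-missing neighbours on both sides agree with each other and differ
   from it — a single simultaneous pass against the input matrix, never
   iterated, with terminal loci exempt.  The masked matrix is re-ordered
   with the previous order as the ripple's starting point (a warm start
   stabilises re-ordering where masking has thinned the local signal).
4. **Binning.**  A bin opens at the first unassigned position and absorbs
   every position < bin_width (1 cM) beyond its anchor.  Representatives
   prefer markers bridging the most other populations, then the highest
   call count, then the smallest name.  The stated "up to ~20 markers" of
   typical bins is descriptive; no cap is enforced.
5. **Integration.**  Two engines, compared deliberately:
   - *Regression*: pooled r̄ = Σ n_k r̂_k / Σ n_k with summed LODs;
     incremental placement in decreasing total-LOD order; each insertion
     minimizes S = Σ w_ij (d_ij − |x_i − x_j|)² (w = LOD², positions by
     weighted least squares, the first marker anchoring the origin); after
     each insertion the last three placed markers may be relocated if that
     lowers S.  The jump statistic is (S_new − S_old) / (n_placed · mean w)
     — in cM² — and markers exceeding the threshold (default 5.0, usual
     range 4–6) are deferred to Round 2, then forced in Round 3.
   - *DAG*: component maps become arc chains (weight = cM gap; co-located
     markers joined by 0-weight arcs in name order); the merged multigraph
     keeps per-map provenance.  Conflicts (cycles) are resolved by deleting
     marker occurrences: exact minimum-weight subset search per strongly
     connected component with ≤ 12 occurrences, otherwise a greedy that
     deletes the occurrence on the most simple cycles, followed by
     redundancy pruning and 2→1 exchange improvement.  The deletion weight,
     1 + (maps with locally consistent neighbours)/10, makes poorly
     supported occurrences cheap; "consistent with map j" means a strict
     majority of markers shared between the two maps lie on the same side
     of the occurrence in both.  Linearisation is a priority topological
     sort (mean normalized component rank, then name) with longest-path
     coordinates — chosen over least squares precisely to preserve the
     documented length inflation of graph merging.
6. **Re-attachment and orientation.**  Residual markers take their
   representative's consensus position; residuals of deleted
   representatives are reported unplaced.  Because least-squares
   coordinates are sign-blind, both engines orient the consensus to the
   first component map, which the caller orients to a reference map.

## Comparative mapping

Hit filtering applies assay-class profiles (max e-value, min identity,
min alignment length): (1e-7, 86%, 100 nt) for RFLP probes against a
diverged reference, (1e-3, 80%, 30 nt) for SSR clone sequences, identity
raised to 90% for within-genus comparisons.  Best hits maximize bitscore
(ties: e-value, then coordinate).  Virtual PCR accepts a primer pair when
both primers hit the same chromosome on opposite strands pointing inward,
each with ≤ 1 mismatch, and the outermost span lies strictly between 150
and 1000 bp.  Collinearity blocks chain loci in genetic order per target
chromosome, breaking at > 5 cM genetic or > 1 Mb absolute physical gaps,
and keep chains of ≥ 4 loci; the pairwise-gap formulation is equivalent
to "at least one shared locus within every 5 cM / 1 Mb" for chains and is
decidable greedily, and absolute physical gaps let inverted blocks chain
naturally, with orientation assigned afterwards by the sign of the
cM-vs-bp Spearman correlation.  A locus homologous to several chromosomes
chains on each independently, so nested and overlapping blocks are all
reported.  Scaffolds are anchored to the linkage group holding a strict
majority of ≥ 2 mapped-marker hits.  Spearman p-values are exact (full
permutation enumeration, two-sided) up to 8 shared markers and use the
t-approximation beyond.

## Synthetic data

The generator emulates the study conditions of a multi-population
*B. napus*-style DH panel: by default 3 populations × 100 lines, one
100 cM linkage group with 40 uniformly placed markers, 30% bridge markers
scored in all populations (the rest in exactly one), 0.5% per-call allele
flips, 5% missingness.  Gametes follow a Markov chain along the true
order with per-interval transition probability ½·tanh(Δd/50) — the
inverse Kosambi of the gap — i.e. no interference beyond what the map
function implies, matching two-point estimation assumptions.  Segregation
distortion is single-locus viability selection by acceptance–rejection
(gametes carrying B at a distortion locus accepted with probability w),
giving an expected A:B ratio of 1/w : 1.  Homology emulates an
ancestrally triplicated genome: each linkage group is cut into segments
and every pseudo-reference segment is reused in three map segments with
random orientation, at 200 kb/cM; simulated hit tables carry one strong
true hit per marker plus Poisson spurious sub-threshold hits.

What this does **not** emulate: crossover interference beyond Kosambi's
implicit level, non-uniform marker spacing, locus duplication within a
population (paralogue confusion), genotype-call correlation between
markers of one assay, and real sequence divergence structure.  Passing
recovery tests therefore demonstrates correctness of the pipeline's
logic under its own model, not robustness to those real-data effects.

## Numerical choices and problem sizes

Recombination fractions are capped at 0.4999 before distance conversion
(Kosambi diverges at 0.5).  Ties everywhere break deterministically
(lexicographic names, earlier sources, smaller coordinates), so identical
inputs and seeds give byte-identical outputs.  Map files are normalized
so each LG starts at 0 cM; physical coordinates are 1-based inclusive,
with BED-like input converted on read.  Degenerate inputs (single-marker
groups, empty maps, markers without informative pairs) return trivial
results rather than errors wherever a trivial result is well defined.

Recovery tests and the acceptance script use 10–20 replicate seeds of
the default panel (3 × 100 lines × 40 markers) and a single-population
50-marker variant — sizes at which every stage completes in seconds while
estimator variance is still visible.

## Known biases and limitations

Two-point Kosambi distances under-measure multi-interval gaps of the
simulated crossover process (whose composition is Haldane-like), by ~4%
at 10 cM and ~14% at 40 cM, and the masking pass removes a few genuine
double crossovers at sparse subset spacing.  Consequently consolidated
and regression-consensus lengths run some 10–20% below the simulated
truth on sparse subsets (order recovery is unaffected; Spearman ≥ 0.98),
and at n = 100 lines the realized crossover count itself has ~10%
sampling spread — so length-recovery guarantees hold for the mean over
replicate seeds, not per seed.  The DAG engine inherits component-length
over-estimates by construction.  Exact conflict resolution is per
strongly-connected component; deletions interacting across components are
handled by iteration plus a global minimality pass, which is minimal in
practice but not provably minimum for adversarial graphs above the exact
search size.
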