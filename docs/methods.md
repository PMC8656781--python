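# Methods

## Model and procedure

The pipeline analyses paired tumor/normal methylation fractions (beta
values) at CpG probes. Per probe with matched pairs (t_i, n_i), i = 1…k:

- differences d_i = t_i − n_i; zero differences are dropped (classic
  Wilcoxon reduction; the Pratt alternative was considered and not adopted —
  with continuous beta values exact zeros essentially never occur);
- two-sided Wilcoxon signed-rank p-value, exact by the full sign-assignment
  null distribution when the reduced k ≤ 25 with no tied |d_i|, otherwise a
  normal approximation with tie-corrected variance and 0.5 continuity
  correction (computed via scipy.stats.wilcoxon; the test suite checks the
  exact branch against an independent full 2^k enumeration);
- the W statistic reported is the sum of ranks of positive differences.

### maxT family-wise error control

The Westfall–Young step-down maxT procedure is implemented directly (no
library provides the paired sign-flip variant). The null is invariance of
each pair's difference vector under sign flips: a permutation draws one sign
per pair and applies it across all probes, preserving the inter-probe
correlation structure. The per-probe statistic is

  T = |Σ_j s_j r_j| / sqrt(Σ_j r_j²)

with s_j the sign and r_j the midrank of |d_j| (zeros get rank 0). Under
random flips Var(Σ s_j r_j) = Σ r_j² exactly, so midrank ties need no
separate correction. Probes are ordered by decreasing observed T; for each
permutation successive maxima are taken over the ordered tail (least
significant upward); adjusted p_j = (1 + #{perm tail-max ≥ T_j}) / (B + 1),
followed by a cumulative-maximum pass that enforces step-down monotonicity.
When 2^k ≤ B the full flip set is enumerated and the result is
seed-independent; otherwise B flips are sampled from the stated seed, which
is mandatory. Observed-statistic comparisons carry a 1e-12 tolerance so the
exhaustive regime is float-safe.

Significance gating defaults to the raw p ≤ α column (α = 0.05), with the
maxT column always reported alongside and selectable — the count tables this
package reproduces are raw-p tabulations, while maxT gives the strongly
FWER-controlled view.

### Fold change

Beta medians near zero make a plain ratio explode, so the fold-change
methylation difference uses pseudo-counted medians:
r = (med_T + c)/(med_N + c) with c = 0.01 (flag-exposed), reported as +r for
r ≥ 1 and −1/r otherwise. The magnitude is therefore always ≥ 1, the sign
encodes direction (+ hyper), and a ratio of exactly 1 is reported +1 by
convention. Candidate sites are significant sites with |fold| ≥ 2.

### CpG islands and genomic context

Islands are detected from raw sequence with the Gardiner–Garden/Frommer
style criterion: 200 bp windows at 1 bp steps qualify when GC > 0.5
(strict) and obs/exp CpG = (N_CpG · L)/(N_C · N_G) ≥ 0.6 (inclusive; a 1e-12
tolerance keeps the exact-0.6 boundary float-safe); windows containing an
ambiguous base never qualify; overlapping or book-ended windows union-merge
into maximal islands whose statistics are recomputed over the merged span.
Step size, merging rule, and the obs/exp formula are deliberate choices
where the bare definition is silent; they are deterministic and validated
against a brute-force window enumeration in the tests.

Neighborhood distance is the number of bases strictly between a position
and the island (an adjacent base has d = 0): shore d ≤ 2000, shelf
2000 < d ≤ 4000, open sea d > 4000, all inclusive at the stated bounds.
North is the lower-coordinate flank of the island, so a position whose
nearest island lies at higher coordinates is N_*; ties between equidistant
islands break toward the lower island start. This convention makes
classification exactly symmetric under coordinate reflection with N/S
swapped (property-tested).

TSS distance is strand-aware with the TSS stored as a coordinate boundary
(interval start for +, half-open end for −): u ∈ [1, 200] is TSS200,
(200, 1500] TSS1500. Inside a gene the per-gene precedence is
UTR5 > FirstExon > UTR3 > Body, and one class is emitted per (position,
gene); a probe touching several genes keeps all per-gene assignments, and
count tables count each site once per category. Gene context is
coding > noncoding (miR genes count as noncoding) > intergenic; the
coding-over-noncoding precedence for probes hitting both is a documented,
configurable choice.

### Over-representation

Per-miR target sets are tested against pathway gene sets with the exact
hypergeometric upper tail P[X ≥ k] for X ~ Hypergeom(N, K, n), BH-adjusted
within each miR. This replaces the EASE-style conservative Fisher variant
of the original web tooling with the standard exact test — a deliberate
substitution since those internals are not specified. The default universe
is the union of all pathway genes, overridable; target genes outside the
universe are dropped with a logged count. Note the upper-tail p is monotone
non-increasing in the universe size at fixed (k, K, n): a larger background
makes a fixed overlap more surprising.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *design* of a 24-pair tumor/normal array
study on a single synthetic chromosome (300 kb by default):

- islands (20 × 600 bp) are built from a CG-dense tile so that every 200 bp
  window qualifies, then verified with the package's own detector before
  emission — truth labels are correct by construction; the background is
  sampled CpG-free (every CG replaced by CA), so no spurious window can
  qualify and inter-island gaps > 8 kb guarantee open-sea territory;
- gene models place coding, non-coding, and miR genes both at island
  promoters (TSS mid-island, alternating strands, with exons and UTRs) and
  in open-sea gaps, so functional and miR annotations are exercised on both
  sides of the island asymmetry;
- probes are laid out 35/18/8/39 % across island/shore/shelf/open sea,
  mirroring the genome-wide distribution of differentially methylated CpGs;
  2 % carry a SNP-proximity flag and 1 % a non-unique-mapping flag;
- normal-tissue betas are Beta-distributed around a two-component baseline
  (island probes mean 0.15, open-sea probes 0.75, shores/shelves
  intermediate) at concentration κ (default 50, i.e. s.d. ≈ 0.05 at the
  extremes); tumor betas shift the mean by +δ at planted hyper sites
  (placed on island probes) and −δ at planted hypo sites (open-sea probes),
  δ = 0.3 by default, means and draws clipped to (0.001, 0.999) with a
  logged clip count; κ = ∞ gives the noise-free limit exactly;
- every artifact draws from its own RNG stream derived from the single
  config seed, so identical configs are byte-identical end to end.

Not modelled: array chemistry (type I/II probe design, dye bias), batch
effects, tumor purity and copy-number confounding, clinical subgroups, and
realistic inter-probe spatial correlation beyond what shared pairs induce.
Passing tests therefore demonstrate the correctness of the statistical
machinery and annotation logic under a clean beta-noise model, not
robustness to technical artefacts of real arrays.

## Numerical and design choices

- Beta offset default 100 in β = M/(M + U + offset); offset 0 gives the
  literal ratio. Zero denominators become missing values with a logged
  count. An optional per-sample median-scaling normalization exists but is
  off by default (no formula is canonical for it).
- Probe exclusions are attributed to the first matching rule in the order
  sex chromosome → SNP within 5 bp → non-unique mapping, so the filter
  report partitions the input exactly.
- Intensity simulation inverts the beta formula under
  M + U + offset = total; it validates β ≤ (total − offset)/total so the
  unmethylated channel stays non-negative and the round trip is exact.
- Percentages are rounded half-up to one decimal, matching the reporting
  precision of the count tables.
- All intervals are 0-based half-open internally; BED output follows BED
  conventions.
- Site tables sort by (gating p, probe_id); all cross-tab and count outputs
  are deterministic given the config, and the run report stores output
  paths relative to the run directory so reports are location-independent.

## Problem sizes used by the validation suite

The family-wise error simulation uses 1000 replicate complete-null datasets
of 50 probes × 24 pairs with 1000 sign-flip permutations each; planted-effect
recovery uses the generator defaults (1000 probes, 200 planted effects,
24 pairs). These sizes give binomial standard errors of ~0.7 percentage
points on the FWER estimate and ~2 points on recall, which is tight enough
to detect any real miscalibration of the procedures.

## Known limitations

- The published cohort's headline discovery counts (e.g. 37 candidate CpG
  sites in 18 miR genes) depend on the real array data and reference
  annotations and are not reproducible from synthetic data; the validation
  suite instead checks the published *aggregate tables* exactly and the
  statistical operating characteristics by simulation.
- The printed miR-specific count table contains typesetting defects in its
  last rows (shifted status labels, a blank cell); the packaged fixture
  transcribes the cells as printed, and only its reconciling margins
  (170 total / 115 hypo / 55 hyper) are asserted.
- Mapping uniqueness and SNP proximity are consumed as manifest flags;
  recomputing them would require the reference genome and variant catalog.
- The island detector implements the stated window criterion only; it does
  not replicate any additional length/merging heuristics a particular
  genome-browser island track may apply.
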