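# Methods

## Statistical model and procedure

The pipeline treats a methylation study as a loci × samples matrix of beta
values β ∈ [0, 1] (methylated / total intensity) with a parallel matrix of
detection p-values, a sample sheet assigning each array to a phenotype
(RA/OA/NL), a cell line, and a passage (3/5/7), plus genomic annotation for
CpGs and transcript TSSs.

**Quality control.** Two detection thresholds act at different stages and
are deliberately kept separate: a dataset-level filter removes any locus
with detection p > 0.001 in *any* sample; within a comparison, individual
values with detection p > 0.01 (or missing) are excluded per locus. The
order (0.001 filter first, then 0.01 masking) is configurable because
either convention is defensible; the default applies both.

**Differential methylation.** For each locus with ≥ 3 usable values per
group, Welch's unequal-variance t-test gives a two-sided p-value with
Welch–Satterthwaite degrees of freedom. The test is two-sided because both
hyper- and hypomethylation are biologically expected. Degenerate inputs
follow explicit conventions: both groups constant and equal → t = 0, p = 1;
both constant but unequal → |t| = ∞, p = 0. P-values are converted to
q-values by the Storey procedure: π₀ is estimated by the smoother method
(π₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95 step 0.05, cubic smoothing
spline evaluated at λ = 0.95, clamped to (0, 1]; with m < 100 tested loci
the estimate is unstable and π₀ = 1 is used, which reduces to
Benjamini–Hochberg), then q(i) = min over j ≥ i of π₀·m·p(j)/j on the
ascending ordering, capped at 1. Q-values are computed per comparison over
its tested loci only — skipped loci never had p-values, so they cannot
enter m. A DML requires q < 0.05 **and** |Δβ| > 0.1 (both strict), with
Δβ = mean(group A) − mean(group B) and group A = RA in all shipped
configurations, so "hyper" means higher methylation in RA.

**Promoter DMGs.** The promoter window is −2500..+500 bp around the TSS,
oriented by transcription direction and inclusive at both ends (3001
positions; the ±1 inclusivity is configurable). A gene is a DMG if any
transcript window contains ≥ 1 DML; a locus inside overlapping windows
counts for every overlapped gene. Gene status is hyper/hypo when all
supporting DMLs agree and mixed otherwise. Derived comparison sets are
gene-level unions of already-called sets — q-values are not recomputed
after union, and direction statuses merge (hyper ∪ hypo → mixed).

**Enrichment.** The background N is the intersection of the database's
gene universe with the chip-covered genes (genes whose promoter contains at
least one array CpG); each pathway's size K is likewise chip-restricted,
and n counts DMGs inside that background (counting the whole DMG set
instead is exposed as an option). EF = (k/K)/(n/N); the p-value is the
inclusive upper tail P(X ≥ k) of Hypergeometric(N, K, n); q-values use the
same Storey procedure within each database, so a KEGG run never influences
a GO run. Printed percentages are 100·k/K rounded half-even to one decimal.

**Signature stability.** Spearman ρ between two samples is computed on
pairwise-complete signature CpGs with average ranks for ties (undefined,
reported missing, below 3 complete pairs). Per cell line, every
inter-passage sample pair and every within-line replicate pair is
correlated, then averaged across lines per passage pair. Δβ histograms use
fixed bin edges at multiples of 0.01 spanning [−1, 1] and are normalized so
Σ density·width = 1 exactly. For heat maps, betas are scaled ×100 and both
axes are clustered by complete linkage on Euclidean distances; with missing
data, squared differences are summed over dimensions observed in both
members of a pair and rescaled by (total/observed) dimensions, so sparse
pairs are not biased toward small distances. A pair sharing no observed
dimension is an error rather than an imputation. Trees are exported as
Newick with merge heights.

## Synthetic cohorts

The generator's defaults are the study conditions the pipeline targets:
20 000 CpGs; 11/11/6 RA/OA/NL cell lines, each assayed at passages 3, 5
and 7 (84 samples); 1000 genes on one synthetic chromosome with 10 kb TSS
spacing and alternating strands, so promoter windows never overlap and the
planted truth is unambiguous; half the CpGs placed uniformly inside
promoter windows, the rest in the inter-promoter gaps.

Per-CpG baselines come from an equal mixture of Beta(2, 18) and Beta(17, 3)
(modes near 0.1 and 0.85), reproducing the characteristic bimodality of
array methylomes. 2% of promoter CpGs receive a planted RA-group shift of
±0.3 beta (balanced hyper/hypo, signs flipped where a shift would leave
(0.02, 0.98)); these loci and their owning genes and two designated
pathways (built to draw ≥ 60% of their 25 members from planted genes, out
of 40 pathways) form the recoverable truth. A further 2% of intergenic
CpGs receive an NL-group shift of the same magnitude so that all three
phenotype groups are mutually separable — placing them outside promoters
keeps the gene- and pathway-level truth a pure RA effect.

Noise: each cell line draws a per-locus line effect (SD 0.05 beta, shared
across its passages), and each sample adds assay noise of SD 0.05 beta,
with an extra 0.03 at passage 7 to emulate drift toward senescence. Noise
is applied on the logit scale and inverse-transformed so values stay
strictly inside (0, 1); the logit-scale SD is scaled by 1/max(m(1−m), 0.15)
so the beta-scale SD matches the configured value at intermediate
methylation and shrinks toward the boundaries, as on real arrays (an
uncapped 1/(m(1−m)) factor produces unrealistic heavy-tailed outliers at
near-boundary loci). 0.5% of cells are masked missing; 0.05% of values
receive a failing detection p drawn from U(0.02, 0.2) (the rest from
U(0, 0.0009)), a realistic per-value failure rate for this array class —
note that the 0.001 QC rule then removes ≈ 4% of loci outright, since one
failing sample among 84 condemns the locus.

What the generator does **not** emulate: Infinium I/II probe-chemistry
differences, batch or chip-position effects, SNP/copy-number artifacts,
correlated methylation blocks along the chromosome, and OA-specific group
effects. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated noise model, not robustness to
array artifacts that upstream normalization is assumed to have handled.

## Numerical and design choices

- All genomic coordinates are 1-based inclusive internally; UCSC 0-based
  half-open input is converted at the file boundary only.
- Missing values are accepted on read as "", "NA", "NaN" and written as
  "NA"; reader/writer pairs round-trip exactly.
- Interval containment uses an interval tree with exclusive ends adjusted
  by +1 to honour inclusive genomic ends; tests compare against an
  all-pairs scan.
- The hypergeometric tail is inclusive of k (P(X ≥ k)), the standard
  over-representation convention.
- Enrichment tables sort by q then descending EF, with stable ties.
- Run manifests record the seed, package version, SHA-256 of every input
  and output file, and per-stage counts; determinism is defined as
  manifest equality.
- Analysis scripts and tests run the generator at the full default study
  size (20 000 loci × 84 samples, a few seconds per cohort thanks to the
  vectorized Welch path); unit fixtures use a 3 000-locus, 5/5/4-line
  cohort, chosen as the smallest size at which every structural feature
  (replicates, QC losses, planted pathways) is still exercised.

## Known limitations

- π₀ smoothing needs a few hundred p-values to be meaningful; below 100 the
  implementation deliberately falls back to π₀ = 1 (conservative).
- The published real-data headline counts (e.g. thousands of combined DMGs
  and the 0.950/0.943/0.883 passage correlations) depend on the full
  28-line cohort, which is not fully deposited; this package reproduces the
  printed enrichment-factor arithmetic exactly and validates everything
  else by planted-truth recovery on synthetic cohorts.
- Derived union sets keep their parents' q-values; no locus-level
  deduplication is attempted before gene labelling in unions.
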