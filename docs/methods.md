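# Methods

This note records the models and procedures implemented in `htrscan`, the
parameters and their defaults, why the defaults are what they are, and what
the synthetic data generator does and does not capture. All empirical numbers
quoted here are produced by this package's own test suite or by
`scripts/acceptance.py`.

## 1. Pairwise matching

`align.anchor_match` is a seed-and-extend matcher: exact k-mers (default
k = 15, encoded base-4; positions containing non-ACGT characters are skipped)
shared between query and target are chained along diagonals, allowing gaps of
at most `max_gap` (default 1000 bp) between consecutive seeds on the same
diagonal. Chains spanning at least `min_block` (default 1000 bp) become match
blocks; identity is computed by direct column comparison of the two
subsequences (the chain is gapless, so coordinates map 1:1). Both strands are
searched; minus-strand hits are reported with ascending target coordinates
and strand `-`. Overlapping blocks are resolved in favor of the one with the
most matched bases.

This matcher exists so the pipeline runs hermetically; it handles the
substitution-only divergence of the simulator exactly, and its PAF reader and
writer make external aligner output a drop-in replacement for real assemblies,
where indels and rearrangements call for a production aligner.

k = 15 keeps random 400-kbp genome pairs seed-free in practice (expected
shared 15-mers ≈ L²/4¹⁵ ≈ 0.15) while ≈99%-identical HTRs still contain
runs of ≥15 matching bases every few hundred positions. A minimum of k ≥ 11
is enforced; below that, random seed collisions dominate.

## 2. Threshold calibration

Given match blocks from a control species pair (related at a similar
divergence to the study pair, with no suspected transfer), among matches of
length ≥ `min_match` (default 1000 bp):

- `identity_threshold` = floor(maximum control identity), in percent;
- among control matches at or above that floor, `length_threshold` = the
  second-longest match length rounded **up** to the nearest 100 bp.

The second-longest (not longest) match sets the length bar so one extreme
control outlier cannot inflate it; rounding up makes the bar conservative.
With fewer than two qualifying matches the result is flagged `underpowered`
and the longest match is used. A control set with maximum identity 98.21% and
second-longest near-identical match 6,972 bp calibrates to (98, 7000) exactly
(`test_calibration_rule_reproduces_published_thresholds`).

## 3. HTR detection, masking, reporting

Matches between every strain of species A and every strain of species B that
pass both thresholds are projected onto one designated reference strain per
species. Projection through a non-reference strain uses that strain's match
blocks against its own species reference as a gapless offset map; an interval
lifts only if a single plus-strand block covers at least half of it,
otherwise the match is counted as unlifted and excluded. Projected intervals
are single-linkage merged on reference-A coordinates — any overlap of ≥1 bp
merges, adjacency does not — and each merged candidate gets:

- length (reference-A span),
- mean identity = Σ(identityᵢ · matchedᵢ) / Σ matchedᵢ over contributing
  matches (matched-bases weighting, so long confident matches dominate),
- the count of distinct supporting strain pairs,
- an id `HTR1, HTR2, …` assigned by descending length.

TE masking subtracts the union of TE intervals from each candidate;
candidates with less than `min_unmasked` (default 500 bp) of unmasked
sequence are dropped — short leftovers after masking are almost always TE
fragments, not transferred genes. TE intervals extending past the contig are
clipped with a warning. The extremity report gives, for each HTR terminus,
whether its terminal base lies inside a TE and the distance to the nearest TE
(infinity when the contig has none), plus the fraction of extremities inside
TEs. `merge_for_plotting` overlap-merges consensus intervals and keeps
regions ≥ 35 kbp as queries for genome-wide similarity plots.

## 4. Panel scanning

Each consensus HTR sequence is matched against every contig of every panel
genome. A match is kept only if one of three rules applies:

1. it covers the entire HTR (≥ `cover_fraction`, default 0.95, of the HTR
   span — alignment ends are usually trimmed a little);
2. it covers an entire contig and carries ≥ 1 kbp of matched bases (genuine
   copies split by assembly fragmentation);
3. it is longer than 10 kbp and starts or ends within 1 kbp of a terminus of
   a contig longer than the HTR (a copy running off a contig edge); at most
   the two longest such edge matches count.

Everything else — typically repeat-driven partial hits in the middle of
contigs — is discarded. Presence is the fraction of HTR positions covered by
the union of kept matches; identity is matched bases over that union, with
positions covered by several matches attributed to the higher-identity match
(or excluded entirely with `exclude_ambiguous=True`). Both quantities are
invariant to the order of the kept matches (`test_panel_scan_arithmetic`).
Genome ordering can follow the leaf order of a Newick tree; leaf names must
match genome ids exactly. `genome_size_regression` reports OLS slope,
intercept, and adjusted R² = 1 − (1 − R²)(n−1)/(n−2) of genome size on total
kept-HTR length.

## 5. Population genetics

**Filtering.** Haploid VCFs are read with pysam. Indels and non-biallelic
records are removed, then GATK-style hard filters: QD < 2, MQ < 40, FS > 60,
MQRankSum < −12.5, ReadPosRankSum < −8.0, and > 10% missing genotypes. The
rank-sum bounds are negative, following the GATK convention that strongly
negative rank sums indicate alternative alleles supported by worse reads;
both bounds are configurable. INFO fields absent from a record or its header
simply do not trigger their filter. Diploid genotypes raise `PloidyError` —
every statistic downstream assumes haploidy.

**Diversity.** π is computed per site as 2·n₀·n₁ / (m(m−1)) over the m
non-missing calls (pairwise-complete), summed and divided by the genome
length L (monomorphic sites contribute zero, so only variant records are
needed); θ_W = S / (a₁·L). Tajima's D uses the standard variance constants;
for n ≤ 3 those constants vanish and D is returned as NaN rather than a
division by zero. Standard errors for π and θ_W come from a delete-one-block
jackknife over 100-kbp windows.

**Null interval for D.** The distribution of D under neutrality is evaluated
conditional on S: `TajimaDNullBank` simulates (once) a bank of neutral
single-tree coalescent genealogies (msprime, n haploid samples), stores each
genealogy's branch-length proportions and the pairwise-difference weight of
each branch, then for any S drops S mutations multinomially on branches and
recomputes D. Reusing genealogies makes intervals for many S values cheap.
Calibration: over 200 neutral non-recombining replicates (n = 20, θ = 0.002,
L = 100 kbp), mean D = −0.055 and the 95% interval covers the simulated D in
96% of replicates (`test_tajima_d_null_calibration`). The replicates must be
non-recombining because the null conditions on a single genealogy; D over a
recombining region averages many marginal trees, has smaller variance, and
would be covered trivially (observed coverage 1.0 in that setting).

**LD.** r² is the squared allelic correlation between haploid sites over
pairwise-complete strains. `ld_decay` averages r² for site pairs within
15 kbp (MAF ≥ 0.2) in 500-bp distance bins. `ld_prune` first drops sites
with MAF < 0.05 or minor-allele count < 2, then greedily scans each contig
left to right, dropping any site with r² ≥ 0.2 to a retained site within
1 kbp upstream; the output is verified to be a fixed point. In a fully clonal
two-lineage panel every informative pair has r² = 1 at all distances
(`test_clonal_r2_is_one`), the diagnostic signature of asexual populations.

**Mating type.** Each reference idiomorph (MAT1-1, MAT1-2) is translated and
its peptide 8-mers are searched in the six-frame translation of the assembly;
the score per idiomorph is the fraction of its peptide k-mers found, and the
call is the idiomorph scoring ≥ 0.3 ("both"/"none" for anomalies). Peptide
k-mers tolerate silent nucleotide divergence, which is why the scan is done
in protein space. This replaces an external translated-BLAST dependency with
a deterministic, hermetic equivalent adequate for idiomorph presence calls.

## 6. Selection inference

**MK counting.** Site opportunities per codon are counted NG86-style: the
synonymous fraction of each codon position is the share of its three one-step
changes that preserve the amino acid; per-gene L_syn/L_rep are the average
over sequences weighted by non-missing length. Changes between two codons are
counted over all orderings of the differing positions, excluding paths through
stop codons (unless all paths do), averaging over the remainder so pathway
ties split equally. A codon column is scored when ≥ 2 in-group and ≥ 1
outgroup codons are valid; a column is polymorphic if the in-group segregates
(each minor variant compared to the major one), and fixed if the in-group is
monomorphic and differs from the outgroup consensus. Polymorphic columns do
not also count as fixed.

**Per-gene test.** NI = (PR/PS)/(DR/DS); p from the two-sided Fisher exact
test on the rounded table. The exact conditional p is conservative under the
null because the hypergeometric support is discrete — its null distribution
is demonstrably non-uniform, so no implementation can make classical exact
p-values uniform. An optional mid-p variant (half-weight on tables exactly as
probable as the observed one) restores approximate uniformity at large
counts; the property test verifies both the conservatism of the exact p and
the approximate uniformity of the mid-p variant.

**Hierarchical model.** Counts y_{g,c}, c ∈ {PS, PR, DS, DR}, are Poisson
with log λ = log L_site + β₀ + β_R·R + β_D·D + β_RD·R·D + u_g + s_g·R +
d_g·D, where R indicates replacement cells, D divergence cells, and u_g
(mutation rate), s_g (selection effect), d_g (lineage-specific divergence)
are gene-level Gaussian random effects with half-normal(1) priors on their
scales; fixed effects have N(0, 5²) priors. Inference is
Metropolis-within-Gibbs: random-walk updates per fixed effect, vectorized
per-gene proposals for each random-effect block, log-scale updates for the
three scales, with proposal widths adapted during burn-in toward 30%
acceptance. Defaults: 25,000 iterations, 10,000 burn-in, thinning 4.
Convergence is monitored by split-chain R-hat on the shared parameters;
values above 1.1 set `converged=False` on all calls and raise a warning. A
gene is classified positive/negative when the 95% credible interval of s_g
excludes zero. On 200 simulated genes with 20 planted positives at effect
+1.5 the fit recovers ≥ 80% (observed: 100%) with ≤ 5% false positives among
neutrals and ≤ 5% non-neutral calls under an all-neutral simulation
(`test_selection_recovery_and_null_error_rates`).

**Enrichment.** Per functional category, a Fisher exact test of membership
versus the selected gene set, with odds ratio, raw p, and Benjamini–Hochberg
q (`scipy.stats.false_discovery_control`).

## 7. The synthetic generator: realism and limits

Genomes are i.i.d. nucleotides at configurable GC (default 0.48). Divergence
between species and polymorphism within species are exact per-site
substitutions; there are no indels, so every truth coordinate is exact. HTRs
are planted by replacing a window of each recipient species' reference with a
donor segment mutated independently to the configured identity per recipient
— two recipient copies of a donor at identity q are therefore ≈ (2q − 1)
identical to each other, which is what detection between species sees.
Within-strain substitutions spare HTR windows so planted identities remain
exact. TEs are annotation intervals only (2-kbp elements at the configured
density; `te_at_edges` plants an element straddling each HTR terminus).
Mating types are fixed stop-free ORF cassettes appended to the assembly. SNP
panels come from a neutral msprime coalescent (with a fixed-S and a clonal
two-lineage alternative); MK tables are drawn from the same hierarchical
Poisson model the fit assumes.

Deliberate simplifications, and what they mean for interpretation:

- No indels or rearrangements: the anchor matcher's gapless identity is exact
  here; on real assemblies a gapped aligner should provide the PAF input.
- No TE sequence model: masking is interval arithmetic; real repeat-driven
  false matches are represented only through the match-keeping rules.
- MK recovery tests share the generating model with the fit, so they verify
  inference correctness, not robustness to model misspecification.
- The neutral jitter on "neutral" genes' selection effects is σ_s = 0.05 —
  small, because neutrality means a zero selection effect and the jitter
  exists only to keep the scale parameter identifiable; planted classes are
  ±1.5. Generator fixed effects default to β₀ = log 0.02, β_R = log 0.6,
  β_D = log 4, β_RD = 0, giving realistic per-gene MK tables (PS ≈ 5–15,
  DS ≈ 25–60 for 200–600-codon genes).

## 8. Numerical and reproducibility choices

- Coordinates are 0-based half-open everywhere internally; 1-based inclusive
  only in GFF3 and VCF output.
- All randomness flows from `numpy.random.default_rng(seed)`; msprime seeds
  are drawn below 2³¹. Reruns with identical seed and configuration produce
  byte-identical outputs; `manifest.json` records a sha256 per output file
  and the TSV headers carry the seed and a configuration hash (the output
  directory is excluded from the hash).
- Problem sizes in tests and in `scripts/acceptance.py` (panel lengths
  100–400 kbp, 20 detection seeds, 200 null replicates, 200 genes, 10,000
  null genealogies) are chosen to keep the full suite around one to two
  minutes while leaving Monte Carlo error well inside the asserted margins.
- Tajima's D returns NaN for S = 0 and for n ≤ 3 (degenerate variance);
  the null bank requires n ≥ 4.
- Fisher tests run on tables rounded to integers (fractional counts arise
  from pathway averaging).

## 9. Limitations

The detector assumes assemblies good enough that an HTR is spanned by one or
few contigs; the contig-edge rule compensates for fragmentation but not for
misassembly. Calibration inherits the control pair's properties — a control
pair with genuinely transferred material would inflate the thresholds.
The selection model, like any MK-framework method, conflates relaxed
constraint with positive selection when divergence times are short, and the
fixed-S null for D assumes a panmictic constant-size population. None of the
synthetic benchmarks substitute for validation on real sequence data.
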