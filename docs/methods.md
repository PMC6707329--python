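# Methods

`lncpeptidome` implements a computational-proteogenomic workflow for
discovering and quantifying polypeptides translated from long non-coding
RNAs (lncRNAs) out of peptide-level mass-spectrometry evidence, and the
downstream specificity and cancer differential-abundance analyses. The
spectrum search itself (peptide-spectrum matching, FDR control, MaxLFQ
normalization) is upstream of this package: we consume search-engine output
in a MaxQuant `peptides.txt`-like dialect and operate on it.

## The candidate database

Each lncRNA transcript is translated in the three sense-strand reading
frames with the standard genetic code (mature transcripts have a defined
orientation, so the reverse strand is not translated). The translation of
each frame is split at stop codons; every stop-free segment of at least
`min_orf_len` amino acids (default 8) is a candidate polypeptide. The
8-residue floor follows from the detection rule: a reported polypeptide
needs two tryptic peptides of at least 6 residues, which cannot both fit on
a shorter segment together with tryptic termini unless they overlap.
Codons containing N translate to `X` when the ambiguity matters (Biopython
resolves e.g. `GGN` to glycine); peptides containing `X` are removed before
matching, since they cannot be assigned to spectra.

In-silico tryptic digestion cleaves after K or R except before P,
enumerating all peptides with up to `max_missed` retained internal sites
(default 2) and at least `min_peptide_len` residues (default 6). All
coordinates in the package are 0-based, half-open.

The novelty filter discards a candidate peptide if its sequence occurs as a
contiguous substring of any canonical proteome entry. By default the match
is computed after collapsing I to L on both sides, because isobaric
leucine/isoleucine are indistinguishable by MS; the flag is exposed
(`--no-collapse-il`). Substring identity — rather than heuristic alignment
with mismatches — is the conservative, deterministic reading of "matches
the proteome": any peptide explainable by an annotated protein is removed.

## Grouping and quantification

Peptide evidence maps peptides to database entries. Transcripts whose
observed peptide sets are identical, or where one set is contained in the
other, are merged into one reported polypeptide group (subsumption
grouping, as in protein-inference tools); generalized to k transcripts, a
subset transcript joins the candidate host with the largest peptide set
(ties: lexicographically smallest leading member id), which makes the
grouping invariant to input order. A peptide mapping to two groups that
cannot be merged is non-unique and excluded from both groups' unique
peptide lists. Peptides that also map to a canonical protein never reach
this stage (novelty filter).

A group is reported only if it carries at least two **non-overlapping**
unique peptides. Non-overlap is defined on sequence intervals of a
representative polypeptide — the member segment supporting the most unique
peptides (ties: longest, then smallest entry id). Because a peptide may
occur at several positions, the count is the exact maximum over choices of
at most one interval per distinct peptide with pairwise-disjoint intervals
(intervals touching at a boundary are disjoint). Exact maximization by
depth-first search is used instead of a first-fit greedy because per-group
peptide counts are small; the brute-force enumeration over all occurrence
subsets is the test oracle.

Per-sample group abundance is the median of the unique peptides'
non-missing linear intensities (even counts: mean of the two central
values); log2 happens only in analysis. MaxQuant writes 0 for
non-quantified cells, so zeros are recoded to missing on ingest and no zero
ever enters a median or fold change. The within-context consistency of a
group's peptides is summarized as %CV = 100·sd/mean (sd with n−1 df),
and the across-context variability of single peptides by one-way ANOVA on
log2 intensities.

The two-peptide rule is enforced per dataset: a group exists if its
evidence anywhere in the table supports two non-overlapping unique
peptides, while individual samples may still be missing. A per-sample
variant would only shrink the reported matrix; the threshold is exposed as
`min_nonoverlap`.

## Specificity classes and universal expression

A group is detected in a context (tissue, cell line) when it is quantified
in at least one sample of that context (`min_samples` configurable).
Groups detected in exactly one context are *specific*, in all contexts
*ubiquitous*, otherwise *shared*; the three labels partition the groups.
Universally expressed (UExp) polypeptides are the exact intersection of the
tissue-ubiquitous and cell-line-ubiquitous sets.

Profile summaries: per-row z-scores of log2 intensities over non-missing
cells (constant rows become zeros with a warning); Spearman or Pearson
correlation with pairwise-complete deletion and a t-transform p-value
(n−2 df, undefined below three complete pairs); agglomerative clustering
(Euclidean or 1−Pearson distance, average or complete linkage) after
imputing missing cells to the row minimum, which preserves the
low-abundance semantics of non-quantification; plasma candidates are ranked
within a descending abundance profile with average ranks for ties. The
Euclidean/average defaults are the common choice for intensity heatmaps and
are recorded in the output metadata.

## Differential abundance

The two-group test is a moderated t in the empirical-Bayes style of limma.
For feature g with pooled per-feature variance s²_g on d_g residual df, a
scaled-F prior (d₀, s₀²) is fitted across features by moment matching on
log s²_g (digamma/trigamma matching; the trigamma inversion is a Newton
iteration). The posterior variance is

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

and t_g = Δ̄_g / (s̃_g √(1/n₁+1/n₂)) is referred to a t distribution with
d_g + d₀ df, capped at the pooled residual df over all tested features.
When the spread of log variances does not exceed what χ² sampling alone
implies, the prior df is infinite and s₀² is the plain mean of the
variances. At d₀=0 the statistic is the ordinary pooled t; both limits are
exposed (`d0_override`) and tested, and the implementation is cross-checked
against the reference R implementation (limma) in the test suite. Features
with fewer than `min_n` (default 2) values in either group are flagged
excluded, never silently dropped; each feature's per-group n is reported.

Stage analysis first applies a presence filter — at least 2 quantified
samples in each of stages I–IV — then a classical one-way ANOVA on log2
values across stages (zero total variance yields p=1 with a warning).
Because stage strata are typically unbalanced, stages are also pooled into
early (I+II) versus late (III+IV) and compared with an unpaired t-test;
Welch's form is the default because the pooled groups have unequal sizes
and visibly unequal spread in tumor cohorts, with the pooled-variance form
available. For patient-matched designs a paired-difference t on per-patient
log2 differences is provided; the package does not claim either form as
uniquely correct for matched tumor/normal pairs, and reports both paths.

Multiple testing uses Benjamini–Hochberg throughout (via statsmodels), with
0.05 on the adjusted p as the default significance threshold. Term
enrichment of a significant set against the universe of all quantified
groups uses the upper-tail hypergeometric probability P(X ≥ overlap), BH
across terms; term sets are intersected with the universe first.

## The synthetic cohort generator

The generator replaces the raw public-repository cohorts with simulated
panels carrying a known ground truth, so every stage is testable without
downloads. Its defaults encode the targeted study design: 14 tissues and 11
cell lines (named), 3 samples per context, 60 polypeptide groups of which
45% are context-specific, 12% tissue-ubiquitous and 8% universal (the
universal groups are ubiquitous in both panels, the remaining ubiquitous
groups cover a strict subset of cell lines — mirroring a tissue-ubiquitous
set larger than the universal set); 4 planted tryptic peptides per group; a
colon-cancer cohort of 92 tumors (stages cycling I–IV) against 30 normals
with 10% of groups differentially abundant at +2 log2 units plus a
monotone stage trend of 0.5 log2 per stage step; and a 4-sample plasma
panel in which the ubiquitous groups circulate. Universal groups are
assigned the planted fold changes first, making them the cohort's biomarker
candidates.

Planted peptides are drawn from a reduced alphabet (no K/R/P internally, no
I) with a C-terminal K/R, so digestion with zero missed cleavages
regenerates exactly the planted peptides, and I/L collapse cannot create
accidental proteome hits; transcripts are deterministic reverse
translations of the concatenated peptides flanked by stop codons. The
synthetic proteome is random sequence verified free of planted peptides; a
configurable `decoy_fraction` of planted peptides is appended verbatim to
proteome entries to exercise the novelty filter (appended, not inserted,
so decoys cannot split each other).

Intensities follow a log-normal model: log2 intensity = 25 (a typical
MaxQuant intensity scale) + group effect N(0,1) + context effect N(0,1) +
sample noise N(0, log2_sd=1) + peptide noise N(0, 0.1·log2_sd). Peptides of
one group share the sample-level signal, so within-context %CV is low
relative to between-context variation. The tumor cohort and its normal
counterpart share one biological context effect, so the planted fold change
is the only systematic disease-axis difference. Missingness is
missing-completely-at-random with probability `dropout_prob` (default 0.1);
an intensity-dependent logistic option (`dropout_model="censored"`)
reflects the left-censoring of real label-free data. Matrix-level
simulators (`simulate_de_matrix`, `simulate_stage_matrix`) generate plain
Gaussian log2 matrices for calibration studies.

What the generator does **not** emulate: peptide-level missingness
structure tied to physicochemical properties, correlated peptide noise,
batch effects, shared-peptide degeneracy beyond exact transcript-set
subsumption, and any spectrum-level features (m/z, retention time,
charge). Passing tests therefore demonstrate correctness of the pipeline's
logic and calibration of its statistics under the declared generative
model, not robustness to every pathology of real LC-MS/MS cohorts.

## Numerical choices and problem sizes

Group/interval maximization is exact (search with pruning), feasible
because groups carry few peptides. Clustering ties follow SciPy's
deterministic agglomeration order. All randomness flows through
`numpy.random.default_rng` seeded from the configuration, and the
orchestrated pipeline writes no timestamps, so re-running a configuration
is byte-identical.

Calibration studies in the tests and the acceptance script use 5,000-row
matrices at n=10/10 over 10–50 replicates for the two-group pipeline, and
20-row × 4-stage × 5-sample matrices over 25–50 replicates for the stage
pipeline — sizes at which the Monte-Carlo error of the reported rates
(type-I error, FDR, power) is a small fraction of the margins being
checked.

## Known limitations

- The novelty filter is exact-substring only; homologous-but-mutated
  peptides are retained by design.
- The moderated t supports two-group designs (plus the paired-difference
  variant); there is no general design-matrix interface, no trend/robust
  empirical Bayes, and no observation weighting.
- Grouping operates on transcript-level peptide sets; it does not
  re-examine segment-level ambiguity within a transcript.
- Specificity calling is presence/absence; it does not model quantitative
  enrichment of a context.
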