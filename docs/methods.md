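# Methods

This note documents the models implemented in `tmtnet`, the defaults and
the reasoning behind them, what the synthetic cohort does and does not
emulate, and the numerical choices made where the design was open.

## Junction summarization and the alt-EEjxn peptide database

Junction evidence is consumed as per-read records (chromosome, strand,
last exonic base of the 5′ exon, first exonic base of the 3′ exon, and the
read's exonic overlap on each side, in nucleotides). A read supports a
junction only when **both** overlaps are ≥ `min_overlap_nt` (default 4 nt);
junctions with fewer than `min_reads` (default 2) qualifying reads are
dropped. The 4-nt rule is applied as a read-support criterion, not as a
peptide criterion — peptides instead must have at least one residue fully
encoded on each side of the junction, which is the weakest condition under
which a peptide identification genuinely reports the splice.

A junction is *alternative* iff at least one other junction in the set
shares its donor (left) or acceptor (right) end on the same chromosome and
strand; all others are singletons or constitutive junctions and are
excluded from peptide extraction.

**Translation frame.** When the transcript-5′ base of the junction lies in
an annotated CDS, the annotated frame is used (computed from the CDS
coordinate of that base, honoring GFF3 phase); otherwise all three frames
are translated. Open reading is truncated at stop codons: only the
stop-free segment containing the junction can yield peptides. Each peptide
records which frame produced it.

**Flanks.** Up to `flank_nt` (default 120 nt) of sequence is taken on each
side, truncated at annotated exon boundaries and chromosome ends. 120 nt
is enough to encode any ≤ 50-aa peptide with one retained bond entirely
within the window.

**Digestion.** LysC cleaves C-terminal to every lysine including Lys-Pro
bonds (the \[K|P\] rule). Output contains the fully cleaved products plus
merged forms that retain up to `max_kp_miscleavage` (default 1) K|P bonds —
only K|P bonds may be retained, mirroring "with and without miscleavage at
proline". Trypsin mode (cleave after K/R, not before P; miscleavage budget
applies to any site) is provided for cross-method comparison only.

**Deduplication.** A peptide sequence arising from ≥ 2 distinct genomic
loci is removed entirely: a shared sequence cannot be attributed to one
locus at quantification time. A sequence present in the LysC digest of the
canonical proteome (same miscleavage budget) is a canonical duplicate and
leaves the novel set. Survivors are appended to the canonical FASTA with
headers encoding junction coordinates (1-based inclusive), strand, frame
and the miscleavage flag.

Peptide length bounds default to 6–50 aa, the usual MS-observable range.
An independent brute-force enumerator (all frames × all digestion products
× span filter) is kept in the test suite and acceptance script and must
set-equal the implementation on toy genomes.

## TMT normalization

Protein-level abundances are log₂(sample/GIS) per batch; a zero or absent
intensity on either side is missing. Filters, in order:

| parameter | default | meaning |
|---|---|---|
| `outlier_bound` | log₂ 100 ≈ 6.6439 | \|log₂ ratio\| at or beyond a 100-fold change is excluded |
| `max_bad_gis_batches` | 4 (of 8) | feature dropped if GIS is 0/NA in more batches |
| `max_missing_protein` | ⌊(n−1)/2⌋ = 23 at n = 47 | strict "< 50% missing" cap |
| `max_missing_peptide_kme` | 25 (of 47) | missingness cap for peptide kME assignment |
| `drop_sub_one` | true | linear values < 1 removed before log₂ (peptide path) |

The bound is stored at full precision log₂ 100; a rounded 6.64 supplied in
a config is widened back to the exact value, so a ratio of exactly 100 is
excluded. The missingness cap generalizes 23-of-47 as the largest integer
strictly below half the cohort.

The peptide path sums PTM-modified forms of a base peptide (N-terminal
acetylation, N/Q deamidation, M oxidation, TMT labels — written as
bracketed tokens, e.g. `[Oxidation]MAK`) on linear scale, then rescales
each batch by (grand mean of batch GIS means)/(batch GIS mean) so all
batch GIS means coincide, then log₂-transforms. Batch scaling is
idempotent and preserves within-batch ratios exactly. An optional
`equalize_channel_totals` step (equal column sums within batch) is
available as a simple stand-in for vendor within-batch normalization; it
is off by default because the synthetic generator plants batch-level, not
channel-level, effects. No step imputes: missing stays missing.

## Cell-type deconvolution

Weights for four brain cell types are estimated per sample by non-negative
least squares of the linear-scale marker mixture against a reference
profile of marker means in pure cell types, then row-normalized to sum
to 1 ("DSA-style"; the digital sorting literature specifies the estimator
only through its software interface, so NNLS + simplex normalization is
this package's concrete choice). Only markers with **no** missing values
across samples enter the fit; a missing marker is dropped, never imputed.
On noiseless mixtures recovery is exact; at log₂ noise sd 0.1 the mean
absolute weight error at n = 47 is well below 0.05.

## Bootstrap covariate regression

Per feature, the linear model `value ~ 1 + covariates + group` is fit on
available cases and on `n_boot` (default 1000) case-resamples with
replacement; coefficients are aggregated by the mean (median available).
Only the covariate components, evaluated at covariates centered over the
feature's observed samples, are subtracted — centering makes the
subtraction mean-preserving per feature, and the group term is estimated
but never removed. Sex is a 0/1 indicator. Features with fewer than
(model terms + 2) observations are left unregressed and flagged, mirroring
peptides that cannot be regressed in sparse data. Rank-deficient
resamples (e.g. a bootstrap draw missing a group level) are redrawn with a
logged count; after 100 rounds any irreducible remainder falls back to the
full-data least-squares fit. Resampling is vectorized (batched normal
equations), so 1000 iterations over hundreds of features take seconds.

The two-pass scheme first removes the four cell-type weight components,
then age/sex/PMI. Because weights sum to one, their centered versions have
rank 3; three of the four columns enter the design, which spans the same
removal space. The two-pass output feeds differential abundance only — the
network is built on the covariate-only regressed matrix.

## Weighted correlation network

Similarity is biweight midcorrelation with the standard 9-MAD weighting,
computed on pairwise-complete observations; a vector with zero MAD falls
back to Pearson standardization (per vector, logged). The all-pairs matrix
version transforms each feature once over its own observed entries and
normalizes pairs over shared entries — identical to pairwise bicor on
complete data and a close approximation under missingness.

Signed adjacency is ((1 + r)/2)^β. The soft threshold is chosen as the
lowest power (step 0.5) whose signed scale-free fit R² — regression of
log₁₀ p(k) on log₁₀ k over 10 equal-width connectivity bins, sign taken
from the negated slope — reaches 0.80; if no power reaches it, the first
power whose gain falls below 0.01 (the plateau) is used and logged. Equal
sized planted blocks are deliberately *not* scale-free; the benchmark for
the R² ≥ 0.80 behavior uses heterogeneous module sizes and strengths.

TOM uses the mean-connectivity denominator:
TOM_ij = (Σ_u a_iu a_uj + a_ij)/((k_i + k_j)/2 + 1 − a_ij), symmetric in
[0, 1] with unit diagonal.

**Module detection** is a specified simplification of the blockwise
procedure: average-linkage clustering of 1 − TOM; a static cut at a
deepSplit-controlled fraction of the tallest merge (0.99, 0.98, 0.97,
0.96, 0.95 of max height for deepSplit 0–4); clusters below
`min_module_size` (17) dissolve to grey; a PAM-like stage reassigns each
assigned feature to the module of its highest kME when that exceeds its
current kME; modules whose eigenproteins are closer than
`merge_cut_height` (1 − correlation < 0.07) merge iteratively; labels are
ordered by size (M1 largest) with ties and input order broken by feature
id. This reproduces the four behaviors that matter (split, dissolve,
reassign, merge) without reimplementing hybrid dynamic tree cutting; exact
dendrogram-respecting cut heights will differ from WGCNA's.

**Eigenproteins** are first right-singular vectors of the standardized
member submatrix (missing values mean-imputed for the decomposition only),
scaled to unit sample variance (ddof = 1) and sign-oriented so the mean
member correlation is non-negative. kME is bicor(feature, eigenprotein)
for every feature × module. Module–trait correlations use bicor with a
Student-t p-value, except MMSE, which is monotone-but-bounded and uses
Spearman.

## Differential abundance and enrichment

One-way ANOVA on available cases, then Tukey HSD with the Tukey–Kramer
statistic q = |m_a − m_b| / √(MSE/2 · (1/n_a + 1/n_b)) for the unequal
group sizes (13/14/20), referred to the studentized range with k groups
and N − k df. Large batches of tail probabilities are served from a dense
512-point interpolation grid per (k, df) — direct evaluations agree with
`scipy.stats.tukey_hsd` to ≥ 6 decimals and the grid error is far below
reporting precision. Zero within-group variance with equal means gives
F = 0, p = 1 by convention. Under the global null the familywise rate of
the three Tukey contrasts sits at the nominal 5% while each single
adjusted contrast stays below it — that is what family control means, and
the calibration tests assert exactly that.

Enrichment is the hypergeometric upper tail (one-tailed Fisher exact) or
the standard two-sided Fisher exact (sum of outcomes no more probable than
observed), with BH correction applied across the family of tests made in
one call (per analysis surface). The alt-EEjxn quantifiability rule keeps
peptides with ≥ 2 measurements in ≥ 2 case groups. Peptides are assigned
to the module of their highest kME; more than 25 of 47 missing values
forfeits assignment, guarding against spurious correlations.

## The synthetic cohort: what it emulates and what it does not

The generator reproduces the study's *statistical* structure: 47 samples
(13 control / 14 AsymAD / 20 AD) in 8 TMT 10-plex batches, GIS on channel
126, samples randomized to batches within group so groups stay balanced
across batches. Intensities are log-normal on linear scale; every planted
effect is additive in log₂: group shifts (AsymAD = half the AD shift),
covariate slopes (age 70–100 y, PMI 4–20 h uniform, sex 0/1), module
latent factors (module M1 tracks a pathology score that also drives the
CERAD/Braak/MMSE/molecular traits), and batch multiplicative effects. The
GIS channel carries each feature's base intensity times the batch effect,
so its expectation is the cohort grand mean — the real GIS is a pool of 60
external samples, and the grand-mean model is an explicit approximation.
Cell-type markers are generated as reference-profile × weight mixtures on
linear scale (weights Dirichlet, glia rising and neurons falling with
severity), which makes digital-sorting recovery well-posed; the reference
is emitted on the observed ratio scale. A configurable fraction of
features is emitted as 2–3 modified forms whose intensities sum exactly to
the base signal. Default problem sizes (300 features; benchmarks of
100–1000 features) are chosen so the full suite runs in well under a
minute per stage while keeping every estimator in its intended regime;
they are deliberately far below the study's 6533 proteins, so absolute
counts (proteins quantified, modules found, differential hits) are not
comparable to the study — recovery *properties* are what the synthetic
cohort certifies.

Not emulated: raw reads and spectra, chromatographic artifacts,
channel-level (as opposed to batch-level) normalization effects,
peptide-to-protein roll-up ambiguity, and informative missingness
(missing values are missing completely at random).

## Known limitations

- The module detector is a simplification; on real data its partitions
  will differ in detail from hybrid dynamic tree cutting, especially for
  nested or weakly separated modules.
- Matrix bicor under missingness is an approximation to strict
  pairwise-complete bicor (each vector is transformed once, not per pair).
- The DSA-style estimator assumes the reference profile is on the same
  scale as the mixture; reference mismatch biases weights.
- Two-sided overrepresentation is the standard two-sided Fisher exact;
  other definitions (doubling, mid-p) exist and give different values on
  small tables.
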