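# Methods

This note records the statistical model behind each module, the
conventions chosen where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Variant inclusion model

The unit of analysis is the *novel nonsynonymous singleton*: an allele
observed exactly once within its sequenced cohort, absent from the
supplied reference allele sets (dbSNP-style and exome-variant-server
style lists, matched exactly on chrom/pos/ref/alt), and below the rare
frequency ceiling (1%). Singleton status is evaluated within each
sequencing screen (Sanger set, population-control exomes, consortium
exomes) rather than pooled, mirroring how such cohorts are screened
sequentially; pooled counting is available as an option. The index de
novo variant that motivates a targeted screen is excluded from the
overall burden comparison — counting it would condition on the
observation that triggered the study — but retained in all
deleteriousness analyses.

Exome site QC mirrors production-centre criteria with cutoff operators
fixed as follows: missingness exclusion is inclusive at 10%
(`≥ 0.10`); mean-coverage exclusion is strict (`< 17` Broad profile,
`< 12` Baylor); the minor-allele-support rule fires when a strict
majority (>50%, ties keep the site) of minor-allele calls either have
fewer reads than the profile minimum or a balance of depth (reference
reads / total reads) strictly above the profile ceiling (0.66 / 0.75).
A site with no minor-allele calls passes the rule vacuously (logged).
Whether the support/balance rule aggregates per call or per site is not
well determined in the field's descriptions; per-call evaluation with
majority aggregation is implemented.

## Conservation binarization

Three measures, three cutoffs: PhyloP ≥ 1.3 (≈ P = 0.05 for
conservation), GERP ≥ 5, ConSurf < 0 (ConSurf normalises so conserved
residues are negative). PhyloP/GERP cutoffs are inclusive; ConSurf is a
strict less-than, so a residue exactly at the average is not counted.
Binarization is monotone in each score by construction. Because every
analysed variant is a singleton, carriers and variants are in
bijection; the functional matrix is subject-indexed (the permutation
unit is the subject), with all-zero rows padding non-carriers up to the
cohort sizes.

## Burden statistics

Right-tailed Fisher exact P = Σ P(X ≥ a) under the hypergeometric law
at fixed margins (the one-sided alternative: more case carriers). The
reported odds ratio is the sample cross-product; the conditional MLE is
deliberately not used for reporting because the cross-product is what
such studies print. Two CI methods: Woolf log-interval (default;
Haldane–Anscombe 0.5 correction when a cell is zero) and the exact
conditional interval solving the noncentral hypergeometric tail
equations at α/2 (via `scipy.stats.nchypergeom_fisher` and Brent root
finding). Multiplicity: `min(1, m·p)` with m = 2 by default (two genes
screened). A rounding convention worth stating: corrected values are
conventionally displayed as twice the *displayed* per-test P, so a
tail of 0.0423 is shown as 0.042 and its doubled value as 0.084, even
though the unrounded doubled tail (0.0845) would round to 0.085.

## Max-ratio permutation test

Statistic: the maximum over measures of the case/control
carrier-proportion ratio. Conventions, applied identically to observed
and permuted data so the test is well-defined: ratio = +∞ when the
control proportion is zero and the case proportion positive; ratio = 1
when both are zero. Null: uniform reassignment of case/control labels
with group sizes fixed, implemented as a Fisher–Yates shuffle of an
index vector over all subjects (non-carrier rows cannot change the
counts, so only carrier rows are re-aggregated per permutation). P is
the plain proportion of permuted statistics ≥ the observed one — not
(k+1)/(n+1) — with ties counting toward the numerator (conservative),
and an absolute 1e-12 guard on the float comparison. The Monte-Carlo
standard error √(p(1−p)/n) is reported alongside.

The exact oracle groups carriers by distinct indicator pattern and sums
multivariate hypergeometric probabilities over all compositions of
pattern counts into the case group. Its cost is ∏(countᵢ+1) over
distinct patterns, so it enforces both a carrier bound (200) and a
composition bound (5×10⁶) and otherwise directs callers to the
Monte-Carlo path. On the bundled fixture (29 carriers, 6 distinct
patterns) the oracle gives P = 0.00970.

## Structure rubric

The published criteria hierarchy (core vs surface; hydrophilic residue
into hydrophobic core environment; size change; conserved surface
patch; charge/size change on a conserved patch; truncation) fixes the
*shape* of the scheme but not per-criterion weights. The default
weights (truncating +3; core: hydrophilic-into-hydrophobic +2, size
large +2 / moderate +1; conserved surface: charge +2, size large +2 /
moderate +1; unconserved surface +0) are one consistent instantiation,
fully overridable via `RubricWeights`, with classification at score
≥ 3. Residues beyond the alignment limit (451) are never assessable.
The bundled structural-annotation table is synthetic — constructed so
the default rubric reproduces the fixture's printed classifications —
and is labelled as such; it demonstrates the rubric's mechanics, not
the original structural curation.

## Ancestry QC

Genotype dosages are mean-imputed per SNP, standardised
(zero-variance SNPs dropped with a warning) and decomposed by SVD;
eigenvalues are of the subject covariance, and each component's sign
is fixed so its largest-magnitude loading is positive, making results
deterministic. The outlier rule computes Q1/Q3 with
linear-interpolation quantiles (the common statistics-software default;
the original software's convention is not recoverable) over the study
cluster and excludes subjects beyond Q3 + k·IQR (k = 5) on any of the
first 3 components. One-sided-above-Q3 is the default reading of the
rule; a two-sided variant and a joint Euclidean distance-from-median
variant are provided because the published phrasing is ambiguous
between per-component and combined-distance thresholds.

## Co-expression contrast

Spearman rho (average ranks for ties) between the target gene and each
module gene, vectorised as Pearson on ranks; genes absent from the
matrix are skipped and countable by the caller. The contrast is a
two-sided Wilcoxon rank-sum on module vs background rho samples, exact
for combined n ≤ 50 without ties, else the tie-corrected normal
approximation. The default background is all matrix genes minus the
target, *retaining* module genes (matching the published style of
comparison against "all brain-expressed genes"); note that this
overlap makes the null conservative, so calibration experiments use
the disjoint option (`exclude_module_from_background=True`). Density
export uses a fixed absolute Gaussian bandwidth (h = 0.1) on a grid
spanning the data ± 3h — deliberately not a scaled-by-σ bandwidth, so
plots are comparable across gene sets. Top-k lists break rho ties by
gene id for determinism.

## Synthetic data: what it emulates, and what it does not

`gen_functional_matrix` draws per-subject indicator triples from a
Gaussian-copula threshold model: a shared latent normal per subject
mixed with per-measure noise at weight ρ (`measure_correlation`),
thresholded at the per-group, per-measure carrier rates. This gives
*exact* marginal carrier rates (controls at the base rate, cases at
base × per-measure enrichment) and concentrated graded patterns
(111/110/100/000), which is why it was chosen over a
latent-Bernoulli-with-flip-noise mechanism: flip noise cannot hit
unequal per-measure marginals exactly. Defaults are study-scale
(2,196/3,389, control rate 9/3,389, enrichment ≈ (2.9, 2.4, 2.3),
ρ = 0.8).

`gen_genotypes` uses Balding–Nichols-style drift (Beta around ancestral
frequencies, divergence parameter F) for the main populations, plus an
optional strongly diverged population for planted ancestry outliers. No
linkage disequilibrium or haplotype structure is simulated, so
recovery results speak to the outlier rule's behaviour under clean
population structure, not to LD-pruning practice. `gen_expression` is a
one-factor model (target and module load at 0.8 over noise sd 0.6,
background independent) — sufficient for calibration and recall
experiments, but without the spatio-temporal structure of real brain
expression data. `gen_callsites` plants QC violations just past each
cutoff and clean sites comfortably inside all cutoffs, so
planted-recovery tests are exact by design. All generators are
bit-reproducible given the seed.

Passing calibration/recovery tests therefore show that the statistics
are correctly implemented and well calibrated under their model
assumptions; they do not certify behaviour on real cohorts with LD,
batch effects, or relatedness.

## Problem sizes and determinism

The bundled fixture analyses run in well under a second; the
permutation test costs ~0.1 ms per permutation at 5,585 subjects
(10,000 permutations ≈ 1 s). Calibration suites use 1,000 synthetic
replicates at reduced scale (e.g. 300-subject cohorts at a 2,000-fold
higher carrier rate than the study, 340-gene expression matrices, 400
permutations per replicate) — chosen so that permutation P values have
enough resolution at α = 0.01 while the suites stay interactive. All
randomness flows through `numpy.random.default_rng` seeds; outputs are
identical across runs given (seed, n_permutations).

## Known limitations

- The rubric weights are a scaffold, not the original graders'
  judgement; only the fixture's printed classes are authoritative.
- The exact-conditional CI convention (central, α/2 each tail) is one
  of several exact constructions and will not reproduce every printed
  interval from other software.
- `exact_p` is exponential in the number of distinct carrier patterns.
- The greedy case-control matching used for consortium cohorts and any
  liftover/annotation retrieval are out of scope; conservation scores
  are inputs, not computed here.
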