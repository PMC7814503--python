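# Methods note

This note records the statistical methods implemented in `envmeta`, the
exact conventions used, and the rationale for choices that could have
gone another way.

## Genotype handling

Genotypes are alt-allele dosages in {0, 1, 2} with a sentinel (−1) for
missing calls, stored as a SNP × accession `int16` matrix. Minor allele
frequency is computed on non-missing calls as min(p, 1 − p) of the
alt-allele frequency. The standard quality filter keeps a SNP when its
missing rate is ≤ 0.20 **and** its MAF is ≥ 0.05; an all-missing SNP has
undefined MAF and is always removed. The filter is idempotent because
removing SNPs never changes any remaining SNP's per-column statistics.
VCF input (via cyvcf2) is restricted to biallelic SNP records; skipped
records are counted, not silently dropped.

## Population structure

* **PCA** — mean-imputed, column-centered dosages decomposed with
  scikit-learn's exact SVD solver. Three PCs are the default covariate
  set for association scans.
* **Kinship** — VanRaden's first method: centered dosage cross-product
  scaled by 2 Σ pᵢ(1 − pᵢ). The matrix is symmetric PSD up to numerical
  noise; the mixed model rejects matrices with eigenvalues below a small
  negative tolerance and suggests jittering.
* **IBS distance** — 1 − mean allele-sharing over pairwise-complete
  sites, computed with one-hot matrix products; feeds neighbor-joining
  (scikit-bio's `nj`, Saitou–Nei with negative branch lengths clamped to
  zero). Additive distance matrices are recovered exactly, which the
  test suite checks on four-taxon trees.

## Single-marker association

Two models per environment:

* `lm` — OLS of phenotype on intercept + PCs + dosage; missing
  genotypes are dropped pairwise per SNP. Complete SNPs are tested in a
  single vectorized pass using Frisch–Waugh–Lovell residualization (QR
  of the covariate block); SNPs with missing calls fall back to a
  per-SNP loop. The marker t-test agrees with an explicit
  normal-equations oracle to 1e-10.
* `mlm` — P3D/EMMAX shortcut. The variance ratio λ = σ²g/σ²e is
  REML-estimated **once** on the null model: the kinship eigenbasis
  diagonalizes the covariance, the profiled REML log-likelihood is
  maximized over log λ on a 61-point grid refined by bounded scalar
  minimization, and every marker is then tested by GLS after rotating
  with Uᵀ/√(λs + 1). Missing genotypes are mean-imputed before rotation
  (the rotation mixes individuals, so pairwise deletion is not
  available). Consequence: on complete data `mlm` with identity kinship
  reproduces OLS to machine precision, while on markers with missing
  calls the two models legitimately differ because they use different
  data conventions.

Monomorphic markers and markers with too few complete observations are
reported in a per-scan `skipped` map with reasons rather than silently
omitted. P-values are floored at 1e-300 to keep −log₁₀ finite.

## Meta-analysis

Per-marker p-values from the k available environments are combined with
Fisher's statistic X² = −2 Σ ln pᵢ, referred to χ²(2k). Because 2k is
even, the survival function has the closed form
e^(−x/2) Σ_{j<k} (x/2)^j / j!, which the package exposes as an internal
oracle; the production path uses scipy's chi-square survival function
and must agree with the series to 1e-12. A marker absent from some
scans is combined over the scans that contain it (per-marker k).
Significance is Benjamini–Hochberg at q = 0.01 on the combined
p-values; `envs_significant` counts, per marker, the environments in
which it passed a per-scan BH at the same q, which is what exposes the
"combined-significant but individually weak" pattern.

BH is implemented as the classical step-up rule and validated against
exhaustive enumeration on short vectors and against statsmodels'
adjusted p-values.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosages over
pairwise-complete accessions, computed with nan-aware matrix products.
The decay profile is a LOESS fit (statsmodels lowess) of r² against
inter-marker distance; the decay distance is the first distance at
which the fitted curve drops below the unlinked background, defined as
the 99th percentile of r² between markers on different chromosomes. If
the curve never crosses the background the profile reports an explicit
no-decay sentinel instead of extrapolating.

## Two-locus epistasis screen

For a candidate pair the LRT compares Gaussian maximum likelihood of
`y ~ 1 + PCs + m1 + m2 + m1·m2` against `y ~ 1 + PCs`, referred to
χ²(3). The full model deliberately includes the marginal terms, so the
test measures the pair's joint explanatory power; a redundant tag pair
inside one strong-effect LD block can therefore compete with the true
interacting pair, which is why recovery is asserted at the LD-block
level and as a majority across seeds rather than per-panel. Candidates
come from a relaxed BH prescreen (q ≤ 0.1) of a single-trait scan, and
all C(n, 2) pairs are tested; degenerate pairs (constant or collinear
markers) are skipped with reasons.

## Growth-habit classification

* Vernalization response from unvernalized days to flowering:
  insensitive ≤ 73 d, intermediate 74–129 d, sensitive ≥ 130 d; the
  assay is censored at 154 d, so censored observations classify as
  sensitive. Missing DTF → unclassified.
* VRN-H2 status from the three ZCCT-H genes: all absent →
  complete deletion; all present → intact; any other known combination
  → partial deletion; any unknown flag → missing. Printed assay labels
  ("Deletion ZCCT_Ha ZCCT_Hb", "Partial deletion", "Intact …") are
  parsed into these calls.
* Facultative growth habit requires the full key: complete VRN-H2
  deletion AND intact-intron-1 VRN-H1 AND truncated HvFT3 AND
  vernalization insensitivity. Intact VRN-H2 with a vernalization
  requirement is winter; insensitive accessions missing part of the key
  are spring-like; anything needing an unknown field is unclassified
  rather than guessed.

## Summaries and field-design support

* Top-fraction selection takes floor(frac · n) accessions by mean WS
  (n counted after dropping accessions with no WS data); ties at the
  cutoff break lexicographically by accession id so selection is
  deterministic. A fraction that floors to zero warns and returns an
  empty selection.
* Clade means round half-up (conventional rounding), not banker's
  rounding — on the packaged 44-accession table this changes one clade
  mean (64.5 → 65) and is required to reproduce the published-style
  integers.
* Augmented-design adjustment (Type II modified augmented design):
  `primary` subtracts each block's primary-check deviation from the
  grand primary-check mean; `secondary` corrects by block means over
  all checks. Relative efficiency is the ratio of replicated-check
  variance before/after adjustment, evaluated on checks **not** used to
  build the correction; RE ≤ 1 means the adjustment adds noise and raw
  values should be kept.
* Candidate genes: for each placed significant marker, genes on the
  same chromosome overlapping it (distance 0) or within a window of its
  position (distance = gap to the nearest gene edge), sorted by
  distance. Unplaced markers are skipped.

## Synthetic panels

The simulator is a Balding–Nichols model: ancestral allele frequencies
drawn from the configured MAF range, two subpopulations (default 60/40,
matching a 2-row/6-row split) with divergence parameter F, and block LD
created by copying a per-block template haplotype signal with a small
flip probability. Winter-survival phenotypes are
intercept + Σ effect · dosage + Gaussian noise per environment, clipped
to [0, 100], with per-QTL environment-activity masks; DTF comes from a
3×3 two-locus epistasis lookup plus noise, censored at 154 d.
Phenotypes are generated from the complete dosage matrix and
missingness is masked afterwards, so ground truth is exact. All
randomness flows from one seeded generator; derived sub-seeds stay
below 2³¹.

Default scale (882 accessions × 5,725 SNPs on 7 chromosomes, 10
environments) mirrors a realistic winter-barley panel; tests and
examples down-scale it for speed. The "moderate effect" used in the
recovery acceptance (effect 3 on noise sd 10, active in 6 of 10
environments) was fixed **before** the acceptance thresholds were
frozen, by choosing the regime in which single-environment scans
rarely reach per-scan significance while the combined test almost
always does — the regime the meta-analysis exists for.
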