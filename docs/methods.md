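# Methods

## Stage 1: the SNP mixed model and its solver

The model for one trait is `y = Xb + Z1 g + Z2 a + e` with
`g ~ N(0, I σ²a/m)`, `a ~ N(0, A w σ²a)` and `e ~ N(0, D σ²e)`,
`D = diag(1/EDC)`.  `X` is a column of ones; the polygenic ratio `w`
defaults to 0.4.  The solver assembles the full Henderson coefficient
matrix

    C = W' R⁻¹ W + blockdiag(0, I·m/σ²a, A⁻¹/(w σ²a)),   W = [X Z1 Z2],

factorises it by dense Cholesky and obtains the prediction-error
variances (PEV) of `g` from the diagonal of the g-block of `C⁻¹`
(LAPACK `dpotri` on the cached factor).  `C` is positive definite
whenever the variances are positive and animals are not duplicated, so
Cholesky cannot silently produce a wrong answer; a non-positive pivot
raises with the offending block named.  The factorisation does not
depend on `y`, so replicate traits on the same bulls reuse it
(`MmeSystem.solve_many`), which is what makes the 200-replicate
calibration study cheap.  Dense factorisation is intentional: the
target scale (dimension `1 + m + n_pedigree` up to a few thousand) fits
comfortably in memory, and a dense solve gives the exact PEVs the Wald
test needs without iterative-solver approximations.

Variance components are inputs, not estimates.  `variances_from_heritability`
derives them from a trait heritability h² and the observed DRP variance
using standard deregression algebra: a bull's DRP is his true breeding
value (variance `(1+w)σ²a`) plus noise of variance `TBV·(1−rel)/rel` at
reliability `rel = EDC/(EDC+k)`, `k = (4−h²)/h²`; equating the noise to
`σ²e/EDC` gives `σ²e = (1+w)σ²a·k`.  This keeps the generator and the
analysis on the same scale without a REML step.

## Wald standard errors: two regimes

For a random effect u with prior variance G and BLUP û, two variances
can stand behind `W = û/SE`:

* `Var(û) = G − PEV` — the variance of the BLUP itself;
* `PEV = Var(û − u)` — the prediction-error variance.

Which one yields a calibrated test depends on who dominates, the prior
or the data.  In a diagonalised ridge picture with per-effect
information d and penalty λ, the null-variance ratios are `d/(d+λ)`
against PEV and `λ/(d+λ)` against `G − PEV`.

**Stage 1 is prior-dominated** (m SNPs ≫ n bulls, λ = m·σ²e/σ²a huge):
`W = ĝ/√PEV` would have null variance `d/(d+λ) ≪ 1` — at this package's
calibration conditions about 0.02, i.e. a genomic-control λ of ~0.02 and
essentially zero power at panel-wide thresholds.  The default is
therefore `SE² = σ²a/m − PEV`, the BLUP-variance convention; Gualdrón
Duarte et al. (2014, BMC Bioinformatics 15:246) show the resulting
statistic equals the single-marker generalised-least-squares Wald test
with the rest of the genome as background, which is the accepted way to
obtain p-values from SNP-BLUP.  `se_method="pev"` remains available.

**Stage 2 is data-dominated** (few terms, tens of SNPs per term, light
shrinkage): there `PEV` converges to the GLS standard error and the
PEV-based Wald test is the appropriate one; the BLUP-variance convention
would collapse toward `σ²p` and lose all power.  The term model
therefore tests `W = p̂/√PEV`.

A strict global null (no SNP carries any effect) is analysed with
variance components that assume the trait's heritability, so the
assumed covariance `V = V₀ + Z1 G1 Z1'` overstates the truth `V₀` and
the stage-1 test is mildly conservative by construction: the exact null
variance of W is deflated by ≈ `V₀/V` (measured ≈ 0.91 at the
calibration study's conditions, giving a type-I rate of ≈ 0.039 at the
nominal 0.05 and λ ≈ 0.90).  Under the model-consistent alternative
(polygenic SNP effects present) the same computation gives exactly 1.
The deflation factor shrinks as the SNP share of the phenotypic
variance falls, which is why low-heritability traits sit close to
λ = 1.  Family-wise error control, the guarantee that matters for
declaring SNPs, holds with margin either way.

λ is the genomic-control definition median(W²)/0.4549 (the 1-d.f.
chi-square median); the mean-based variant is not used.  "Variance
explained" has no unique definition for shrunken joint estimates; the
convention here is the empirical variance, over the analysed bulls, of
the score built from centred significant-SNP columns times their
estimated effects, divided by var(y), as a percent.  Because BLUP
shrinks, this underestimates the generating contribution unless
non-causal variance is small; the unit test that checks recovery against
the ground-truth score constructs exactly that regime.

## QC and imputation

SNPs are dropped when MAF < 0.01 (allele frequency from non-missing
calls) or call rate < 0.99, in that order of accounting; the filter
report keeps both counts.  Remaining missing calls are replaced by the
per-SNP mean of called genotypes — a real value in [−1, 1] — which keeps
the MME well defined without modelling linkage disequilibrium.  Missing
genotypes carry a dedicated sentinel (−9), never 0, since 0 is a valid
heterozygote code.

## Annotation and the term-model inputs

A SNP is assigned **every** gene on its chromosome within 5,000 bp
(distance 0 inside the 1-based inclusive interval, otherwise the
distance to the nearer end; strand ignored), not only the closest one —
a single SNP can mark several functional elements.  The join is
implemented with sorted-position window lookups and is cross-checked
against an all-pairs scan in the tests, including the 5,000-in /
5,001-out boundary.  Chromosome name sets that do not intersect raise
instead of producing an empty join.

"Percentage of common genes" between two gene sets is ambiguous about
its denominator; the package uses the Jaccard fraction
`|G_s ∩ G_t| / |G_s ∪ G_t|` because it is symmetric — a requirement for
a covariance matrix — with `min-size` and `geometric-mean` available as
options.  The gene universe is restricted to genes reachable from the
SNP panel, mirroring annotation built from chip markers.  If the
smallest eigenvalue of P falls below 1e-8 the spectrum is floored there
and the matrix rescaled to unit diagonal; the repair is recorded in the
inputs' metadata.  Terms none of whose genes are reachable are dropped
with a note.  Every SNP is either incident on ≥1 term with residual
weight 1 or carries an all-zero row with weight 10; the weight for
unassigned SNPs is a config value defaulting to 10.

The fixed mean u is included in the term model.  One degenerate case is
worth knowing: a term incident on *every* SNP is confounded with u and
its estimate collapses to zero; `include_mean=False` gives the pure
weighted-ridge reduction for such constructions.

## Stage-2 variance components

When not fixed by the user, (σ²p, σ²e*) are estimated by profiling the
restricted likelihood over a grid of ratios σ²e*/σ²p (default
0.1–100), with the common scale solved in closed form at each grid
point.  The covariance `V₀ = Z*PZ*' + ratio·L` is handled through the
Woodbury identity, O(n·T²) per grid point, so chip-scale panels are
cheap.  Constant y* raises: the ratio is then unidentifiable.
Calibration of the Wald test is assessed at fixed variance components
(the test's reference distribution assumes known variances); under a
pure null, REML drives σ²p → 0 and the test becomes arbitrarily
conservative, which is the correct behaviour but uninformative about
the Wald machinery.

## The synthetic-data generator

What it emulates: a discrete-generation pedigree with random matings;
founder genotypes in Hardy–Weinberg proportions at allele frequencies
uniform on [maf_low, maf_high]; Mendelian transmission by unlinked
gene-drop; missing calls at a configurable rate with the −9 sentinel;
non-overlapping gene intervals with exponential lengths; overlapping
gene sets; polygenic values through the pedigree recursion (founder
variance w·σ²a, Mendelian-sampling variance `w·σ²a·(½ − ¼(F_s+F_d))`
with inbreeding from the A matrix, the half-known-parent case using
`¾ − ¼F_known`); DRPs `y = μ + Z1 g + a + e` with `e_i ~ N(0, σ²e/EDC_i)`
and EDC uniform on a configurable interval.  Defaults describe a
low-heritability trait (h² ≈ 0.05 via the deregression algebra above,
EDC 20–100, MAF 0.05–0.5, missing rate 0.002).

What it does not emulate — and hence what passing tests do not show
about real data: linkage disequilibrium and recombination maps (SNPs
are dropped independently, so LD-driven redundancy between markers and
LD-based gene tagging are absent), selection and assortative mating,
the MACE deregression machinery (DRPs are generated directly from the
model), realistic EDC distributions (uniform, not long-tailed), and
X-chromosome hemizygosity (all chromosomes are treated as autosomal
diploid).  Every draw is fixed by the config seed through per-operation
substreams, so any artefact can be regenerated byte-identically; the
complete genotype matrix behind a missing-data panel is recovered by
rerunning with `missing_rate=0`.

## Validation studies (funcblup.studies)

Problem sizes are the package's own choices for desk-scale validation:

* **stage1_null_study** — 600-animal pedigree (200 founders, 2
  generations), 400 phenotyped bulls, 5,000 SNPs, h² = 0.03 (the low end
  of the calving-trait range), EDC ~ U(10, 50), 200 replicate null
  traits sharing one MME factorisation.  Reports mean λ, mean nominal
  type-I rate and the Bonferroni family-wise error.
* **stage1_recovery_study** — 10 seeds of 1,000 bulls × 500 SNPs with 10
  causal SNPs carrying 80% of σ²a at h² = 0.12 (workability-like),
  EDC ~ U(50, 200); reports corr(ĝ, g_true) per seed.
* **stage2_null_study / stage2_power_study** — a realistic Z*/P/L
  structure from the generator's annotation path (1,500 SNPs, 20 terms,
  ~15–70 SNPs per term), y* = |N(0,1)| per SNP, fixed σ²e* = 1 − 2/π
  (the half-normal variance) and ratio σ²e*/σ²p = 5; the power study
  adds a shift of 0.75 half-normal SDs to the SNPs of the median-sized
  term and reports how often that term tops the Wald ranking.

## Numerical choices and degenerate inputs

Cholesky everywhere (coefficient matrices are positive definite by
construction); relative solution residuals are recorded in the solution
metadata and checked ≤ 1e-8 in tests.  A⁻¹ is assembled in sparse
triplet form from Henderson's rules with inbreeding and densified only
at desk scale.  Ties in SNP positions are kept in stable sort order;
QC preserves panel order.  Monomorphic SNPs are removed by the MAF
filter before they can produce zero-information effects; a SNP that
still carries no information makes the BLUP-variance SE non-positive
and raises with the SNP named.  `alpha` may be 1.0 (everything flagged
significant — useful for export pipelines), and Bonferroni p-values are
clipped at 1.

## Known limitations

* Dense factorisation bounds the practical panel size (~10⁴ equations
  on a laptop); the 46k-SNP scale of a real chip needs either more
  memory or an iterative solver, which is out of scope.
* Unlinked simulation means annotation enrichment through LD cannot be
  studied; term signal must be injected directly.
* The strict-null conservatism of stage 1 described above is a property
  of analysing a null trait with production variance components, not a
  tunable defect; users comparing λ against ~1 should remember their
  real traits are not global nulls.
* Genetic groups, genomic (G) and single-step (H) relationship
  matrices, REML for stage 1, and hemizygous X coding are not
  implemented.
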