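# Methods

## Model and assumptions

The engine fits a two-variance-component linear mixed model to a
quantitative trait `y` (n individuals) and a marker panel `Z` stored
marker-by-individual (m × n; `Z_i` denotes the length-n vector of marker
i across individuals):

```
y = Xβ + Σ_i Z_i a_i + Σ_{i<j} W_ij γ_ij + e,    W_ij = Z_i ∗ Z_j
```

with exchangeable random effects `a_i ~ N(0, σ²_a)`,
`γ_ij ~ N(0, σ²_aa)` and residuals `e ~ N(0, σ²I)`.  `X` is an
intercept-only fixed-effect column (rank 1); covariates are out of scope.
Marginalizing the random effects gives
`var(y) = K_a σ²_a + K_aa σ²_aa + I σ²` with

```
K_a  = (1/d_a)  Σ_i Z_i Z_iᵀ,            d_a  = tr(Σ_i Z_i Z_iᵀ)/n
K_aa = (1/d_aa) Σ_{i<j} W_ij W_ijᵀ,      d_aa = tr(Σ_{i<j} W_ij W_ijᵀ)/n
```

The trace normalizers put both kinship diagonals near unity
(`tr(K) = n` exactly).  Assumptions worth keeping in mind: marker effects
share one variance each (no per-marker weights), residuals are
homoscedastic and uncorrelated, and the trait is Gaussian after the
intercept.  Markers are used as coded — no centering or scaling is
applied unless the caller asks for standardization explicitly.

The model applies unchanged to any numeric panel: genotype bins coded
±1, log2 expression, log2 abundance.  For two-state RIL genotypes coded
±1 the pair columns `W_ij` are again ±1 vectors, which is why that coding
is the recommended one.

## Epistatic kinship: closed form

The literal pair sum is O(m²) outer products — ~2.5×10⁸ pairs for a
transcriptome-scale panel — but collapses exactly to

```
[Σ_{i<j} W_ij W_ijᵀ]_kl = (G_kl² − S_kl)/2,
G = ZᵀZ,  S_kl = Σ_i Z_ik² Z_il²
```

an O(m·n²) computation.  The brute-force double loop is retained as a
test oracle; the suite checks the two agree to < 1e−10 on random real
and ±1 panels, which is the module's central correctness property.

## REML

With `C = λ_a K_a + λ_aa K_aa + I`, both β and σ² profile out of the
restricted likelihood:

```
β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y
σ̂² = (y − Xβ̂)ᵀC⁻¹(y − Xβ̂)/(n − 1)
l(λ_a, λ_aa) = −½ln|C| − ½ln|XᵀC⁻¹X| − ((n−1)/2)(ln σ̂² + 1)
```

Each evaluation is one Cholesky factorization (O(n³), n a few hundred).
The two-parameter surface is maximized by Nelder–Mead over
`(ln λ_a, ln λ_aa)` from five fixed starts
{(0.01,0.01), (1,1), (10,0.1), (0.1,10), (5,5)}, λ clipped to
[1e−6, 1e6], tolerance 1e−9 on the log-likelihood.  The surface can be
nearly flat along the σ²_aa/σ² ridge (see *Identifiability* below) and
occasionally multimodal, hence the restarts.  Estimates landing on the
lower box edge are reported as exactly 0 with a boundary flag.  From the
optimum: `σ²_a = λ̂_a σ̂²`, `σ²_aa = λ̂_aa σ̂²`, variance fractions
`ratio_x = σ²_x / (σ²_a + σ²_aa + σ²)`, and
`H = ratio_a + ratio_aa` (broad-sense heritability, scale-invariant).

A sign note: one published form of this profiled likelihood carries the
`((n−r)/2)·ln σ²` term with a positive sign, under which the function is
unbounded above; the implementation uses the standard negative sign,
which is the maximizable form consistent with the unprofiled restricted
likelihood (the suite verifies the profiled value against a direct
evaluation of `−½ln|V| − ½ln|XᵀV⁻¹X| − ½(y−Xβ̂)ᵀV⁻¹(y−Xβ̂)` at
`V = C·σ̂²`).

### Identifiability of σ²_aa

For panels of independent ±1 markers, `K_aa` approaches the identity as
m grows (its off-diagonal entries are O(1/m) relative to the diagonal),
so σ²_aa and σ² become nearly confounded and the interaction fraction is
driven to the boundary.  Linkage disequilibrium rescues identifiability:
with long LD blocks (few effective loci) `K_aa` carries strong structure
and the three components separate cleanly.  This is a property of the
model, not of the optimizer, and it is why the synthetic study
conditions use strongly linked genotype bins (below).

## 1D and 2D scans

After REML the ratios are frozen ("estimate once, test everywhere") and
never re-estimated per marker.  Each scan fit is GLS under
`V = (H_mat + I)σ²`, `H_mat = λ_a K_a + λ_aa K_aa`:

* model I (1D): design `P = [1 | Z_i]`, test `H0: a_i = 0`;
* model II (2D): design `P = [1 | Z_i | Z_j | W_ij]`, test `H0: γ_ij = 0`.

One eigen-decomposition `H_mat = U diag(δ) Uᵀ` rotates every fit into
diagonally weighted least squares with weights `w_k = 1/(δ_k + 1)`,
transformed design `P* = UᵀP` and trait `y* = Uᵀy`:

```
b̂ = (P*ᵀWP*)⁻¹P*ᵀWy*,   σ̂² = (y*−P*b̂)ᵀW(y*−P*b̂)/(n − r(P)),
var(b̂) = (P*ᵀWP*)⁻¹σ̂²
```

The Wald statistic is the squared tested coefficient over its variance,
referred to χ²₁ (1 df — a single coefficient is tested; the design rank
r(P) ∈ {2, 4} enters only the residual degrees of freedom).  Exactly, the
statistic is F(1, n−r(P)) conditional on the design; at the sample sizes
used the χ²₁ reference is indistinguishable in practice (excess type-I
≈ 3.5×10⁻⁴ at n = 800) and the suite's null-calibration test confirms
pooled type-I error inside the 95% binomial interval around 0.05.

Numerical choices:

* p-values are floored at 1e−300 before −log10 so significance scores
  stay finite;
* designs with condition number > 1e12 (constant marker; duplicated
  marker making `W_ij` collinear with the intercept under ±1 coding) get
  `status = "singular"` rows — the scan continues and thresholded
  outputs exclude them;
* pairs run in row-major i<j order in chunks; chunking is a pure
  partition, so any chunk size gives identical output (verified);
* dense all-pairs storage is allowed up to m = 2000; beyond that a
  −log10(p) storage threshold is mandatory (m = 22,584 would mean
  2.5×10⁸ rows);
* negative eigenvalues of `H_mat` above −1e−8·δ_max are clipped to 0;
  anything lower is rejected as a non-PSD kinship.

Conditional 1D slices (all stored pairs involving one marker, in partner
order) and descending-significance thresholded pair lists (ties broken
by pair indices) are derived views of the 2D table.

## Predictability (PRED)

Each omic marker w is treated as an intermediate trait and scored by
leave-one-out R² from the genotype kinships: `PRED = 1 − PRESS/SS`.
Rather than n refits, PRESS uses the hat matrix of the mixed-model
smoother.  With `C = H_mat + I` and `P_x = X(XᵀC⁻¹X)⁻¹XᵀC⁻¹`,
fitted values are `ŵ = S w` with the BLUP-inclusive smoother

```
S = P_x + H_mat C⁻¹ (I − P_x)
```

and the leave-one-out residuals are `r_i = (w_i − ŵ_i)/(1 − S_ii)`,
`PRESS = Σ r_i²`.  For fixed variance ratios this equals n explicit
leave-one-out refits (refit the intercept on n−1 individuals, predict
the held-out one by its conditional mean under the marginal covariance)
to machine precision; the suite asserts agreement to 1e−6 at n = 15.
Variance ratios are re-estimated by REML per marker by default; a fast
mode reuses panel-level ratios.  A fixed-effect-only smoother
(`S = P_x`) is available; the BLUP-inclusive form is the default since
predictability should credit the genetic covariance, not just the mean.
PRED ≤ 1 always; it can be negative (marker predicted worse than its
mean) and is reported unclamped.  The threshold sweep rebuilds the
kinships from markers with PRED ≥ t and re-runs REML on the downstream
trait, tracing H against the threshold; points keeping fewer than two
markers are marked unavailable.

## Integration utilities

* **Bin reduction**: transcripts map many-to-one onto genotype bins; the
  transcript with the highest −log10(p) represents its bin (ties break
  by lowest marker index — an arbitrary but deterministic rule), rows
  ordered by the bin order.  A per-bin max-significance table supports
  positionally aligned Manhattan-style comparisons; taking the maximum
  of −log10(p) and the minimum of p per bin are the same rule.
* **Tissue top-n tables**: markers rank by ascending p (ties by input
  index); each cut records the nth-ranked significance and leaf/seed
  counts.  Counts always sum to n and the implied threshold is
  non-increasing in n.
* **Networks**: thresholded or top-k significant pairs become an
  undirected graph with −log10(p) edge weights, optionally restricted to
  the star of a focal (hub) marker.  Default significance threshold 3.0
  on −log10(p), i.e. p ≤ 0.001.  Export is a plain edge-list TSV.

## Synthetic data: what it emulates, what it does not

`simulate_ril_genotypes` draws each individual's chromosome as a
two-state ±1 Markov chain along marker order with transition probability
`switch_prob`; defaults (12 chromosomes, switch_prob = 0.02, expected
block length 50 bins) emulate a rice-style RIL bin map, where bins sit
between recombination breakpoints and neighbours are strongly
correlated.  `simulate_quantitative_markers` draws standardized Gaussian
rows with optional within-block correlation, emulating log2
expression/abundance panels.  `simulate_trait` assembles the generative
model exactly; by default every marker and every pair carries an effect
(the model's exchangeable reading), and each of the three components is
rescaled so its empirical variance hits the requested target — recovery
tests need controlled truth; an unscaled mode exists.  All generators
are reproducible from (seed, parameters).

Not emulated: allele-frequency spectra and segregation distortion,
missing data, genotyping error, microarray/mass-spec noise models,
population structure beyond the biparental RIL design.  Passing tests
therefore certify the estimator and scan machinery under a correctly
specified model with realistic LD, not robustness to real-data
artifacts.

## Problem sizes used in tests and the acceptance script

The suite's simulation-based checks run at n = 15–800 individuals and
m = 10–300 markers — sizes chosen so the whole suite and the acceptance
script each complete in a few minutes while keeping every check
informative (e.g. n = 800 for the null calibration so the χ²/F gap is
negligible; 20 seeds at n = 300, m = 200 for variance-fraction
recovery; 5 replicate rice-style 210 × 300 datasets in the acceptance
script).  Replicate simulations draw their streams from spawned children
of one root `SeedSequence` — consecutive-integer seeding of parallel
streams measurably correlated "independent" replicates in development
and is avoided throughout.

## Known limitations

* No dominance or additive×dominance components; no covariates beyond
  the intercept; no standard errors or likelihood-ratio tests on the
  variance components.
* The σ²_aa/σ² separation degrades on panels with weak LD (see
  *Identifiability*); boundary estimates are flagged, not hidden.
* Multiple-testing correction is out of scope — thresholds on −log10(p)
  are descriptive, as is conventional for this kind of scan.
* The scans reuse the full polygenic covariance for every fit; the
  tested marker's own contribution is not removed from `H_mat` (proximal
  contamination is a known, accepted approximation of this design).
* Missing values are rejected, never imputed; upstream preprocessing
  (replicate averaging, log transforms) is assumed done.
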