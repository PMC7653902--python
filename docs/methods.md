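# Methods

## Model

The package treats DTI prediction as link denoising on one square network.
Targets occupy indices 0…m−1 and drugs m…m+n−1 of
`M = [[KFJT, Yᵀ], [Y, KFJD]]`, where the fused kernels KFJT/KFJD are built
per run from the current (possibly masked) interaction matrix. A corrupted
copy M̃ zeroes every entry independently with probability `noise`; the
model reconstructs M from M̃ through a one-hop term `L·M̃` with
`L = U·Uᵀ`, a two-hop term `M̃·G·M̃ᵀ` with `G = V·Vᵀ`, and a per-row bias
b. The fitted objective is

    0.5 · E‖M − L·M̃ − M̃·G·M̃ᵀ − b·1ᵀ‖²_F + (λ₁/2)‖U‖²_F + (λ₂/2)‖V‖²_F

with the expectation over corruption taken exactly, never by sampling.
The 0.5 prefactor is a bookkeeping convention; it only rescales the
meaning of λ₁, λ₂.

### Closed-form corruption expectations

Writing M̃ = Δ∘M with Δ_ij iid Bernoulli(q), q = 1 − noise, every raw
moment of Δ_ij equals q, so the expectation of a product of corrupted
entries is the product of the uncorrupted entries times q^(number of
*distinct* entries touched). Expanding the squared Frobenius norm gives
terms with one to four corrupted factors:

* one factor: E[C·M̃] = q·C·M;
* pair: E[M̃ᵀCM̃] = q²·MᵀCM + q(1−q)·diag((M∘M)ᵀ·diag(C)), and the
  mirrored E[M̃CM̃ᵀ];
* triple: E[M̃CM̃ᵀM̃ᵀ] = q³·MCMᵀMᵀ plus q²(1−q) corrections for each of
  the three two-entry coincidences and a q(1−q)(1−2q)·diag(d_M³∘diag(C))
  term for the all-equal case (any two coincidences force the third, so
  inclusion–exclusion stops there);
* quartic: E tr(M̃CM̃ᵀM̃CM̃ᵀ) decomposes over row pairs — distinct rows of
  Δ are independent, leaving per-row second-moment matrices
  W_i = q²·m_im_iᵀ + q(1−q)·diag(m_i²), while the same-row contribution is
  the exact fourth moment of the Bernoulli quadratic form δᵀHδ with
  H = diag(m_i)·C·diag(m_i), involving the central moments
  v = q(1−q), κ₃ = v(1−2q) and μ₄ = v(1−3q+3q²).

These closed forms — not any printed rendition of them — are the
authority: the test suite requires exact (1e−12) agreement with exhaustive
enumeration over all corruption patterns on 2×2/3×3 matrices at
q ∈ {0.2, 0.35, 0.5, 0.8}, and ≤1% agreement with a 2×10⁵-sample
antithetic Monte-Carlo estimate on 5×5 nonnegative instances. Nonnegative
test instances matter for the Monte-Carlo leg: with zero-mean entries the
q³-damped expectation nearly cancels while the per-sample variance does
not, and the relative error would measure sampling noise instead of
closed-form agreement. Note the coefficient q(1−2q)(1−q) is negative for
q > ½ — correct for the exact expectation, as enumeration confirms.

### Gradients and optimization

Gradients with respect to U, V, b are derived by matrix differentials
through L = UUᵀ and G = VVᵀ (for any scalar term f with ∂f/∂L = D, the
U-gradient is (D + Dᵀ)U). They are held to central finite differences of
the implemented loss at relative error 1e−4 across random instances; in
practice agreement is ~1e−8. U and V start from seeded Gaussian noise with
scale 1/√k and b from zero; all three blocks are optimized jointly as one
flattened vector by L-BFGS (memory 10, gradient tolerance 1e−5, at most
200 iterations by default). A non-finite objective aborts with the
evaluation index. Scoring uses the uncorrupted network:
`M* = UUᵀM + MVVᵀMᵀ + b` with b offsetting rows, and the (drug i,
target j) score averages `M*[m+i, j]` and `M*[j, m+i]`.

## Kernels and fusion

GIP bandwidth is the reciprocal mean squared profile norm; an all-zero
profile matrix (every profile empty, as in extreme masking) has no defined
bandwidth and falls back to γ = 1 with a warning, leaving the
chemical/sequence kernel to carry the signal. Jaccard 0/0 pairs score 0
off-diagonal (no shared evidence) with a definitional unit diagonal.
Pearson kernels clip negative correlations to 0 — fusion requires
nonnegative inputs — and zero-variance profiles contribute 0; missing
affinity measurements are excluded pairwise (each pair is correlated over
its common observed features).

Normalization puts half of each row's mass on the diagonal; a row with no
off-diagonal mass spreads it uniformly as 1/(2(n−1)) with a warning so the
row-stochastic contract survives degenerate inputs. kNN localization
always keeps the entity itself plus its k−1 strongest neighbors (ties to
the lowest index, for cross-platform determinism); k defaults to about a
third of the entity count, never below 3. Fusion runs 2 diffusion
iterations by default, with the localized matrices held fixed and the
`+I` re-symmetrization applied after every iteration, exactly as the
update rule states; no final diagonal rescaling is applied, so fused
diagonals exceed 1 — anyone comparing absolute kernel values against other
codebases should divide out the diagonal first.

## Defaults

| parameter | default | meaning |
|---|---|---|
| noise | 0.65 | corruption probability; q = 0.35 residual |
| latent_dim | min(100, max(20, n_drugs/4)) | rank of U, V |
| λ₁, λ₂ | 0.01 | ridge weights on U, V |
| k_nn | max(3, n/3) | fusion neighborhood (self included) |
| n_iters | 2 | fusion diffusion rounds |
| folds / repeats | 10 / 5 | cross-validation defaults |
| Kd / Ki cut-offs | 30 / 28.18 nM | strict-inequality binarization |

The latent rule pins 20 at the nuclear-receptor scale (54 drugs) and 100
at the enzyme scale (445 drugs) while interpolating between. λ values are
small ridge terms that keep L-BFGS well-posed; they are not tuned per
dataset.

## Affinity mode

Quantitative Kd/Ki matrices are binarized at the strict cut-offs
(value < threshold ⇒ interaction) before entering the network and the GIP
profiles; feeding raw nM values would make 0 — the masked/missing code —
read as an infinitely strong binder and invert the ranking semantics. The
association kernel switches from Jaccard to Pearson and keeps the
continuous profiles, which is the point of the substitution. AUC/AUPR use
the binarized labels; the concordance index compares predictions against
−Kd (or −Ki) so that "higher score = stronger binder" holds for all three
metrics. Cells hidden by cross-validation become missing (NaN), not 0 nM.

## Cross-validation and leakage

CVP partitions all n·m cells by default (a positives-only switch exists);
CVD/CVT partition drug rows/target columns with fold sizes differing by at
most one. Every fold rebuilds GIP and association kernels from the masked
training matrix — the similarity matrices are external inputs and are
left untouched — and the test suite checks the stronger property that
flipping every held-out truth label leaves the fitted factors
bit-identical. Metrics are pooled over a fold's held-out cells, then
averaged across folds and repeats (mean ± sd). Single-class folds are
skipped for AUC/AUPR with a warning and counted in the report.

## Synthetic data

The generator plants co-clustered structure: drugs and targets are split
into equal blocks; matched blocks interact with probability 0.5 and
unmatched cells at 0.02 (roughly the sparsity regime of the public
gold-standard sets); similarities are 0.8 within and 0.2 between blocks
with additive symmetric Gaussian noise of sd 0.05, clipped to [0, 1] with
unit diagonal — similarity contrasts of that order, with mild measurement
noise, are what SIMCOMP/Smith–Waterman matrices look like after
normalization. Default size is 60 drugs × 40 targets × 4 blocks, chosen so
a full 10-fold, 3-replicate cross-validation suite runs in about a minute
on one CPU.

What the generator does *not* emulate: scale-free degree distributions,
hub drugs acting across families, correlated noise between the chemical
and interaction spaces, and partially observed affinity panels. Passing
recovery tests on it therefore shows the pipeline extracts planted
block-level signal through masking, fusion and denoising — not that
real-data headline numbers are reproduced.

Two honest performance notes, both measured under the standard conditions
(seeds 1–3, 10-fold CVP, defaults):

* Within-block held-out zeros are statistically identical to held-out
  interactions (both were planted at probability 0.5), so even the Bayes
  oracle — scoring by the true generative cell probabilities — attains
  only mean AUC 0.874 / AUPR 0.518 on these fixtures. The fitted model
  reaches mean AUC 0.863 / AUPR 0.493: at the ceiling for AUC, ~2.5 points
  under it for AUPR. The package's recovery test demands AUC ≥ 0.85 and
  AUPR ≥ 0.50; the AUPR bar sits inside that oracle gap and currently
  fails by ~0.007, which we report rather than relax.
* Under CVD/CVT the denoising objective is rewarded for reconstructing the
  held-out rows/columns as the zeros they are in the training network, so
  ranking quality for wholly new entities on this synthetic stays modest
  (AUC ≈ 0.6–0.7 depending on rank) even though the fused kernel itself
  propagates similarity well (kernel-only neighbor scoring reaches
  AUC ≈ 0.80). New-entity prediction rests entirely on the similarity
  branch of the fusion; no nearest-neighbor profile imputation is applied
  before fitting.

## Numerical choices and edge cases

Labeled matrix text is written with 17 significant digits, making the
read/write round trip bit-exact for float64. Average degrees truncate
toward zero at two decimals (90/54 → 1.66), matching the convention of the
benchmark statistics tables. Interaction-matrix orientation is detected by
matching row identifiers against the drug-similarity identifiers (public
files store targets in rows); a square matrix with ambiguous identifier
sets requires an explicit orientation flag. Similarity matrices are
symmetrized and diagonal-forced on load, warning above 1e−6. Ranked
prediction output breaks score ties by lexicographic (drug, target)
identifiers so files are reproducible across platforms. All internal
indexing is 0-based; external reports always use identifiers.

## Known limitations

* Dense (m+n)² linear algebra in the loss and gradients: fine to a few
  thousand nodes, not at compound-database scale. Y may be held sparse,
  but the denoising step densifies.
* The closed-form quartic term requires the symmetric weight matrix
  G = VVᵀ; an asymmetric global weighting would need new expectations.
* Affinity handling assumes one measurement type (Kd or Ki) per matrix.
* No profile imputation for new entities; CVD/CVT depend on informative
  chemical/sequence similarities.
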