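# Methods

## Model

A drying slice observed from above loses projected area as it loses
water. We model the dimensionless moisture ratio `MR(t) = MC(t)/MC(0)`
(dry-basis moisture content `MC = (m - m_d)/m_d`) as a polynomial in the
area shrinkage `S(t) = A(t)/A(0)`:

    MR(t) = phi(t)^T alpha + v(t),   phi = [1, S, S^2, ..., S^n]^T

with `alpha = [a0 .. an]` (Q = n + 1 parameters) and `v` independent
zero-mean Gaussian observation noise of variance `sigma^2`. The
polynomial form is justified by uniform approximation of any continuous
MR–S relationship; in practice low orders (n ≤ 3) suffice and are the
default candidate set. Both MR and S equal 1 at the start of drying by
construction.

Assumptions worth stating: noise enters the *moisture* observations, not
the shrinkage (S is treated as an exact regressor); samples are
uniformly spaced (default period 0.5 min); the slices shrink without
fragmenting, so a fixed particle count is meaningful.

## Imaging pipeline

Each frame passes through six steps: (1) read RGB; (2) grayscale by the
exact mean of the three channels, rounded half-to-even; (3) global
threshold by two-cluster iterative intermeans on the 256-bin histogram —
the Ridler–Calvard fixed point `T = floor((mean_below + mean_above)/2)`,
iterated from the global mean — with Otsu as a selectable alternative;
(4) binarise, keeping pixels strictly above the threshold (slices are
lit, the cavity floor dark; an invert flag covers the opposite
polarity); (5) fill holes (background not 4-connected to the border) and
keep the six largest 8-connected particles, discarding small bright
debris; (6) sum the retained pixel counts. Dividing by the first frame's
sum gives S(t); any camera scale cancels in the ratio.

Choices the pipeline's description leaves open were fixed as follows:
intermeans rather than Otsu as default (the two differ by at most a few
grey levels on bimodal frames; both are exposed); strict inequality at
the threshold, which matters because intermeans thresholds are integers;
8-connectivity for particles with 4-connectivity for hole filling (the
standard complementary pair, avoiding paradoxes at diagonal contacts);
ties for the k-th largest particle keep the earlier raster-scan label
and emit a warning.

## Estimator

The fitness of a candidate coefficient vector is the mean squared
residual

    J(alpha) = (1/D) sum_k [MR(k) - phi(k)^T alpha]^2.

Profiling the Gaussian likelihood over `sigma^2` gives the maximiser
`sigma^2 = J(alpha)` and the profile log-likelihood
`const - (D/2) ln J(alpha)`, so minimising J *is* maximum likelihood —
and, the model being linear in its parameters, also ordinary least
squares. The evolutionary search is therefore not needed for this
particular model class to be fittable; it is the estimator of record
here, and the closed-form normal-equations solution serves as an
independent oracle in the tests (the two routes are never collapsed).

The population of P candidate vectors evolves by, per generation and
target index p: rand/1 mutation `beta = alpha_r1 + F (alpha_r2 -
alpha_r3)` with r1, r2, r3 rejection-sampled distinct and distinct from
p; binomial crossover that takes each mutant coordinate with probability
CR and always takes coordinate `q_rand` (drawn fresh per individual from
{1..Q}); greedy selection, the trial replacing the target only on a
strict fitness improvement (ties keep the incumbent). The reported
estimate is the argmin-J member of the final population, not an elitist
archive — equivalent in effect, since greedy selection never lets the
population's best worsen, which also makes the best-J trace monotone.
A single seeded PCG64 generator drives initialisation, index draws and
crossover uniforms in a documented order (indices, then q_rand, then Q
uniforms), so runs are bit-reproducible.

### Parameters

| parameter | default | why |
| --- | --- | --- |
| population size P | 30 | drying-study setting; ample for Q ≤ 6 |
| generations | 500 | settles onto the least-squares optimum for D ~ 83, n ≤ 3 |
| scale factor F | 0.5 | standard differential-evolution practice |
| crossover rate CR | 0.9 | standard practice for correlated parameters |
| init range | [-20, 20) | covers drying-fit coefficient magnitudes (order 1–15) |
| sampling period | 0.5 min | one frame and mass reading every 30 s |

The init range deserves its justification: a narrow initial hypercube
such as [0, 1) is tempting but unsafe. With rand/1 mutation the
population's spread contracts multiplicatively, and when the optimum
lies several units outside the initial box — as polynomial drying-curve
coefficients routinely do (magnitudes up to ~12 with alternating signs)
— the population collapses before reaching it and the fit stalls at
1.3–3× the attainable residual. We confirmed the same stall with an
independent differential-evolution implementation under identical
settings. Wide initialisation removes the failure mode at no cost;
`init_low`/`init_high` stay configurable for narrower priors.

## Metrics and order selection

R² is `1 - SSE/SST` about the observed mean; adjusted R² is
`1 - (1 - R²)(D - 1)/(D - (n + 1))`, strictly decreasing in n at fixed
R², so it can arbitrate between orders; RMSE is `sqrt(J)` at the fitted
coefficients — an identity the tests assert to 1e-12. The selected order
maximises adjusted R², ties going to the smaller order and then the
smaller RMSE. Reports round to 4 decimal places.

## Synthetic generator

The generator emulates the bench conditions the method targets: ~41 min
of drying sampled every 30 s (D = 83), six 25 mm slices viewed from
above (rendered at 40 px initial radius on a 360×260 canvas — the pixel
scale is arbitrary since S is a ratio), moisture ratio decaying
exponentially `MR = exp(-k t)` with k anchored so a slice dries from
9.87 to 0.176 g/g over the run (final MR ≈ 0.018), and observation
noise sigma = 0.02 on MR.

Shrinkage is obtained by inverting a known monotone cubic `MR = p(S)`
on [0.35, 1] by bisection (tolerance 1e-10). The default link
interpolates (0.35, 0.012), (0.60, 0.20), (0.80, 0.45), (1.0, 1.0) — a
convex increasing curve of the shape slice-drying studies report.
Published fitted cubics themselves are a poor choice of generating link:
a representative one is strictly increasing yet *negative* below
S ≈ 0.52, so it cannot generate the near-dry tail of a full run. The
generator validates strict monotonicity of any user-supplied link on the
configured S range and rejects the run otherwise.

Frames are rasterised without anti-aliasing (a pixel is foreground iff
its centre lies inside a disk), so a noiseless frame binarises back to
exactly the rendered pixel count — the basis of the exact round-trip
test. Disk radii scale with sqrt(S), uniformly across disks unless
per-disk scale factors are given; layouts where disks would touch or
leave the canvas are rejected. Optional Gaussian pixel noise is applied
to the grayscale plane before quantisation.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: uneven illumination and vignetting, specular
highlights, browning and other colour drift, slice fragmentation or
curling (which breaks the fixed top-6 particle count), off-axis camera
distortion, and mass-reading artefacts. On real frames the intermeans
and Otsu thresholds may differ by a few levels; on the synthetic
two-level histograms they agree.

## Numerical choices and degenerate inputs

Horner evaluation for polynomial prediction (matches naive power sums to
1e-12 relative for |S| ≤ 2, |a| ≤ 100); rejection sampling for the
mutation indices; a constant image thresholds to its own intensity with
a warning; an empty mask yields an empty particle set (area 0) with a
warning; J = 0 makes the profile log-likelihood +infinity, reported with
a perfect-fit warning; fits with D < Q proceed with an
under-determination warning; adjusted R² requires D > n + 1 and errors
otherwise.

## Problem sizes

The validation studies use 20 seeded runs at the full study size
(D = 83, P = 30, 500 generations) for estimator–oracle comparison,
coefficient recovery and order selection, plus one 83-frame image
round trip per noise setting; together they complete in about a minute
on one core.

## Known limitations

The estimator is quadratic-bowl optimisation done stochastically: for
this linear-in-parameters model it can only approach, never beat, the
closed-form least-squares solution. Shrinkage enters as an error-free
regressor; pixel-level extraction error (~1% here) biases coefficients
slightly and is not propagated. Order selection by adjusted R² is
greedy and can prefer an overfit order when noise is far larger than
the defaults. The imaging pipeline assumes exactly six well-separated
slices; fragmentation changes what "top 6" means mid-run.
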