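# Methods

## The descriptor

The package projects each RGB channel of a square N×N carrier onto the
tensor-product basis FH_p(x)·FH_q(y), where

FH_p(t) = sqrt(2 α t^(α−1)) · ψ_p((2 t^α − 1)/σ)

and ψ_p is the orthonormal Hermite function of degree p (physicists'
Hermite polynomial H_p with Gaussian envelope, normalized so that
∫ψ_pψ_q = δ_pq on the real line). The power map x = 2t^α − 1 carries the
Hermite family from the line to the unit interval; the square-root Jacobian
factor is folded into FH_p so that orthonormality is preserved under the
substitution: ∫₀¹ FH_p FH_q dt = ∫₋₁¹ ψ_p(x/σ)ψ_q(x/σ)/σ dx ≈ δ_pq, exact
up to the Gaussian tail mass outside [−1, 1]. The fractional exponent α
warps spatial emphasis: α = 1 recovers the classical Gaussian–Hermite family
on a symmetric interval, larger α concentrates resolution toward t = 1. The
envelope of the pulled-back basis is centered at t* = 2^(−1/α) (≈ 0.694 at
the default α = 1.9); this asymmetry matters for the robustness discussion
below.

All evaluation uses the orthonormal three-term recurrence
ψ_{p+1}(u) = u·sqrt(2/(p+1))·ψ_p(u) − sqrt(p/(p+1))·ψ_{p−1}(u), which keeps
every intermediate bounded; the factorial explicit form is implemented only
inside the test suite, in exact arithmetic, as a cross-check oracle.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α | 1.9 | fractional exponent of the power map; the operating point used throughout the experiments |
| nmax | 37 | maximum degree per axis; with the q ≠ 4m eligibility rule this yields 38·28 = 1064 index pairs per channel, enough for a 32×32 payload even from a single channel |
| σ | 0.105 | Gaussian envelope scale. Never fixed by theory alone: it must be small enough that ψ_nmax's support (turning points at ±σ·sqrt(2·nmax+1)) fits inside [−1, 1]. Chosen by a one-time grid search (step 0.005) as the largest σ whose orthonormality defect at nmax = 37 stays below 1e−4; the defect at the default is 9.3e−5, and σ = 0.12 already fails at 1.5e−1 |
| quad order c | 8 | Gauss–Legendre nodes per pixel subinterval; doubling to 16 changes the kernels by < 1e−10, so 8 is converged at double precision |
| P×Q | 32×32 | watermark payload size |
| Chebyshev (r, x0, burn-in) | (4.0, 0.631, 100) example keys | r ≥ 2 is required for the chaotic regime; burn-in discards transient iterates and is part of the key material |
| binarization threshold T | mean of the selected amplitudes | per the construction; ties (A_i = T) map to bit 1 |
| chaotic bit threshold | 0 | midpoint of the map's range [−1, 1], giving near-balanced keystream bits |

`validate_basis` recomputes the (nmax+1)² Gram matrix with dense composite
Gauss–Legendre quadrature (512 panels × 16 nodes) and rejects any basis
whose defect exceeds 1e−4, guarding user overrides of σ or nmax.

## Moment computation

Pixel i covers [(i−1)/N, i/N] with center (i−1/2)/N; rows index y, columns
x, origin top-left. The kernel route integrates each basis function exactly
over each pixel (c-point Gauss–Legendre per subinterval) and contracts
IXᵀ·G·IY per channel — two matrix products, never a quadruple loop. The
classical midpoint ("zeroth-order") route is retained solely as an accuracy
baseline; on reference problems its error is two or more orders of
magnitude above the kernel route's and grows faster with degree.

Gauss–Legendre nodes are strictly interior to each subinterval, so the
t = 0 singularity of the Jacobian for α < 1 is never touched during moment
computation; direct basis evaluation at t = 0 with α < 1 raises instead of
returning an infinity.

## Keys and determinism

Two independent secrets exist: the *selection key* (an integer seeding
numpy's PCG64 generator; features are drawn without replacement from the
channel-pooled eligible index set, enumerated channel-major, then p, then q)
and the *scramble key* (the Chebyshev parameters). The sampling procedure
is identified by a version string stored in the zero-watermark sidecar, so
registered watermarks remain verifiable across releases. Chaotic iteration
is pinned to IEEE doubles; keystreams are reproducible within one
implementation but not portable across differing math libraries —
acceptable because generation and verification run in the same code.

Verification resamples a presented image back to N×N (bilinear) whenever
its frame disagrees with the basis grid; attacks in the bundled simulator
already preserve frame size (rotation crops to the original frame and
zero-fills corners; scaling attacks resize away and back).

## The synthetic test bed

Real MRI carriers cannot be redistributed, so all tests and examples run on
seeded phantoms: a dark background, a centered bright elliptical skull
annulus, interior elliptical structures of varying intensity and
orientation, mild Gaussian texture noise (sd 0.02 in unit intensities), and
a warm pseudo-color mapping exercising the full 8-bit range. Phantoms
reproduce the gross geometry and dynamic range of brain slices but not
their fine anatomical texture; real MR images carry substantially more
high-frequency energy, which *raises* the moment-amplitude threshold T and
therefore tends to make the binarized features more stable than the
phantom results suggest. Passing tests demonstrate the algebraic and
numerical correctness of the pipeline and attack-relative robustness
ordering on phantom-like content; they do not certify clinical-image BER
levels.

## Robustness: what holds and what does not

The exact round trip (BER 0, NC 1 on the unattacked carrier) is structural:
XOR involution plus deterministic features. Wrong keys degrade extraction
to coin-flip BER (~0.5). Under signal-processing attacks that approximately
preserve low-order image content — JPEG recompression, light salt-and-pepper
noise, 3×3 median/Gaussian/average filtering, mild rescaling, corner
cropping — the mean BER over phantoms stays at or below ~0.02.

Three attacks measurably exceed that level on phantoms: Gaussian noise of
variance 0.005 (~0.03), 5° rotation (~0.065), and horizontal flip (~0.09).
This is a property of the feature definition, not of the implementation:
amplitudes of *Cartesian* moments are not rotation or reflection
invariants, and the fractional map makes it worse — the basis envelope is
centered at t* ≈ 0.694 while rotation pivots about the image center 0.5,
and a flip (t → 1 − t) is not a symmetry of the basis for α ≠ 1 (at α = 1
it is, up to sign, which is why integer-order Gaussian–Hermite amplitudes
are flip-stable). The q ≠ 4m eligibility rule originates in radial-moment
families whose amplitudes *are* rotation invariant; it does not confer
invariance on a Cartesian family. Diagnostics in the development notes show
the rotation/flip bit errors spread across all moment orders and driven by
amplitude jitter of order 10% of the binarization threshold, insensitive to
the choice of nmax between 21 and 37.

## Problem sizes

The shipped tests and the acceptance script run generation/verification at
the full operating point (N = 256, nmax = 37, 32×32 payload; ~30 ms per
verify), robustness sweeps over 10 phantoms × 8 attacks, brute-force moment
oracles on 8×8–16×16 images at nmax ≤ 6, and reconstruction convergence at
nmax up to 30 — the whole suite completes in well under a minute.

## Known limitations

- Rotation/flip robustness is bounded by the non-invariance discussed above;
  methods needing strong geometric invariance should use radial moment
  families or register the image before verification.
- NC is asymmetric by definition (denominator over the reference watermark
  only) and is reported exactly in that form; an all-zero reference is
  rejected.
- Kernel matrices are recomputed per call (cheap at N = 256); no sidecar
  caching is implemented.
- Quaternion moment algebra, polar/radial families, and FFT-accelerated
  moment computation are out of scope.
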