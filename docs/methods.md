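# Methods

## Model

A traced neuronal process is modeled as a regular curve c: [0, L] → ℝ³,
|ċ| > 0, known only through samples (tᵢ, c(tᵢ)).  Traces are taken at
face value as piecewise-linear curves parameterized by cumulative chord
length, so |ċ| = 1 segment-wise.  A coordinate transformation
φ: ℝ³ → ℝ³ is assumed to be an orientation-preserving C¹ (for the
first-order machinery, C²) diffeomorphism; for gridded displacement
fields φ(x) = x + u(x) the sufficient condition sup|Du| < 1 is used as
the operational surrogate and checked by sampling.

Mapping of order k acts on the k-jet of the curve at each sample:
position through φ, first derivative through the Jacobian Dφ, second
derivative through Dφ plus the correction D²φ[x₁, x₁].  Timestamps are
unchanged, so the mapped curve keeps the *original* arc-length
parameters; it is generally not unit-speed, which is intentional — the
action must commute with composing φ with the curve.  Reconstruction
uses a spline of order 2k+1 over those parameters: piecewise-linear
(k = 0) or piecewise cubic Hermite (k = 1), each segment constrained by
the two mapped endpoint positions, the mapped right derivative at its
left knot and the mapped left derivative at its right knot.  Position is
continuous across knots; derivatives need not be, mirroring the
one-sided-derivative structure of a polyline.  One-sided derivatives of
a polyline are chord slopes, which are the *exact* one-sided derivatives
of the piecewise-linear interpolant — this is why first-order mapping of
a polyline converges at O(δ⁴) to the mapped polyline rather than being
limited by derivative-estimation error.

Second-order jets are supported in the action (with closed-form or
finite-difference Hessians) but are only accepted from analytic curve
specifications; they are never estimated from polylines, whose second
derivatives do not exist at knots.

## Error bounds

Three bounds on max_t |f(t) − g(t)|, f = φ∘c, are implemented:

1. **C¹ bound** (any piecewise-C¹ arc-length curve): per segment,
   `C · δᵢ · max_seg |Dφ∘c|` with spectral norms, C = √3 by default
   (exposed as a parameter; validity holds for any C ≥ ½ since both f
   and the first-order spline g are Lipschitz with constant
   max|Dφ∘c| on the segment).  Does not vanish for φ = identity.
2. **Piecewise-linear bound**: per segment
   `½ max_seg |Dφ∘c − I| · δᵢ + |εᵢ − εᵢ₋₁|`, εᵢ = c(tᵢ) − φ(c(tᵢ)).
   Vanishes as φ → identity.  Continuum maxima are estimated by dense
   sampling along each segment at steps ≤ min(0.5 µm, segment/50).
3. **Comparable smooth bounds** (C⁴ data): with h = δ/2 and M_k the
   coordinate-wise maxima of |∂ₜ⁽ᵏ⁾ f|, the first-order (cubic Hermite)
   bound is (√3/4!)·M₄·h⁴ — the classical per-coordinate Hermite
   remainder M₄δ⁴/384 combined across three coordinates — and the
   zeroth-order bound adds (√3/2)(M₃h³ + M₂h²), with M₃, M₂ evaluated at
   the knots.  The prefactors are exposed as parameters; the ordering
   (first ≤ zeroth) is structural.  M_k are estimated by second-order
   central difference stencils on a 201-point uniform grid — exact for
   cubic data, so the quartic term genuinely vanishes there; the grid
   step balances truncation against the 1/h⁴ roundoff amplification of
   the fourth difference.  Estimated maxima can only under-resolve the
   continuum maximum by O(h²); the √3 prefactor slack dominates this in
   all tested regimes.

Applying bound 2 to a single straight segment of length L gives
`a·L + b` with a = ½·sup|Dφ − I| and b = 2·sup|x − φ(x)| over a domain
grid (the intercept uses the triangle inequality for |εᵢ − εᵢ₋₁|).  Its
inversion L*(e) = ⌊(e − b)/a⌋ is the maximal straight-branch sampling
period for error budget e; with a = 0.011, b = 0.022 this yields
L*(1 µm) = 88 µm.

**Evaluation protocol.** Ground truth is the mapped dense polyline:
resample each segment at ≤ 2 µm, map every point.  Mapped splines are
sampled on the same parameter grid.  Headline comparisons use discrete
Fréchet distance (dynamic program over the coupling lattice; an upper
bound of continuous Fréchet distance); bound-validity checks use the max
deviation at shared parameters, which is the quantity the bounds govern
and itself upper-bounds Fréchet distance.

## Tree decomposition

Neuron trees are split into non-branching branches by recursively
removing the root-to-leaf path of maximal arc length.  Ties break toward
the smallest leaf id (determinism).  Each remaining subtree keeps its
attachment node as the first knot of its branch, so junction knots are
duplicated and every branch is a standalone curve; branch segments
partition the edge set and branch count equals leaf count.  Branches are
mapped independently; at junctions only positional agreement is
guaranteed, since each branch carries its own one-sided derivatives.
Consecutive duplicate knots (common in real SWC files) are dropped with
a warning to restore regularity.  Downsampling by period p keeps both
end knots plus interior knots at indices ≡ 0 (mod p), then reparameterizes.

## Displacement fields

u is stored on a regular grid (origin, spacing, values) and trilinearly
interpolated, so the Jacobian is the exact in-cell gradient of the
interpolant; points on a cell face take the gradient of the cell with
larger indices (clamped at the top boundary).  In-cell Hessians carry
only mixed partials (trilinear forms are linear per axis).  Out-of-domain
points raise an error unless zero-displacement padding is requested.
Compositions (e.g. affine ∘ field) use chain-rule Jacobians and Hessians;
a `nonlinear_only` flag selects the field component alone, matching the
protocol of applying only the nonlinear registration component to
neurons.  Finite-difference fallbacks (central, step
max(10⁻³ µm, 10⁻⁶·|x|)) serve transforms without closed-form
derivatives.  `log det Dφ` and the Jacobian spectral norm (whose log is
the finite-time Lyapunov exponent), |Dφ − I|, |u| and the displacement
of a tangent vector (default (1,1,1)ᵀ) are reported per grid node.

## Synthetic study conditions

The generator emulates the regime of whole-brain tracing plus
registration, *not* imaging noise or tracing errors:

- **Curves**: straight / helix / sinusoid / random Fourier families with
  closed-form derivatives; Fourier coefficients decay as 1/m² so curves
  are C^∞ with bounded derivatives; regularity (min|ċ| > 0.05) is
  verified by sampling and violating specs are rejected.  Knots are
  placed by numeric arc-length inversion.
- **Fields**: sums of Gaussian bumps a·d·exp(−r²/2σ²), whose gradient
  bound a/(σ√e) is closed-form; specs are rejected unless bounds sum
  below 1, so every generated field is a diffeomorphism by construction
  (and re-verified by sampled validation in tests).  Defaults mirror the
  registration regime: 100-µm grid spacing, displacements of tens of
  microns, σ ≈ 150–300 µm.
- **Registration-regime cases** (the downsampling experiment): 3-mm
  random Fourier branches with 15-µm knots; four bumps of amplitude
  40 µm, σ = 300 µm, centered near the branch (a registration deforms
  where the neuron is); the smooth field is then sampled onto a 100-µm
  grid, as registration pipelines ship it.  Because bump placement is
  anchored to the curve, passing results say nothing about deformations
  far from the trace (where all methods are trivially exact).

With these conditions the two orders tie at native sampling (median
|Fréchet difference| ≈ 0.04–0.07 µm) and first order wins after
downsampling each branch 100× (median difference ≈ 4 µm over 50 seeds)
— the qualitative crossover the method predicts.  "Near zero" is
operationalized as median |difference| below one fifth of the
downsampled median.

## Numerical choices and limitations

- Dense-reference and spline sampling default to 2-µm steps; knot
  parameters are always retained.
- Convergence-order checks use max deviation at shared parameters with
  0.25-µm sampling over knot periods 40→5 µm; slopes are least-squares
  fits in log–log.
- The Fréchet dynamic program is O(nm) time and memory; numba
  accelerates it when present, with a pure-NumPy fallback.
- Problem sizes in the test-suite experiments (200 randomized bound
  cases, 50 downsampling seeds, 100 composition pairs) were chosen to
  make medians and worst cases stable at interactive runtimes.
- Radius and SWC type codes are carried through I/O unchanged but play
  no geometric role; frustum/cylinder geometry is out of scope, as are
  computing registrations (no LDDMM optimization), transform inversion,
  and jets of order ≥ 3.
- Real tracings are not piecewise linear; treating them as such defines
  the ground truth here, as it does in the evaluation protocol this
  package implements.
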