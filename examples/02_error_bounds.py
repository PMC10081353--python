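"""Zeroth-order mapping error bounds, including the a*L + b corollary.

Computes the two computable bounds on zeroth order mapping error for a
branch under a deformation field, then fits the affine-in-length bound
a*L + b over the field's domain: a is half the largest Jacobian deviation
from identity, b twice the largest displacement.  Inverting it gives the
largest knot spacing for a straight branch that keeps mapping error below
a tolerance — with the constants a = 0.011, b = 0.022 this reproduces the
88-micron spacing at 1 micron of error.
"""

import numpy as np

from jetmap import (
    AffineLengthBound,
    affine_bound_in_length,
    arc_length_parameterize,
    bound_c1,
    bound_piecewise_linear,
    max_deviation,
    random_bump_transform,
)

rng = np.random.default_rng(1)
phi = random_bump_transform(rng, n_bumps=3, amplitude=20.0, sigma=100.0,
                            box=200.0)
branch = arc_length_parameterize(
    np.linspace([-150, 0, 0], [150, 0, 0], 11))

observed = max_deviation(branch, phi, order=0)
print(f"observed zeroth-order error: {observed:.4f} um")
print(f"C1 bound:                    {bound_c1(branch, phi).overall:.4f} um")
print(f"piecewise-linear bound:      {bound_piecewise_linear(branch, phi).overall:.4f} um")

ab = affine_bound_in_length(phi, lower=(-200,) * 3, upper=(200,) * 3)
print(f"fitted bound: {ab.slope:.4f} * L + {ab.intercept:.4f}")

published = AffineLengthBound(slope=0.011, intercept=0.022)
print(f"with a=0.011, b=0.022: bound(10 um) = {published.bound(10):.3f} um, "
      f"bound(1 mm) = {published.bound(1000):.3f} um, "
      f"max spacing for 1 um error = {published.max_length(1.0):.0f} um")
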