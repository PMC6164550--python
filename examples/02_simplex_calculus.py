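"""Simplex-valued calculus on a quadratic gradient curve: derivative,
rate of change, integral mean, and the zero-dissimilarity condition.

A quadratic curve in ilr coordinates, M(z) = γ0 ⊕ (z⊙γ1) ⊕ (z²⊙γ2),
describes how an expected community composition moves along a gradient.
Its simplex derivative D⊕M(z) = γ1 ⊕ (2z⊙γ2) is itself a composition, and
the Aitchison norm of the derivative is a scalar rate of change that is
zero exactly when the community is not changing.
"""

import numpy as np

from gradcoda import PolySimplexCurve, build_ilr_basis
from gradcoda.curves import (
    collinearity_check,
    curve_derivative,
    curve_eval,
    curve_mean,
    derivative_norm,
    expected_dissimilarity,
    rate_minimiser,
)

basis = build_ilr_basis(3, labels=("algae", "sponge", "bare"))
beta = np.array([[0.2, -0.1], [1.0, 0.4], [-0.3, 0.5]])  # β0, β1, β2
curve = PolySimplexCurve(beta, basis)

for z in (-1.0, 0.0, 1.0):
    comp = curve_eval(curve, z)
    rate = derivative_norm(curve, z)
    print(f"z={z:+.1f}: composition {np.round(comp.parts, 3)}  rate {rate:.3f}")

zstar = rate_minimiser(curve)
print(f"rate of change is minimised at z* = {zstar:.4f}")
print("derivative there:", np.round(curve_derivative(curve, zstar).parts, 4))

mean = curve_mean(curve, -1.5, 1.5)
print("gradient-integrated mean composition:", np.round(mean.parts, 4))

# dissimilarity between expected compositions factorizes for quadratics:
# d(z1, z2) = |z1 - z2| · ||β1 + (z1 + z2)β2||
d = expected_dissimilarity(curve, -1.0, 1.0)
print(f"dissimilarity between z=-1 and z=+1: {d:.4f}")

# the same composition can recur at two depths only if β2 = c·β1; then the
# dissimilarity vanishes along the counter-diagonal z1 + z2 = -1/c
collinear = PolySimplexCurve(
    np.vstack([beta[0], beta[1], -0.5 * beta[1]]), basis
)
res = collinearity_check(collinear)
print(f"collinear curve: c = {res['c']:.2f}; "
      f"d(0.5, 1.5) = {expected_dissimilarity(collinear, 0.5, 1.5):.2e} "
      "(z1+z2 = 2 = -1/c, so the two expected compositions coincide)")
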