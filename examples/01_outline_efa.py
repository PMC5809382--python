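"""Decompose a shell outline into elliptic Fourier harmonics.

Builds a mussel-like closed curve, extracts 7 harmonics, normalizes
away size/rotation/start point, and shows how quickly the harmonic
power accumulates — the basis for choosing how many harmonics to keep.
"""

import numpy as np

from musselshape.efa import efa_forward, efa_inverse, efa_normalize, harmonic_power
from musselshape.outline_io import Outline

t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
r = 1 + 0.28 * np.cos(t) + 0.10 * np.sin(2 * t) + 0.045 * np.cos(3 * t)
outline = Outline("demo", "lateral", np.column_stack([r * np.cos(t), 0.6 * r * np.sin(t)]))

coeffs = efa_normalize(efa_forward(outline, 7))
power, cumulative = harmonic_power(coeffs)

print("normalized first harmonic (a1, b1, c1, d1):", np.round(coeffs.harmonics[0], 4))
print("cumulative power fraction per harmonic:")
for n, frac in enumerate(cumulative, start=1):
    print(f"  harmonic {n}: {frac:.6f}")
# the first harmonic is the best-fitting ellipse; the tail harmonics add
# finer outline detail.  d1 < 1 is the ellipse's minor/major axis ratio.

reconstruction = efa_inverse(coeffs, 512)
back = efa_normalize(efa_forward(reconstruction, 7))
print("round-trip coefficient error:", np.abs(back.harmonics - coeffs.harmonics).max())
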