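"""Quaternion pre-processing: canonical form, geodesic distance, SLERP.

Joint rotations arrive as arbitrary-sign, roughly-unit quaternions; the
pipeline first canonicalizes them (unit norm, w >= 0) so every rotation has
one representation.  Distances between rotations use the quaternion-log
geodesic (half the relative rotation angle), and blending uses SLERP along
the geodesic arc.
"""

import numpy as np

from mirrorgame import canonicalize, from_axis_angle, geodesic_distance, slerp

raw = np.array([-0.5, 0.5, 0.5, 0.5])  # non-canonical sign
q = canonicalize(raw)
print(f"canonicalize({raw}) -> {q}")

identity = np.array([1.0, 0.0, 0.0, 0.0])
quarter_turn = from_axis_angle(np.array([0.0, 0.0, 1.0]), np.pi / 2)
d = geodesic_distance(identity, quarter_turn)
print(f"geodesic(identity, 90deg-about-z) = {d:.6f} rad  (= pi/4, half the angle)")

halfway = slerp(identity, quarter_turn, 0.5)
print(f"slerp(identity, 90deg, w=0.5)     = {np.round(halfway, 6)}  (45deg about z)")

# constant angular velocity: equal steps in w give equal geodesic steps
steps = [
    geodesic_distance(slerp(identity, quarter_turn, w), slerp(identity, quarter_turn, w + 0.25))
    for w in (0.0, 0.25, 0.5, 0.75)
]
print("geodesic per quarter-step of w:", np.round(steps, 6), "(all equal)")
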