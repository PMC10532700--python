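"""Generate a synthetic pre/post CT pair with full ground truth.

The phantom is a bone-like body cut by four planes; the freed fragment is
repositioned by a known rigid transform, callus forms at the cut
interfaces, and four metal screws fix the fragment.  Every quantity the
pipeline later estimates is recorded exactly.
"""

import numpy as np

from postop3d import PhantomConfig, make_phantom

pre, post, truth = make_phantom(PhantomConfig(seed=42))

print(f"volumes: {pre.shape} voxels at {pre.spacing[0]:.1f} mm")
print(f"fragment voxels (post frame): {int((truth.fragment_label.values > 0).sum())}")
print(f"whole-body scanner offset:    {truth.coarse_transform.rotation_angle_deg():.2f} deg")
print(f"fragment repositioning:       {truth.fine_transform.rotation_angle_deg():.2f} deg, "
      f"|t| = {np.linalg.norm(truth.fine_transform.translation):.2f} mm")
for j, p in enumerate(truth.planes, 1):
    print(f"cut plane {j}: center {np.round(p.center, 1)}, normal {np.round(p.normal, 3)}")
print(f"screws: {len(truth.screws)}, entry points at z = "
      f"{[round(float(s.entry_point[2]), 1) for s in truth.screws]} mm")

# The rotation magnitudes above are the ground truth the registration and
# plane-detection stages must recover; the entry points are what the screw
# stage must find.
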