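"""Extract vertex-wise texture features from a phantom surface.

At each surface vertex, spherical neighbourhoods of 3/5/7 mm are split by
the structure boundary into inner (IR) and outer (OR) regions, yielding the
9-component feature vector: normalized intensity (NI = mean/SD of IR),
relative intensity (RI = 2(OR-IR)/(OR+IR), the boundary contrast), and the
mean intensity-gradient magnitude (IG).
"""
import numpy as np

from mtlseg.features import FEATURE_NAMES, compute_vertex_features
from mtlseg.synthetic import PhantomSpec, make_phantom

volume, label, surface = make_phantom(PhantomSpec(level=3), seed=7)
feats = compute_vertex_features(volume, surface, boundary=label)

print(f"feature matrix: {feats.values.shape} (vertices x features)")
print(f"{'feature':>8s} {'mean':>8s} {'sd':>8s}")
for name, col in zip(FEATURE_NAMES, feats.values.T):
    print(f"{name:>8s} {col.mean():8.3f} {col.std():8.3f}")
# RI sits around 0.3: structure intensity 70 against tissue 100 gives
# 2*(100-70)/(100+70) = 0.35 at an ideally placed boundary; noise and
# partial neighbourhoods pull it slightly down. A vertex with RI near 0
# would indicate a boundary without local contrast.
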