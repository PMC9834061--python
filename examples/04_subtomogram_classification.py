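"""Wedge-aware sub-tomogram classification of a two-species mixture.

Ribosome-like particles, half of them carrying an extra surface blob (an
rRNA expansion-segment mimic), are wedge-filtered, degraded to SNR 0.3 and
classified with k = 2.  Scores are computed only over each particle's
sampled Fourier region — without that, classes split on wedge orientation
instead of structure.
"""

import numpy as np
import pandas as pd

from helicta import (
    AcquisitionGeometry,
    ParticleTable,
    Volume,
    add_noise,
    apply_missing_wedge,
    classify_subtomograms,
    ribosome_model,
)
from helicta._geom import matrix_to_euler_zyz, rotate_data
from helicta.simulate import _random_rotation_matrices

vox = 9.02
plain = ribosome_model(vox)
expanded = ribosome_model(vox, expansion_blob=True)
geometry = AcquisitionGeometry()

rng = np.random.default_rng(5)
n = 40
rotations = _random_rotation_matrices(n, rng)
labels = np.array([i % 2 for i in rng.permutation(n)])  # 0 plain, 1 expanded

particles, rows = [], []
for i in range(n):
    base = expanded if labels[i] else plain
    v = Volume(rotate_data(base.data, rotations[i]), vox)
    v = apply_missing_wedge(v, geometry)
    v = add_noise(v, 0.3, seed=1000 + i)
    particles.append(v)
    rot, tilt, psi = matrix_to_euler_zyz(rotations[i])
    rows.append(dict(particle_id=i, center_x=0.0, center_y=0.0, center_z=0.0,
                     euler_rot=rot, euler_tilt=tilt, euler_psi=psi))
table = ParticleTable(pd.DataFrame(rows))

result = classify_subtomograms(particles, 2, seed=3, table=table, geometry=geometry)
purity = max((result.assignments == labels).mean(),
             (result.assignments == 1 - labels).mean())

print(f"particles: {n} (50/50 mixture), SNR 0.3, +-60 deg wedge")
print(f"class populations: {result.populations.tolist()}")
print(f"classification purity: {purity:.2f}")
# Purity is the best label matching between recovered classes and the
# simulator's ground-truth species; >= 0.9 means the expansion-segment
# density is reliably separable at this noise level.
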