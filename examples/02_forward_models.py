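"""Sphere-based forward models and their analytic identities.

Fits single and overlapping spheres to a scalp, builds the three-shell EEG
model with its Berg three-dipole approximation, and prints the physical
identities that hold in these models: a radial MEG dipole is silent, MEG
ignores conductivity, and the Berg fit reproduces the exact multilayer
series to a fraction of a percent.
"""

import numpy as np

from sourcestorm import forward as fw
from sourcestorm import simulate as sim

spec = sim.SimSpec(seed=7, n_eeg=32, n_meg=64)
head = sim.make_head(spec)
sensors = sim.make_sensors(spec, head["scalp"])

center, radius = fw.fit_sphere(head["scalp"].vertices)
print(f"fitted scalp sphere: center {np.round(center, 4)}, radius {radius:.3f} m")

over = fw.fit_overlapping_spheres(head["scalp"], sensors)
radii = [s.radii[0] for s in over.spheres.values()]
print(f"overlapping spheres: {len(radii)} per-channel fits, "
      f"radius spread {np.ptp(radii):.2e} m (0 on a spherical scalp)")

# radial dipole silence
pos = 0.12 * np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
b = fw.meg_sphere_gain(center, (0, 0, 0.06), (0, 0, 1e-9), pos, ori)
print(f"radial dipole field at 3 magnetometers: max |B| = {np.abs(b).max():.2e} T")

model = fw.SphereModel.three_shell(center, radius)
berg = fw.berg_approximation(model)
print(f"Berg approximation: lambdas {np.round(berg.lambdas, 3)}, "
      f"fit RMS {berg.rms_rel * 100:.3f}% of signal")

src = fw.build_source_space(head["cortex"], target_n=300)
lf = fw.compute_leadfield(model, src, sensors)
print(f"lead field: {lf.gain.shape[0]} channels x {lf.gain.shape[1]} dipoles")
eeg_rows = [i for i, k in enumerate(sensors.kinds()) if k == "EEG"]
print(f"EEG average reference: max column mean = "
      f"{np.abs(lf.gain[eeg_rows].mean(axis=0)).max():.2e} V (exactly zero-mean)")
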