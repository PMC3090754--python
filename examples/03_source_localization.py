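"""Localize a simulated dipole with MN, dSPM, sLORETA, LCMV, and MUSIC.

Simulates a single cortical source at SNR 10, estimates the noise
covariance from noise-only data, and reports each method's peak-location
error in centimeters.  sLORETA should land exactly on the true vertex
(zero localization bias); the beamformer and MUSIC peaks should be close.
"""

import numpy as np

from sourcestorm import forward as fw
from sourcestorm import inverse as inv
from sourcestorm import simulate as sim
from sourcestorm.core_io import ChannelInfo, Recording, SensorArray

spec = sim.SimSpec(seed=3, n_eeg=32, n_meg=64, cortex_subdivisions=4)
head = sim.make_head(spec)
sensors = sim.make_sensors(spec, head["scalp"])
src = fw.build_source_space(head["cortex"], target_n=2000)
center, radius = fw.fit_sphere(head["scalp"].vertices)
leadfield = fw.compute_leadfield(fw.SphereModel.three_shell(center, radius),
                                 src, sensors)

profile = sim.noise_profile(leadfield)
rng = np.random.default_rng(0)
channels = [ChannelInfo(name=n, kind="MEG_MAG" if n.startswith("MEG") else "EEG",
                        orientation=[0, 0, 1.0] if n.startswith("MEG") else None)
            for n in leadfield.row_channels]
noise_rec = Recording(data=profile[:, None] * rng.standard_normal((len(profile), 20000)),
                      sfreq=250.0, sensors=SensorArray(channels=channels))
noise_cov = inv.estimate_noise_cov(noise_rec)

true_vertex = 842
spec.sources = [sim.SourceSpec(vertex=true_vertex, amplitude=10e-9)]
spec = sim.snr_scale(leadfield, spec, target_snr=10.0, profile=profile)
epochs, truth = sim.simulate_recordings(spec, leadfield)
data = epochs.epochs.mean(axis=0)

_, op_mn = inv.minimum_norm(leadfield, noise_cov)
ops = {"MN": op_mn, "dSPM": inv.dspm(op_mn, noise_cov),
       "sLORETA": inv.sloreta(op_mn)}
true_pos = src.positions[true_vertex]
for name, op in ops.items():
    est = inv.apply_inverse(op, data)
    peak = int(np.argmax((est.values ** 2).sum(axis=1)))
    err = np.linalg.norm(src.positions[peak] - true_pos) * 100
    print(f"{name:8s} peak error: {err:5.2f} cm")

# beamformer: data covariance from the single trials, not the average
X = epochs.epochs.transpose(1, 0, 2).reshape(len(channels), -1)
X = X - X.mean(axis=1, keepdims=True)
Cd = X @ X.T / X.shape[1]
data_cov = inv.NoiseCovariance(matrix=Cd, channel_names=leadfield.row_channels)
res = inv.lcmv(leadfield, data_cov, noise_cov, data)
err = np.linalg.norm(src.positions[int(np.argmax(res.nai))] - true_pos) * 100
print(f"{'LCMV':8s} NAI peak error: {err:5.2f} cm")

scores = inv.music_scan(leadfield, data, n_sources=1, noise_cov=noise_cov)
err = np.linalg.norm(src.positions[int(np.argmax(scores))] - true_pos) * 100
print(f"{'MUSIC':8s} subcorr peak error: {err:5.2f} cm "
      f"(max subcorr {scores.max():.3f})")
print("errors are in centimeters on a 10 cm head; sLORETA is exactly unbiased")
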