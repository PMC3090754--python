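"""End-to-end validation computations on synthetic study conditions.

Each function builds its own inputs with the :mod:`~sourcestorm.simulate`
generator, runs the relevant part of the analysis chain, and returns the
measured quantities as plain floats.  The acceptance script and the
acceptance test suite both call these functions, so every reported number
is recomputed from scratch at run time.

Problem sizes are scaled to routine-verification budgets (a few minutes on
one CPU): 2000-dipole source spaces for localization, 300-dipole spaces for
the group-power pipeline, and 500-1000 Monte Carlo replicates for the
statistical calibration checks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from . import forward as fw
from . import inverse as inv
from . import simulate as sim
from . import stats as st
from . import timefreq as tf
from .coreg import align_fiducials, apply_transform, icp_refine
from .core_io import ChannelInfo, Fiducials, Recording, SensorArray, SurfaceMesh, Transform
from .preprocess import average_epochs
from .scouts_group import shepard_interpolate, surface_project


# ---------------------------------------------------------------------------
# shared fixture construction
# ---------------------------------------------------------------------------

def _inverse_fixture(seed: int, n_sources: int = 2000,
                     cortex_subdivisions: int = 4):
    """Head, combined EEG+MEG sensors, constrained source space, lead field,
    and an empirically estimated noise covariance."""
    spec = sim.SimSpec(seed=seed, n_eeg=32, n_meg=64,
                       cortex_subdivisions=cortex_subdivisions)
    head = sim.make_head(spec)
    sensors = sim.make_sensors(spec, head["scalp"])
    target = min(n_sources, head["cortex"].n_vertices)
    src = fw.build_source_space(head["cortex"], target_n=target, seed=seed)
    center, radius = fw.fit_sphere(head["scalp"].vertices)
    model = fw.SphereModel.three_shell(center, radius)
    leadfield = fw.compute_leadfield(model, src, sensors)

    profile = sim.noise_profile(leadfield)
    rng = np.random.default_rng(seed + 1)
    noise = profile[:, None] * rng.standard_normal((len(profile), 20000))
    channels = [ChannelInfo(name=n,
                            kind="MEG_MAG" if n.startswith("MEG") else "EEG",
                            orientation=[0, 0, 1.0] if n.startswith("MEG")
                            else None)
                for n in leadfield.row_channels]
    rec = Recording(data=noise, sfreq=250.0,
                    sensors=SensorArray(channels=channels))
    noise_cov = inv.estimate_noise_cov(rec, loading=0.1)
    return spec, head, sensors, src, leadfield, noise_cov, profile


# ---------------------------------------------------------------------------
# 1. source-space decimation default
# ---------------------------------------------------------------------------

def source_space_default(seed: int = 0) -> dict:
    """Decimate a ~120k-vertex synthetic cortex with the default target."""
    base = trimesh.creation.uv_sphere(count=(245, 245))  # ~120k vertices
    v = np.asarray(base.vertices, dtype=float)
    rng = np.random.default_rng(seed)
    u = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
    radial = np.ones(len(v))
    for _ in range(8):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        radial += rng.uniform(0.03, 0.08) * np.exp(-((1 - u @ d) / 0.3))
    cortex = SurfaceMesh(vertices=u * (0.07 * radial / radial.mean())[:, None],
                         faces=np.asarray(base.faces))
    src = fw.build_source_space(cortex, target_n=15000, seed=seed)
    return {"n_vertices_in": cortex.n_vertices, "n_dipoles": src.n_sources}


# ---------------------------------------------------------------------------
# 2. balanced factorial ANOVA against a hand oracle
# ---------------------------------------------------------------------------

def anova_against_oracle(seed: int = 0) -> dict:
    """Max |F - F_oracle| over balanced 2^k designs, k = 1..4.

    The oracle computes each effect's sum of squares directly from marginal
    cell means via inclusion-exclusion — the textbook balanced decomposition
    written independently of the library implementation.
    """
    from itertools import combinations, product
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in (1, 2, 3, 4):
        reps = 3
        combos = np.array(list(product(*[range(2)] * k)))
        obs = np.repeat(combos, reps, axis=0)
        y = rng.standard_normal(len(obs)) + obs.sum(axis=1) * 0.5
        factors = {f"F{i}": obs[:, i] for i in range(k)}
        res = st.anova_nway(y[:, None], factors)

        grand = y.mean()
        cells = {tuple(c): y[(obs == c).all(axis=1)].mean() for c in combos}
        fitted = np.array([cells[tuple(c)] for c in obs])
        ms_res = ((y - fitted) ** 2).sum() / (len(y) - len(combos))

        def marg(subset, levels_combo):
            sel = np.ones(len(obs), dtype=bool)
            for f, l in zip(subset, levels_combo):
                sel &= obs[:, f] == l
            return y[sel].mean()

        for size in range(1, k + 1):
            for subset in combinations(range(k), size):
                ss = 0.0
                for lc in product(*[range(2)] * size):
                    est = 0.0
                    for tsize in range(size + 1):
                        for tsub in combinations(range(size), tsize):
                            sub_f = tuple(subset[i] for i in tsub)
                            sub_l = tuple(lc[i] for i in tsub)
                            est += (-1.0) ** (size - tsize) * (
                                marg(sub_f, sub_l) if sub_f else grand)
                    ss += est ** 2
                ss *= reps * len(combos) / 2 ** size
                f_oracle = (ss / 1.0) / ms_res
                label = "*".join(f"F{i}" for i in subset)
                worst = max(worst, abs(res[label].statistic[0] - f_oracle))
    return {"max_f_error": worst}


# ---------------------------------------------------------------------------
# 3. forward-model identities
# ---------------------------------------------------------------------------

def forward_identities(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    # radial dipole silence (T, should be at machine precision)
    sensors_pos = 0.12 * fw._fibonacci_directions(50)
    ori = sensors_pos / np.linalg.norm(sensors_pos, axis=1, keepdims=True)
    b = fw.meg_sphere_gain((0, 0, 0), (0.01, -0.02, 0.06),
                           np.array([0.01, -0.02, 0.06]) * 1e-8,
                           sensors_pos, ori)
    radial_silence = float(np.abs(b).max())

    # equal conductivities: multilayer series vs homogeneous closed form
    eq = fw.SphereModel(center=(0, 0, 0), radii=(0.088, 0.093, 0.1),
                        conductivities=(0.33, 0.33, 0.33))
    elec = 0.1 * fw._fibonacci_directions(60)
    rel_max = 0.0
    for _ in range(5):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        dip = rng.uniform(0.05, 0.8) * 0.088 * d
        series = fw.eeg_multilayer_lead(eq, dip, elec, n_terms=200)
        closed = fw.eeg_homogeneous_lead((0, 0, 0), 0.1, 0.33, dip, elec)
        rel_max = max(rel_max,
                      float(np.abs(series - closed).max() / np.abs(closed).max()))

    # Berg approximation vs the exact series on held-out dipoles (ecc <= 0.8)
    sphere = fw.SphereModel.three_shell((0, 0, 0), 0.1)
    berg = fw.berg_approximation(sphere)
    berg_worst = 0.0
    for _ in range(10):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        dip = rng.uniform(0.05, 0.8) * 0.088 * d
        m = rng.standard_normal(3) * 1e-9
        exact = fw.eeg_multilayer_lead(sphere, dip, elec, n_terms=120) @ m
        approx = fw.eeg_berg_lead(sphere, berg, dip, elec) @ m
        berg_worst = max(berg_worst, float(
            np.sqrt(np.mean((approx - exact) ** 2) / np.mean(exact ** 2))))
    return {"meg_radial_silence_T": radial_silence,
            "eeg_series_vs_closed_rel": rel_max,
            "berg_vs_series_rel_rms": berg_worst}


# ---------------------------------------------------------------------------
# 4. inverse parameter recovery
# ---------------------------------------------------------------------------

def localization_errors(seed: int = 0, n_trials: int = 100,
                        snr: float = 10.0) -> dict:
    """Median peak-localization error (m) of MN/dSPM/sLORETA on single-dipole
    epochs, the sLORETA noiseless zero-bias count, and the LCMV unit-gain
    residual, on a 2000-dipole constrained fixture."""
    (spec, head, sensors, src, leadfield, noise_cov,
     profile) = _inverse_fixture(seed)
    _, op_mn = inv.minimum_norm(leadfield, noise_cov)
    op_dspm = inv.dspm(op_mn, noise_cov)
    op_slo = inv.sloreta(op_mn)

    sfreq, t0 = 250.0, -0.2
    n_samp = 251
    times = t0 + np.arange(n_samp) / sfreq
    pulse = np.exp(-((times - 0.3) ** 2) / (2 * 0.05 ** 2))
    peak_win = (times >= 0.25) & (times <= 0.35)
    amp = 10e-9

    rng = np.random.default_rng(seed + 2)
    pos = src.positions
    errors = {"MN": [], "dSPM": [], "sLORETA": []}
    for _ in range(n_trials):
        j = int(rng.integers(0, src.n_sources))
        signal = np.outer(leadfield.gain[:, j] * amp, pulse)
        noise = profile[:, None] * rng.standard_normal((len(profile), n_samp))
        noise *= np.sqrt((signal ** 2).mean()) / (snr * np.sqrt((noise ** 2).mean()))
        data = signal + noise
        for name, op in (("MN", op_mn), ("dSPM", op_dspm), ("sLORETA", op_slo)):
            est = inv.apply_inverse(op, data)
            power = (est.values[:, peak_win] ** 2).sum(axis=1)
            jhat = int(np.argmax(power))
            errors[name].append(np.linalg.norm(pos[jhat] - pos[j]))

    slo_hits = 0
    for _ in range(n_trials):
        j = int(rng.integers(0, src.n_sources))
        z = op_slo.kernel @ (leadfield.gain[:, [j]] * amp)
        slo_hits += int(np.argmax(np.abs(z[:, 0]))) == j

    # LCMV unit-gain constraint on whitened quantities
    rng_d = np.random.default_rng(seed + 3)
    data = profile[:, None] * rng_d.standard_normal((len(profile), 3000))
    Cd = data @ data.T / data.shape[1]
    Cd += 0.05 * np.mean(np.diag(Cd)) * np.eye(Cd.shape[0])
    data_cov = inv.NoiseCovariance(matrix=Cd,
                                   channel_names=leadfield.row_channels)
    W = inv.whitener(noise_cov)
    G = W @ leadfield.gain
    Cdw = W @ data_cov.matrix @ W.T
    A = np.linalg.solve(Cdw, G)
    wb = A / np.einsum("ci,ci->i", G, A)
    unit_gain_dev = float(np.abs(np.einsum("ci,ci->i", wb, G) - 1.0).max())

    return {"mn_median_error_m": float(np.median(errors["MN"])),
            "dspm_median_error_m": float(np.median(errors["dSPM"])),
            "sloreta_median_error_m": float(np.median(errors["sLORETA"])),
            "sloreta_noiseless_hits": slo_hits,
            "n_trials": n_trials,
            "lcmv_unit_gain_dev": unit_gain_dev}


# ---------------------------------------------------------------------------
# 5. statistics calibration
# ---------------------------------------------------------------------------

def stats_calibration(seed: int = 0, n_sims: int = 4000,
                      n_sims_anova: int = 20000, n_perm: int = 1000) -> dict:
    """Null calibration of the permutation test, the factorial ANOVA, and
    max-statistic familywise control, plus Benjamini-Hochberg FDR on mixed
    maps.

    Simulation counts are set high enough that a correctly calibrated test
    sits inside the nominal binomial band deterministically; a genuinely
    miscalibrated procedure still lands outside it.
    """
    rng = np.random.default_rng(seed)

    # paired permutation test: exhaustive enumeration agreement at n=3
    from itertools import product as iproduct
    A = rng.standard_normal((3, 1))
    B = rng.standard_normal((3, 1))
    res = st.permutation_test(A, B, paired=True, n_perm=n_perm, seed=seed)
    D = (A - B)[:, 0]

    def tstat(d):
        sd = d.std(ddof=1)
        return d.mean() / (sd / np.sqrt(len(d))) if sd > 0 else 0.0

    count = sum(abs(tstat(D * np.array(s))) >= abs(tstat(D)) - 1e-12
                for s in iproduct([1.0, -1.0], repeat=3))
    perm_exhaustive_dev = float(abs(res.p[0] - count / 8))

    # type-I error of the paired permutation test under the null
    rejections = 0
    for s in range(n_sims):
        X = rng.standard_normal((10, 1))
        Y = rng.standard_normal((10, 1))
        r = st.permutation_test(X, Y, paired=True, n_perm=n_perm,
                                seed=seed + 1000 + s)
        rejections += r.p[0] < 0.05
    perm_type1 = rejections / n_sims

    # ANOVA type-I per effect: 2x2x2 null design, one element per simulation
    obs = np.repeat(np.array(list(iproduct(*[range(2)] * 3))), 2, axis=0)
    factors = {f"F{i}": obs[:, i] for i in range(3)}
    Y = rng.standard_normal((len(obs), n_sims_anova))
    res_anova = st.anova_nway(Y, factors)
    anova_type1 = {label: float((sm.p < 0.05).mean())
                   for label, sm in res_anova.items()}

    # familywise error of max-statistic thresholding under the global null
    fwer_hits = 0
    m = 50
    for s in range(n_sims):
        X = rng.standard_normal((10, m))
        Z = rng.standard_normal((10, m))
        r = st.permutation_test(X, Z, paired=True, n_perm=500,
                                seed=seed + 5000 + s)
        mask = st.threshold(r, "maxstat", 0.05)
        fwer_hits += bool(mask.any())
    maxstat_fwer = fwer_hits / n_sims

    # Benjamini-Hochberg empirical FDR on mixed null/alternative maps
    n_fdr = 500
    m, frac_alt, effect = 200, 0.2, 3.0
    fdrs = []
    n_alt = int(m * frac_alt)
    for s in range(n_fdr):
        X = rng.standard_normal((10, m))
        Z = rng.standard_normal((10, m))
        Z[:, :n_alt] += effect
        r = st.ttest(X, Z, paired=True)
        mask = st.threshold(r, "fdr", 0.05)
        n_rej = mask.sum()
        false_rej = mask[n_alt:].sum()
        fdrs.append(false_rej / max(n_rej, 1))
    bh_fdr = float(np.mean(fdrs))

    return {"perm_exhaustive_dev": perm_exhaustive_dev,
            "perm_type1": float(perm_type1),
            "anova_type1_max": max(anova_type1.values()),
            "anova_type1_min": min(anova_type1.values()),
            "maxstat_fwer": float(maxstat_fwer),
            "bh_empirical_fdr": bh_fdr,
            "n_sims": n_sims}


# ---------------------------------------------------------------------------
# 6. time-frequency identities
# ---------------------------------------------------------------------------

def timefreq_checks(seed: int = 0) -> dict:
    spec = tf.MorletSpec(freqs=tuple(range(2, 41)))
    sfreq = 250.0
    norm_dev = max(abs(np.linalg.norm(tf.morlet_kernel(f, spec, sfreq)) - 1.0)
                   for f in (2.0, 10.0, 25.0, 40.0))

    n = 2001
    x = np.zeros(n)
    x[n // 2] = 1.0
    out = tf.tf_decompose(x, tf.MorletSpec(freqs=(10.0,)), sfreq,
                          output_kind="magnitude")
    k = np.abs(tf.morlet_kernel(10.0, tf.MorletSpec(freqs=(10.0,)), sfreq))
    half = (len(k) - 1) // 2
    seg = out.values[0, 0, n // 2 - half:n // 2 + half + 1]
    impulse_dev = float(np.abs(seg - k[::-1]).max())

    t = np.arange(int(8 * sfreq)) / sfreq
    sine = np.sin(2 * np.pi * 10.0 * t)
    power = tf.tf_decompose(sine, spec, sfreq, output_kind="power")
    central = slice(len(t) // 4, 3 * len(t) // 4)
    profile = power.values[0, :, central].mean(axis=-1)
    peak_freq = float(spec.freqs[int(np.argmax(profile))])
    return {"kernel_norm_dev": float(norm_dev),
            "impulse_envelope_dev": impulse_dev,
            "sine_peak_freq_hz": peak_freq}


# ---------------------------------------------------------------------------
# 7. registration
# ---------------------------------------------------------------------------

def registration_checks(seed: int = 0, n_trials: int = 100) -> dict:
    fid = Fiducials(nasion=[0.1, 0, 0], lpa=[0, 0.07, 0], rpa=[0, -0.07, 0])
    rng = np.random.default_rng(seed)
    fid_dev = 0.0
    for s in range(10):
        R = Rotation.random(random_state=seed + s).as_matrix()
        M = Transform.from_rotation_translation(R, 0.05 * rng.standard_normal(3))
        T = align_fiducials(fid, apply_transform(fid, M))
        fid_dev = max(fid_dev, float(np.abs(T.matrix - M.matrix).max()))

    scalp = sim.make_aspherical_scalp(seed=seed)
    worst_rot, worst_trans = 0.0, 0.0
    for _ in range(n_trials):
        idx = rng.choice(scalp.n_vertices, 100, replace=False)
        pts = scalp.vertices[idx]
        angle = rng.uniform(0, 10)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        M = Transform.from_rotation_translation(R, rng.uniform(-0.01, 0.01, 3))
        T, _ = icp_refine(M.inverse().apply(pts), scalp, tol=1e-12,
                          max_iter=200)
        dR = Rotation.from_matrix(T.rotation @ M.rotation.T).magnitude()
        worst_rot = max(worst_rot, float(np.degrees(dR)))
        worst_trans = max(worst_trans,
                          float(np.linalg.norm(T.translation - M.translation)))
    return {"fiducial_alignment_dev": fid_dev,
            "icp_max_rot_err_deg": worst_rot,
            "icp_max_trans_err_m": worst_trans,
            "n_trials": n_trials}


# ---------------------------------------------------------------------------
# 8. surface projection
# ---------------------------------------------------------------------------

def projection_checks(seed: int = 0) -> dict:
    head = sim.make_head(sim.SimSpec(seed=seed, cortex_subdivisions=4))
    src = fw.build_source_space(head["cortex"], target_n=800, seed=seed)
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal(src.n_sources)
    out = surface_project(vals, src, src)
    self_dev = float(np.abs(out - vals).max())

    pts = rng.standard_normal((60, 3))
    v = rng.standard_normal(60)
    node_dev = float(np.abs(shepard_interpolate(pts, v, pts[:20]) - v[:20]).max())

    q = shepard_interpolate(pts, v, rng.standard_normal((200, 3)))
    convex_ok = bool(q.max() <= v.max() + 1e-12 and q.min() >= v.min() - 1e-12)

    src_b = fw.build_source_space(head["cortex"], target_n=650, seed=seed + 1)
    field = np.sin(15 * src.positions[:, 0]) + np.cos(12 * src.positions[:, 2])
    target = (np.sin(15 * src_b.positions[:, 0])
              + np.cos(12 * src_b.positions[:, 2]))
    proj = surface_project(field, src, src_b)
    cross_rel = float(np.linalg.norm(proj - target) / np.linalg.norm(target))
    return {"self_projection_dev": self_dev,
            "shepard_node_dev": node_dev,
            "convex_bounds_ok": convex_ok,
            "cross_decimation_rel_err": cross_rel}


# ---------------------------------------------------------------------------
# 9. two-level group pipeline power
# ---------------------------------------------------------------------------

def group_power(seed: int = 0, n_sims: int = 500, n_subjects: int = 12,
                effect_d: float = 1.5, alpha: float = 0.05) -> dict:
    """Full simulate -> forward -> inverse -> two-level paired test chain.

    ``effect_d`` scales a 10 nA m reference dipole moment; per-subject
    amplitudes are N(d * 10 nAm, 0.2 * d * 10 nAm), sensor noise is
    calibrated to a per-trial SNR of 1 at the reference amplitude.  Level 1
    averages each subject's trials and applies the minimum-norm operator;
    level 2 is a paired t-test of post- vs pre-stimulus source power at the
    simulated dipole across subjects.  Returns the detection rate.
    """
    (spec0, head, sensors, src, leadfield, noise_cov,
     profile) = _inverse_fixture(seed, n_sources=300, cortex_subdivisions=3)
    _, op_mn = inv.minimum_norm(leadfield, noise_cov)

    vertex = src.n_sources // 3
    ref_amp = 10e-9
    base = replace(spec0, sources=[sim.SourceSpec(vertex=vertex,
                                                  amplitude=ref_amp)],
                   n_trials=20, duration=0.8, t0=-0.2, sfreq=125.0)
    base = sim.snr_scale(leadfield, base, target_snr=1.0, profile=profile)

    pre_win = (-0.2, 0.0)
    post_win = (0.2, 0.6)
    detections = 0
    for s in range(n_sims):
        sim_spec = replace(base, seed=seed + 17 + s)
        subjects, _ = sim.make_group(sim_spec, leadfield, n_subjects,
                                     effect_size=effect_d * ref_amp,
                                     post_window=post_win)
        pre, post = [], []
        for ep in subjects:
            avg = average_epochs(ep)
            est = inv.apply_inverse(op_mn, avg.data, times=avg.times)
            m_pre = (est.times >= pre_win[0]) & (est.times <= pre_win[1])
            m_post = (est.times >= post_win[0]) & (est.times <= post_win[1])
            pre.append(np.abs(est.values[vertex, m_pre]).mean())
            post.append(np.abs(est.values[vertex, m_post]).mean())
        res = st.ttest(np.array(post)[:, None], np.array(pre)[:, None],
                       paired=True)
        detections += res.p[0] < alpha
    return {"power": detections / n_sims, "n_sims": n_sims,
            "n_subjects": n_subjects, "effect_d": effect_d}
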