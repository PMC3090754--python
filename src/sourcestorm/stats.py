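"""Two-sample and factorial statistics with permutation alternatives,
multiple-comparison thresholding, and the two-level group pipeline.

All tests operate elementwise over maps: inputs are (n_observations, m)
arrays where m indexes sensors, sources, or time-frequency bins, and the
outputs are per-element statistic and p-value maps.  Permutation p-values
use the plus-one rule ``p = (1 + #{|T*| >= |T|}) / (1 + n_perm)`` and never
reach zero; when the total number of arrangements is small the schemes
enumerate exhaustively.  Group analysis follows the summary-statistic
approach: per-subject trial averages and window summaries first, then a
paired test across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import EpochSet
from .preprocess import average_epochs


@dataclass
class StatMap:
    statistic: np.ndarray
    p: np.ndarray
    method: str
    df: float | tuple | None = None
    mask: np.ndarray | None = None
    null_max: np.ndarray | None = None  # permutation max-statistic distribution

    def __post_init__(self):
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class GroupDesign:
    """Subjects x elements first-level summaries plus an optional factor table."""

    summaries: np.ndarray
    paired: bool = True
    factors: dict | None = None

    def __post_init__(self):
        self.summaries = np.atleast_2d(np.asarray(self.summaries, dtype=float))
        if self.summaries.shape[0] < 2:
            raise ValueError("group design needs at least 2 subjects")


def _as2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a.reshape(a.shape[0], -1)


# ---------------------------------------------------------------------------
# t tests and difference
# ---------------------------------------------------------------------------

def ttest(sample_a, sample_b, paired: bool = False,
          equal_var: bool = True) -> StatMap:
    """Elementwise Student / Welch / paired t-test with two-sided p-values.

    Zero-variance elements get statistic 0 and p 1 (counted in a warning)
    rather than NaN.
    """
    A, B = _as2d(sample_a), _as2d(sample_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if A.shape != B.shape:
            raise ValueError("paired test needs equal-size samples")
        res = sps.ttest_rel(A, B, axis=0)
        df = A.shape[0] - 1
        method = "ttest-paired"
    else:
        res = sps.ttest_ind(A, B, axis=0, equal_var=equal_var)
        df = (A.shape[0] + B.shape[0] - 2 if equal_var
              else _welch_df(A, B))
        method = "ttest-ind" if equal_var else "ttest-welch"
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{bad.sum()} element(s) with zero variance: t=0, p=1")
        t[bad] = 0.0
        p[bad] = 1.0
    return StatMap(statistic=t, p=p, method=method, df=df)


def _welch_df(A, B):
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    na, nb = A.shape[0], B.shape[0]
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, na + nb - 2)


def difference(sample_a, sample_b) -> np.ndarray:
    """Elementwise mean(A) - mean(B)."""
    A, B = _as2d(sample_a), _as2d(sample_b)
    if A.size == 0 or B.size == 0:
        raise ValueError("empty sample")
    return A.mean(axis=0) - B.mean(axis=0)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _default_stat_paired(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _default_stat_unpaired(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na, nb = A.shape[0], B.shape[0]
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sp > 0,
                     (A.mean(axis=0) - B.mean(axis=0))
                     / (sp * np.sqrt(1 / na + 1 / nb)), 0.0)
    return t


def permutation_test(sample_a, sample_b, paired: bool = False,
                     n_perm: int = 1000, stat_fn=None,
                     seed: int | None = 0) -> StatMap:
    """Nonparametric permutation test (sign flips when paired, label
    shuffles otherwise), with exhaustive enumeration when the total number
    of arrangements does not exceed ``n_perm``.

    The returned StatMap carries the permutation distribution of the
    maximum absolute statistic across elements (``null_max``) for use with
    max-statistic thresholding.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    A, B = _as2d(sample_a), _as2d(sample_b)

    if paired:
        if A.shape != B.shape:
            raise ValueError("paired scheme needs equal-size samples")
        D = A - B
        n = D.shape[0]
        stat = stat_fn if stat_fn is not None else _default_stat_paired
        T_obs = stat(D)
        if 2 ** n <= n_perm:
            signs = np.array(list(product([1.0, -1.0], repeat=n)))
            exhaustive = True
        else:
            signs = rng.choice([1.0, -1.0], size=(n_perm, n))
            exhaustive = False
        if stat_fn is None:
            # closed form for the sign-flipped paired t: sum(d_i^2) is
            # flip-invariant, so only the flipped mean needs recomputing
            mean = signs @ D / n
            ssq = (D ** 2).sum(axis=0)
            var = np.maximum(ssq[None, :] - n * mean ** 2, 0.0) / (n - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                T_null = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
        else:
            T_null = np.stack([stat(D * s[:, None]) for s in signs])
    else:
        X = np.vstack([A, B])
        na = A.shape[0]
        n = X.shape[0]
        stat = (stat_fn if stat_fn is not None
                else lambda a, b: _default_stat_unpaired(a, b))
        T_obs = stat(A, B)
        from math import comb
        if comb(n, na) <= n_perm:
            idx_sets = [np.array(c) for c in combinations(range(n), na)]
            exhaustive = True
        else:
            idx_sets = [rng.permutation(n)[:na] for _ in range(n_perm)]
            exhaustive = False
        T_null = []
        all_idx = np.arange(n)
        for ia in idx_sets:
            mask = np.zeros(n, dtype=bool)
            mask[ia] = True
            T_null.append(stat(X[mask], X[~mask]))
        T_null = np.stack(T_null)

    n_used = T_null.shape[0]
    # relative slack: the identity arrangement must always count as >=
    thresh = np.abs(T_obs) * (1 - 1e-9) - 1e-12
    exceed = (np.abs(T_null) >= thresh[None, :]).sum(axis=0)
    if exhaustive:
        p = exceed / n_used  # the identity arrangement is in the enumeration
    else:
        p = (1 + exceed) / (1 + n_used)
    p = np.clip(p, 0.0, 1.0)
    return StatMap(statistic=T_obs, p=p,
                   method="perm-paired" if paired else "perm-unpaired",
                   null_max=np.abs(T_null).max(axis=1))


# ---------------------------------------------------------------------------
# n-way ANOVA (balanced, fixed effects)
# ---------------------------------------------------------------------------

def anova_nway(data, factor_table: dict[str, np.ndarray]) -> dict[str, StatMap]:
    """Fixed-effects full-factorial ANOVA on balanced designs (up to 4 factors).

    ``data`` is (n_observations, m elements); ``factor_table`` maps factor
    names to per-observation level labels.  Every main effect and
    interaction is decomposed by the classical balanced sums-of-squares
    formulas (marginal cell means combined by inclusion-exclusion), so
    effect SS add up to the model SS.  Unbalanced designs are rejected.
    Zero residual variance is floored so constructed noiseless designs
    report a large finite F rather than dividing by zero.
    """
    Y = _as2d(data)
    names = list(factor_table)
    if not 1 <= len(names) <= 4:
        raise ValueError("supports 1 to 4 factors")
    codes, levels = {}, {}
    n_obs = Y.shape[0]
    for f in names:
        lab = np.asarray(factor_table[f])
        if lab.shape[0] != n_obs:
            raise ValueError(f"factor {f}: length mismatch with data")
        uniq, code = np.unique(lab, return_inverse=True)
        codes[f], levels[f] = code, len(uniq)

    n_cells = int(np.prod([levels[f] for f in names]))
    cell_index = np.zeros(n_obs, dtype=np.int64)
    for f in names:
        cell_index = cell_index * levels[f] + codes[f]
    counts = np.bincount(cell_index, minlength=n_cells)
    if counts.min() != counts.max():
        raise ValueError("unbalanced design: unequal cell counts")
    r = int(counts[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell")

    grand = Y.mean(axis=0)

    def marginal_means(subset):
        """Cell means over the factors in ``subset`` (dict key -> mean row)."""
        if not subset:
            return {(): grand}
        sub_levels = [levels[f] for f in subset]
        idx = np.zeros(n_obs, dtype=np.int64)
        for f in subset:
            idx = idx * levels[f] + codes[f]
        total = int(np.prod(sub_levels))
        sums = np.zeros((total, Y.shape[1]))
        np.add.at(sums, idx, Y)
        cnt = np.bincount(idx, minlength=total).astype(float)
        means = sums / cnt[:, None]
        out = {}
        for flat, combo in enumerate(product(*[range(l) for l in sub_levels])):
            out[combo] = means[flat]
        return out

    cache = {(): marginal_means(())}
    results: dict[str, StatMap] = {}
    ss_effects, df_effects = {}, {}
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            cache[subset] = marginal_means(list(subset))

    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            sub_levels = [levels[f] for f in subset]
            eff_sq = np.zeros(Y.shape[1])
            for combo in product(*[range(l) for l in sub_levels]):
                est = np.zeros(Y.shape[1])
                for tsize in range(size + 1):
                    for tsub in combinations(range(size), tsize):
                        t_names = tuple(subset[i] for i in tsub)
                        t_combo = tuple(combo[i] for i in tsub)
                        sign = (-1.0) ** (size - tsize)
                        est += sign * cache[t_names][t_combo]
                eff_sq += est ** 2
            mult = r * n_cells / int(np.prod(sub_levels))
            ss = mult * eff_sq
            df = int(np.prod([l - 1 for l in sub_levels]))
            ss_effects[subset] = ss
            df_effects[subset] = df

    ss_total = ((Y - grand) ** 2).sum(axis=0)
    ss_model = sum(ss_effects.values())
    ss_resid = np.maximum(ss_total - ss_model, 0.0)
    df_resid = n_obs - n_cells
    ms_resid = ss_resid / df_resid
    floor = 1e-30 * max(float(ss_total.max()), 1.0) / max(df_resid, 1)
    ms_resid = np.maximum(ms_resid, floor)

    for subset, ss in ss_effects.items():
        df = df_effects[subset]
        F = (ss / df) / ms_resid
        p = sps.f.sf(F, df, df_resid)
        label = "*".join(subset)
        results[label] = StatMap(statistic=F, p=p, method="anova",
                                 df=(df, df_resid))
    return results


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold(statmap: StatMap, method: str, alpha_or_q: float = 0.05,
              perm_null: np.ndarray | None = None) -> np.ndarray:
    """Multiple-comparison thresholding: returns (and stores) a boolean mask.

    * ``bonferroni``: reject where p < alpha / m.
    * ``fdr``: Benjamini-Hochberg step-up at rate q.
    * ``maxstat``: reject where |statistic| exceeds the (1 - alpha) quantile
      of the permutation distribution of the maximum statistic.
    """
    a = float(alpha_or_q)
    if method == "bonferroni":
        mask = multipletests(statmap.p, alpha=a, method="bonferroni")[0]
    elif method == "fdr":
        mask = multipletests(statmap.p, alpha=a, method="fdr_bh")[0]
    elif method == "maxstat":
        null = perm_null if perm_null is not None else statmap.null_max
        if null is None:
            raise ValueError("maxstat thresholding needs a stored permutation "
                             "max-statistic null")
        crit = np.quantile(null, 1 - a)
        mask = np.abs(statmap.statistic) > crit
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    statmap.mask = mask
    return mask


# ---------------------------------------------------------------------------
# two-level group analysis
# ---------------------------------------------------------------------------

def two_level_group(epoch_sets: list[EpochSet],
                    contrast_windows: tuple[tuple[float, float],
                                            tuple[float, float]],
                    test: str = "ttest", weighted: bool = False,
                    n_perm: int = 1000, seed: int | None = 0) -> StatMap:
    """Summary-statistic group analysis over two time windows.

    Level 1 averages each subject's usable trials and summarizes the average
    in each window (mean over samples, per channel).  Level 2 runs a paired
    test of window A against window B across the subject summaries.  With
    ``weighted=True`` subjects are weighted by inverse within-subject
    variance of the summary difference (equal variances reduce to the
    unweighted test).  ``test`` is ``"ttest"`` or ``"permutation"``.
    """
    (w1, w2) = contrast_windows
    sums_a, sums_b, wvars = [], [], []
    for i, ep in enumerate(epoch_sets):
        good = ep.good()
        if good.shape[0] == 0:
            warnings.warn(f"subject {i}: no usable trials, excluded")
            continue
        avg = average_epochs(ep)
        m1 = (avg.times >= w1[0]) & (avg.times <= w1[1])
        m2 = (avg.times >= w2[0]) & (avg.times <= w2[1])
        if not (m1.any() and m2.any()):
            raise ValueError("contrast window outside the epoch time axis")
        sums_a.append(avg.data[:, m1].mean(axis=1))
        sums_b.append(avg.data[:, m2].mean(axis=1))
        if weighted:
            per_trial = (good[:, :, m1].mean(axis=2)
                         - good[:, :, m2].mean(axis=2))
            wvars.append(per_trial.var(axis=0, ddof=1) / good.shape[0])
    if len(sums_a) < 2:
        raise ValueError("fewer than 2 subjects with usable trials")
    A = np.stack(sums_a)
    B = np.stack(sums_b)

    if weighted:
        V = np.stack(wvars)
        w = 1.0 / np.maximum(V, 1e-300)
        w /= w.sum(axis=0, keepdims=True)
        D = A - B
        n = D.shape[0]
        mean_w = (w * D).sum(axis=0)
        # effective weighted paired t with n-1 df
        var_w = (w * (D - mean_w) ** 2).sum(axis=0) * n / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(var_w > 0, mean_w / np.sqrt(var_w / n), 0.0)
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        return StatMap(statistic=t, p=p, method="group-weighted-ttest", df=n - 1)
    if test == "ttest":
        out = ttest(A, B, paired=True)
        out.method = "group-" + out.method
        return out
    if test == "permutation":
        out = permutation_test(A, B, paired=True, n_perm=n_perm, seed=seed)
        out.method = "group-" + out.method
        return out
    raise ValueError(f"unknown group test {test!r}")
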