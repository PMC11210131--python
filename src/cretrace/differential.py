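"""TMM normalisation, differential accessibility and the resampling null.

Counts are normalised with the trimmed mean of M-values (TMM) scheme: one
sample is picked as reference (75th-percentile count fraction closest to the
column mean), per-sample scale factors are 2^(weighted trimmed mean of
M-values) with 30% two-sided trimming on M, 5% on A and inverse
asymptotic-variance weights, rescaled to geometric mean 1.  Accessibility is
then compared between groups with a per-region Welch two-sample test on
log2 TMM-counts-per-million (pseudocount 0.5), Benjamini-Hochberg adjusted.

The expected-by-chance analysis re-runs the differential test on pseudo-groups
drawn without replacement from the cohort, size-matched to the true groups,
and reports the observed-over-expected ratio of significant region counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TMMResult:
    factors: pd.Series  # per-sample scale factor, geometric mean 1
    lib_size: pd.Series
    log_cpm: pd.DataFrame  # log2((count + 0.5) / (lib * factor) * 1e6)


@dataclass
class ResamplingNull:
    n_iterations: int
    null_counts: np.ndarray  # significant-region count per iteration
    observed: int
    oe_ratio: float


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    a_cutoff: float = -1e10,
) -> float:
    """Scale factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = 0.5 * (np.log2(obs / lib_obs) + np.log2(ref / lib_ref))
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_normalize(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> TMMResult:
    """TMM scale factors and the log2 normalised matrix."""
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    x = counts.to_numpy(dtype=float)
    f75 = np.quantile(x, 0.75, axis=0) / lib.to_numpy()
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = x[:, ref_idx]
    lib_ref = lib.iloc[ref_idx]
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], ref, lib.iloc[j], lib_ref, trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    factors = pd.Series(factors, index=counts.columns, name="tmm_factor")
    eff = lib * factors
    log_cpm = np.log2((counts + 0.5).div(eff, axis=1) * 1e6)
    return TMMResult(factors=factors, lib_size=lib, log_cpm=log_cpm)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # zero-variance-in-both rows: equal means are a clean null (p = 1)
    nan = ~np.isfinite(p)
    if nan.any():
        diff = b.mean(axis=1) - a.mean(axis=1)
        p[nan] = np.where(diff[nan] == 0, 1.0, 0.0)
    return p


def differential_accessibility(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    logfc_cut: float = 0.7,
    fdr_cut: float = 0.05,
    method: str = "welch",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-region differential test of group B over group A.

    ``log_fc = mean(B) - mean(A)`` on the log2-normalised scale; a region is
    called ``up_in_B``/``up_in_A`` only when both ``|log_fc| > logfc_cut`` and
    ``fdr < fdr_cut``.  ``method='permutation'`` replaces the Welch p-value
    with a label-permutation p-value of the mean difference.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    log_fc = b.mean(axis=1) - a.mean(axis=1)
    mean_log = np.hstack([a, b]).mean(axis=1)
    if method == "welch":
        p = _welch_p(a, b)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.hstack([a, b])
        n_a = a.shape[1]
        obs = np.abs(log_fc)
        exceed = np.zeros_like(obs)
        for _ in range(n_perm):
            idx = rng.permutation(pooled.shape[1])
            pa = pooled[:, idx[:n_a]]
            pb = pooled[:, idx[n_a:]]
            exceed += np.abs(pb.mean(axis=1) - pa.mean(axis=1)) >= obs
        p = (1.0 + exceed) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    fdr = multipletests(p, method="fdr_bh")[1]
    call = np.full(len(log_fc), "ns", dtype=object)
    sig = fdr < fdr_cut
    call[sig & (log_fc > logfc_cut)] = "up_in_B"
    call[sig & (log_fc < -logfc_cut)] = "up_in_A"
    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "mean_log": mean_log,
            "p_value": p,
            "fdr": fdr,
            "call": call,
        },
        index=norm.index,
    )


def resampling_expected(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    n_iter: int = 100,
    seed: int = 0,
    logfc_cut: float = 0.7,
    fdr_cut: float = 0.05,
) -> ResamplingNull:
    """Expected-by-chance differential counts from cohort resampling.

    Each iteration draws disjoint pseudo-groups of the true group sizes from
    the whole cohort without replacement and re-runs the differential test;
    ``oe_ratio`` compares the true-label count with the null mean.
    """
    n_a, n_b = len(group_a), len(group_b)
    cols = list(norm.columns)
    if n_a + n_b > len(cols):
        raise ValueError("group sizes exceed cohort")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    observed = int(
        (
            differential_accessibility(
                norm, group_a, group_b, logfc_cut=logfc_cut, fdr_cut=fdr_cut
            )["call"]
            != "ns"
        ).sum()
    )
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        pick = rng.choice(len(cols), size=n_a + n_b, replace=False)
        pa = [cols[j] for j in pick[:n_a]]
        pb = [cols[j] for j in pick[n_a:]]
        res = differential_accessibility(
            norm, pa, pb, logfc_cut=logfc_cut, fdr_cut=fdr_cut
        )
        null_counts[i] = int((res["call"] != "ns").sum())
    # floor the null total at one count so the ratio stays finite when no
    # null iteration reaches significance (then a lower bound on enrichment)
    oe = float(observed * n_iter / max(1, int(null_counts.sum())))
    return ResamplingNull(
        n_iterations=n_iter, null_counts=null_counts, observed=observed, oe_ratio=oe
    )
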