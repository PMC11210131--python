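"""Dynamic-CRE selection, clustering into C1-C4, and chromatin module scores.

Selection keeps master regions that (a) are highly penetrant across the
disease-stage samples, (b) are poorly detected in healthy samples, and (c)
change their stage-median clonality strongly across disease stages.  The
retained regions are clustered on row-z-scaled log2(TMM) accessibility with
Ward/Euclidean hierarchical clustering cut at k=4 (clusters C1..C4) and k=2
(the two major clades).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .clonality_penetrance import invert_ci


@dataclass
class SelectionConfig:
    """Thresholds of the dynamic-CRE funnel.

    min_pi_disease: minimum number of disease-stage samples detecting the
    region.  max_healthy_ci_fraction: maximum fraction of healthy samples in
    which the region is detected (CI > 0).  min_ci_delta: minimum range of the
    per-stage median clonality, in CI bins, measured by default on the
    inverted (activity-increasing) CI scale so that healthy-silent but
    disease-active regions register a large change.
    """

    min_pi_disease: int = 15
    max_healthy_ci_fraction: float = 1.0 / 3.0
    min_ci_delta: float = 20.0
    use_inverted_ci: bool = True

    def __post_init__(self) -> None:
        if self.min_pi_disease < 0:
            raise ValueError("min_pi_disease must be >= 0")
        if not 0 <= self.max_healthy_ci_fraction <= 1:
            raise ValueError("max_healthy_ci_fraction must be in [0, 1]")
        if not 0 <= self.min_ci_delta <= 100:
            raise ValueError("min_ci_delta must be in [0, 100]")


def select_dynamic_cres(
    ci: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    config: SelectionConfig = SelectionConfig(),
) -> pd.Index:
    """Region ids passing the penetrance / healthy-silence / dynamics rules."""
    for name, cols in groups.items():
        missing = set(cols) - set(ci.columns)
        if missing:
            raise ValueError(f"group {name!r} has samples outside the CI matrix: {sorted(missing)}")
    if "healthy" not in groups:
        raise ValueError("groups must include a 'healthy' stage")
    presence = ci > 0
    disease_cols = [c for name, cols in groups.items() if name != "healthy" for c in cols]
    pi_disease = presence[disease_cols].sum(axis=1)
    healthy_frac = presence[list(groups["healthy"])].mean(axis=1)
    scale = invert_ci(ci) if config.use_inverted_ci else ci
    stage_medians = pd.DataFrame(
        {name: scale[list(cols)].median(axis=1) for name, cols in groups.items()}
    )
    delta = stage_medians.max(axis=1) - stage_medians.min(axis=1)
    keep = (
        (pi_disease >= config.min_pi_disease)
        & (healthy_frac <= config.max_healthy_ci_fraction)
        & (delta >= config.min_ci_delta)
    )
    return pd.Index(sorted(ci.index[keep]))


def zscale_rows(mat: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Row z-scaling (mean 0, sd 1); constant rows dropped with a warning."""
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        if drop_constant:
            warnings.warn(
                f"dropping {int(const.sum())} constant row(s) before z-scaling",
                stacklevel=2,
            )
            mat, mu, sd = mat[~const], mu[~const], sd[~const]
        else:
            sd = sd.replace(0, 1.0)
    return mat.sub(mu, axis=0).div(sd, axis=0)


def cluster_cres(
    norm: pd.DataFrame,
    k: int = 4,
    order_by: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ward/Euclidean hierarchical clustering of z-scaled rows.

    The tree is cut at ``k`` clusters and at 2 clades.  Cluster names C1..Ck
    are assigned deterministically: the clade whose clusters have the highest
    mean z-score over the ``order_by`` sample columns (default: all columns)
    is clade 1, and within a clade clusters are numbered by that mean,
    descending.  With ``order_by`` set to the disease-active samples this
    makes C1/C2 the disease-active clusters, mirroring the heatmap convention.
    """
    z = zscale_rows(norm)
    if len(z) < k:
        raise ValueError(f"need at least {k} non-constant regions, got {len(z)}")
    link = linkage(z.to_numpy(), method="ward")
    raw_k = fcluster(link, t=k, criterion="maxclust")
    raw_2 = fcluster(link, t=2, criterion="maxclust")
    cols = list(order_by) if order_by is not None else list(z.columns)
    zsub = z[cols]
    labels = np.unique(raw_k)
    cluster_mean = {lab: float(zsub[raw_k == lab].to_numpy().mean()) for lab in labels}
    cluster_clade = {lab: int(raw_2[raw_k == lab][0]) for lab in labels}
    clade_score = {
        clade: max(cluster_mean[lab] for lab in labels if cluster_clade[lab] == clade)
        for clade in np.unique(raw_2)
    }
    clade_order = sorted(clade_score, key=lambda c: -clade_score[c])
    name_of: dict[int, str] = {}
    clade_rank: dict[int, int] = {}
    nxt = 1
    for rank, clade in enumerate(clade_order, start=1):
        members = sorted(
            (lab for lab in labels if cluster_clade[lab] == clade),
            key=lambda lab: -cluster_mean[lab],
        )
        for lab in members:
            name_of[lab] = f"C{nxt}"
            clade_rank[lab] = rank
            nxt += 1
    return pd.DataFrame(
        {
            "cluster": [name_of[lab] for lab in raw_k],
            "clade": [clade_rank[lab] for lab in raw_k],
        },
        index=z.index,
    )


def chromatin_module_score(
    region_set: Sequence[str],
    matrix: pd.DataFrame,
    background: bool = True,
    n_background: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Per-unit (sample or cell) module score of a region set.

    Accessibility is z-scored within each unit (across the regions of the
    matrix), then averaged over the region set and, by default, reduced by
    the mean over a size-matched background set drawn once (seeded) from the
    complement.  Per-unit z-scoring makes the score invariant to adding a
    constant to a unit's column; constant columns z-score to 0, so an
    all-constant matrix scores 0 everywhere.
    """
    region_set = list(region_set)
    if len(region_set) == 0:
        raise ValueError("empty region set")
    missing = set(region_set) - set(matrix.index)
    if missing:
        raise ValueError(f"region(s) not in matrix: {sorted(missing)[:5]}")
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0).replace(0, 1.0)
    z = matrix.sub(mu, axis=1).div(sd, axis=1)
    score = z.loc[region_set].mean(axis=0)
    if background:
        complement = matrix.index.difference(region_set)
        n_bg = min(n_background or len(region_set), len(complement))
        if n_bg > 0:
            rng = np.random.default_rng(seed)
            bg = rng.choice(np.asarray(complement), size=n_bg, replace=False)
            score = score - z.loc[bg].mean(axis=0)
    return score
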