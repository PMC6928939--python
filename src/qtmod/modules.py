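"""ICV normalization, structure correlation, module clustering and traits.

Head size is a nuisance scale factor for every structure volume. It is
removed by the residual adjustment

    ROI_norm_i = ROI_raw_i - eps_i * (ICV_raw - ICV_mean)

where eps_i is the OLS slope of the structure's raw volume on ICV fitted
in the normal-control group only (the volume/ICV relationship is taken
as the physiological one, which need not hold in patients), and
ICV_mean is the mean ICV over ALL samples. Normalized volumes are then
correlated across samples (Pearson), structures are agglomerated by
complete linkage on the dissimilarity 1 - |r|, the tree is cut into k
modules, and each module's trait is the per-sample sum of its member
volumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ModulePartition, PhenotypeTable

__all__ = [
    "NormalizationModel",
    "fit_normalization",
    "normalize",
    "structure_correlation",
    "cluster_modules",
    "module_traits",
    "group_summary",
]


class NormalizationModel:
    """Fitted ICV-adjustment parameters: per-phenotype slope + grand mean ICV."""

    def __init__(self, icv_mean: float, eps: pd.Series):
        if not np.isfinite(eps).all():
            raise ValueError("non-finite normalization slopes")
        self.icv_mean = float(icv_mean)
        self.eps = eps.astype(float)

    def to_dict(self) -> dict:
        return {"icv_mean": self.icv_mean, "eps": self.eps.to_dict()}


def fit_normalization(P: PhenotypeTable) -> NormalizationModel:
    """Fit eps_i on NC rows; ICV_mean over all samples.

    eps_i is the simple-regression slope cov(ICV, ROI_i)/var(ICV)
    computed on normal controls. Requires >= 3 NC samples with ICV
    variance > 0.
    """
    nc = P.data[P.data["diagnosis"] == "NC"]
    if len(nc) < 3:
        raise ValueError("normalization needs at least 3 NC samples")
    icv_nc = nc["icv"].to_numpy(dtype=float)
    var = icv_nc.var()
    if var <= 0:
        raise ValueError("ICV variance among NC samples is zero; slope undefined")
    centred = icv_nc - icv_nc.mean()
    vols = nc[P.roi_columns].to_numpy(dtype=float)
    slopes = centred @ (vols - vols.mean(axis=0)) / (var * len(nc))
    return NormalizationModel(
        icv_mean=float(P.data["icv"].mean()),
        eps=pd.Series(slopes, index=P.roi_columns),
    )


def normalize(P: PhenotypeTable, M: NormalizationModel) -> pd.DataFrame:
    """Apply the residual adjustment to every sample and phenotype."""
    missing = [c for c in P.roi_columns if c not in M.eps.index]
    if missing:
        raise ValueError(f"model lacks slopes for phenotypes: {missing[:5]}")
    offset = (P.data["icv"].to_numpy(dtype=float) - M.icv_mean)[:, None]
    vols = P.data[P.roi_columns].to_numpy(dtype=float)
    normed = vols - offset * M.eps[P.roi_columns].to_numpy()
    return pd.DataFrame(normed, index=P.data.index, columns=P.roi_columns)


def structure_correlation(norm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of normalized volumes across samples."""
    if len(norm) < 3:
        raise ValueError("correlation needs at least 3 samples")
    sd = norm.std(ddof=0)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance phenotype(s): {list(dead.index)[:5]}")
    return norm.corr()


def _complete_linkage(D: np.ndarray) -> tuple[list[set[int]], list[float], list[tuple]]:
    """Naive O(n^3) complete-linkage agglomeration with deterministic ties.

    At each step the pair of clusters with the smallest maximum pairwise
    dissimilarity merges; ties break on the smallest (i, j) cluster-index
    pair in the current cluster list. Returns the final single cluster's
    history: cluster sets after each merge, merge heights, merge pairs.
    """
    n = D.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    # inter-cluster distance matrix, complete linkage
    dist = D.copy().astype(float)
    np.fill_diagonal(dist, np.inf)
    heights: list[float] = []
    merges: list[tuple] = []
    active = list(range(n))
    cd = {(a, b): dist[a, b] for a in range(n) for b in range(a + 1, n)}

    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    next_id = n
    while len(active) > 1:
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = cd[(min(a, b), max(a, b))]
                if d < best_d - 1e-15:
                    best_d = d
                    best = (ai, bi)
        ai, bi = best
        a, b = active[ai], active[bi]
        merged = members[a] | members[b]
        members[next_id] = merged
        heights.append(best_d)
        merges.append((a, b))
        active = [c for c in active if c not in (a, b)] + [next_id]
        for c in active[:-1]:
            d = max(
                cd[(min(a, c), max(a, c))],
                cd[(min(b, c), max(b, c))],
            )
            cd[(min(c, next_id), max(c, next_id))] = d
        next_id += 1
    return [members[i] for i in range(next_id)], heights, merges


def cluster_modules(
    C: pd.DataFrame, k: int = 5, distance: str = "abs-corr"
) -> ModulePartition:
    """Cut the complete-linkage tree of 1 - |r| into exactly k modules.

    ``distance`` is ``"abs-corr"`` (d = 1 - |r|; ventricular volumes
    anti-correlate with tissue volumes, and magnitude is what groups
    structures) or ``"corr"`` (d = 1 - r). Modules are renumbered 1..k
    in order of first appearance along the phenotype list.
    """
    n = len(C)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    r = C.to_numpy(dtype=float)
    if distance == "abs-corr":
        D = 1.0 - np.abs(r)
    elif distance == "corr":
        D = 1.0 - r
    else:
        raise ValueError("distance must be 'abs-corr' or 'corr'")
    np.fill_diagonal(D, 0.0)

    _, heights, merge_pairs = _complete_linkage(D)
    # cutting after n-k merges leaves exactly k clusters
    n_merge = n - k
    cluster_sets: dict[int, set[int]] = {i: {i} for i in range(n)}
    active = set(range(n))
    next_id = n
    for step in range(n_merge):
        a, b = merge_pairs[step]
        cluster_sets[next_id] = cluster_sets[a] | cluster_sets[b]
        active -= {a, b}
        active.add(next_id)
        next_id += 1

    labels = np.empty(n, dtype=int)
    # order clusters by smallest member index for stable module ids
    for mod, cid in enumerate(
        sorted(active, key=lambda c: min(cluster_sets[c])), start=1
    ):
        for i in cluster_sets[cid]:
            labels[i] = mod
    assignment = {p: int(labels[i]) for i, p in enumerate(C.columns)}
    return ModulePartition(assignment=assignment, k=k, heights=heights[:n_merge])


def module_traits(
    partition: ModulePartition, norm: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample module volume: sum of member normalized volumes.

    Columns are module ids 1..k; index matches ``norm``.
    """
    uncovered = [p for p in norm.columns if p not in partition.assignment]
    if uncovered:
        raise ValueError(f"partition does not cover phenotypes: {uncovered[:5]}")
    out = {}
    for m in range(1, partition.k + 1):
        mem = [p for p in norm.columns if partition.assignment[p] == m]
        out[m] = norm[mem].sum(axis=1)
    return pd.DataFrame(out)


def group_summary(P: PhenotypeTable) -> pd.DataFrame:
    """AD-vs-NC demographics: n, mean +/- sd and Welch t-test p-values.

    Summarizes every continuous clinical column present (age, education,
    MMSE, CDR-SB) plus group counts and the sex split.
    """
    groups = {g: P.data[P.data["diagnosis"] == g] for g in ("AD", "NC")}
    for g, df in groups.items():
        if len(df) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    rows = []
    rows.append(
        {
            "variable": "n",
            "AD": float(len(groups["AD"])),
            "AD_sd": np.nan,
            "NC": float(len(groups["NC"])),
            "NC_sd": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "variable": "n_female",
            "AD": float((groups["AD"]["sex"] == 0).sum()),
            "AD_sd": np.nan,
            "NC": float((groups["NC"]["sex"] == 0).sum()),
            "NC_sd": np.nan,
            "p": np.nan,
        }
    )
    for col in ("age", "education", "MMSE", "CDRSB"):
        if col not in P.data.columns:
            continue
        a = groups["AD"][col].astype(float)
        b = groups["NC"][col].astype(float)
        if a.var() == 0 and b.var() == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "variable": col,
                "AD": a.mean(),
                "AD_sd": a.std(ddof=1),
                "NC": b.mean(),
                "NC_sd": b.std(ddof=1),
                "p": p,
            }
        )
    return pd.DataFrame(rows)
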