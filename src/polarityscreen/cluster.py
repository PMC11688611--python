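"""Phenotype-profile clustering of screen hits.

Each gene's profile is its Z score on the five morphology parameters in
each of the three replicate screens (a 15-column vector); the control
treatments (non-targeting siRNA, talin-1, poly-L-lysine reference) are
collapsed to one averaged row per treatment so they act as phenotype
anchors in the map. Profiles are clustered hierarchically with average
linkage (Euclidean distance by default, correlation distance optional)
and the dendrogram leaves are rearranged by optimal leaf ordering —
the tree-consistent permutation minimizing the summed dissimilarity of
adjacent leaves — before export as an ordered matrix, a Newick tree and
a heatmap.

Missing entries (a gene dropping a screen to QC) are handled with
pairwise-complete distances rescaled by sqrt(n_total / n_shared); rows
with fewer than half their columns present are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .morphometry import PARAMETERS
from .synth import CONTROL_TREATMENTS


class ClusterError(ValueError):
    pass


def profile_columns(n_screens: int = 3) -> list[str]:
    return [f"{p}|S{s}" for p in PARAMETERS for s in range(1, n_screens + 1)]


def build_profile_matrix(
    ztable: pd.DataFrame,
    genes: list[str] | None = None,
    *,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Assemble the gene x (parameter x screen) score matrix.

    One row per gene (optionally restricted to ``genes``, e.g. the hit
    list); control treatments contribute one averaged row each per
    the wells they occupy, averaged per screen. Entries a gene is missing
    are NaN. Genes absent from every screen are dropped with a warning.
    """
    screens = sorted(ztable["screen_id"].unique())
    cols = profile_columns(len(screens))
    scr_index = {s: i + 1 for i, s in enumerate(screens)}

    lib = ztable[~ztable["is_control"] & ztable["qc_pass"]]
    if genes is not None:
        requested = set(genes)
        present = set(lib["gene"].unique())
        absent = sorted(requested - present)
        if absent:
            warnings.warn(
                f"{len(absent)} requested gene(s) absent from all screens "
                f"dropped, e.g. {absent[:3]}",
                stacklevel=2,
            )
        lib = lib[lib["gene"].isin(requested)]

    def pivot(df: pd.DataFrame) -> pd.DataFrame:
        out = df.pivot_table(
            index="gene", columns=["parameter", "screen_id"], values="z",
            aggfunc="mean",
        )
        out.columns = [
            f"{p}|S{scr_index[s]}" for p, s in out.columns.to_flat_index()
        ]
        return out.reindex(columns=cols)

    mat = pivot(lib)
    if include_controls:
        ctrl = ztable[ztable["is_control"] & ztable["qc_pass"]]
        if not ctrl.empty:
            ctrl_mat = pivot(ctrl)
            ctrl_mat = ctrl_mat.reindex(
                [t for t in CONTROL_TREATMENTS if t in ctrl_mat.index]
            )
            mat = pd.concat([mat, ctrl_mat])
    mat = mat.sort_index()  # lexicographic rows: deterministic tie-breaks
    mat.index.name = "row"
    return mat


def _pairwise_complete(values: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distances over shared non-missing columns, rescaled by
    sqrt(n_total/n_shared) so sparser overlaps are not underweighted."""
    n, m = values.shape
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(values[i]) & ~np.isnan(values[j])
            ns = int(shared.sum())
            if ns == 0:
                raise ClusterError(
                    f"rows {i} and {j} share no observed columns"
                )
            a, b = values[i, shared], values[j, shared]
            if metric == "euclidean":
                d = float(np.linalg.norm(a - b)) * np.sqrt(m / ns)
            elif metric == "correlation":
                d = float(pdist(np.stack([a, b]), metric="correlation")[0])
            else:
                raise ClusterError(f"unknown metric {metric!r}")
            out[k] = d
            k += 1
    return out


def _optimal_leaf_order(Z: np.ndarray, D: np.ndarray) -> list[int]:
    """Exact optimal leaf ordering by dynamic programming.

    Among all 2^(n-1) leaf orders consistent with the tree (flipping any
    internal node), find one minimizing the summed distance between
    adjacent leaves. For each node the table ``M[l, r]`` holds the best
    cost of laying out its subtree with leftmost leaf ``l`` and rightmost
    leaf ``r``; children tables combine through a min-plus product over
    the boundary pair at the junction.
    """
    n = D.shape[0]
    if n == 1:
        return [0]
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    back: dict[int, tuple] = {}
    for k in range(Z.shape[0]):
        u = n + k
        v, w = int(Z[k, 0]), int(Z[k, 1])
        A, B = leaves[v], leaves[w]
        D_AB = D[np.ix_(A, B)]
        # T[l, j] = min_m M_v[l, m] + D[A_m, B_j]
        S1 = M[v][:, :, None] + D_AB[None, :, :]
        T = S1.min(axis=1)
        arg_m = S1.argmin(axis=1)
        # M_u[l, r] = min_j T[l, j] + M_w[j, r]
        S2 = T[:, :, None] + M[w][None, :, :]
        M_AB = S2.min(axis=1)
        arg_j = S2.argmin(axis=1)
        size = len(A) + len(B)
        Mu = np.full((size, size), np.inf)
        Mu[: len(A), len(A):] = M_AB
        Mu[len(A):, : len(A)] = M_AB.T
        leaves[u] = A + B
        M[u] = Mu
        back[u] = (v, w, arg_m, arg_j, len(A))

    def unwind(u: int, li: int, ri: int) -> list[int]:
        # positions li, ri index leaves[u]; returns global leaf ids
        if u < n:
            return [u]
        v, w, arg_m, arg_j, nA = back[u]
        if li >= nA:  # boundary pair given right-to-left: reverse
            if ri >= nA:
                raise ClusterError("inconsistent leaf-order backtrack")
            return unwind(u, ri, li)[::-1]
        j = int(arg_j[li, ri - nA])
        m = int(arg_m[li, j])
        return unwind(v, li, m) + unwind(w, j, ri - nA)

    root = n + Z.shape[0] - 1
    li, ri = np.unravel_index(int(np.argmin(M[root])), M[root].shape)
    return unwind(root, int(li), int(ri))


def cluster_profiles(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
) -> dict:
    """Average-linkage hierarchy with optimal leaf ordering.

    Rows are sorted lexicographically by label before linking so the tree
    is independent of input row order. Rows with fewer than 50% observed
    columns are excluded. Returns a dict with the scipy linkage matrix
    ``Z``, the row ``labels``, the ``leaf_order`` (labels in display
    order, optimal-leaf-ordered), and the condensed distances ``dist``.
    """
    matrix = matrix.sort_index()
    frac = matrix.notna().mean(axis=1)
    dropped = matrix.index[frac < 0.5].tolist()
    if dropped:
        warnings.warn(
            f"{len(dropped)} row(s) with <50% observed columns excluded",
            stacklevel=2,
        )
        matrix = matrix.loc[frac >= 0.5]
    if len(matrix) < 2:
        raise ClusterError("need at least 2 rows to cluster")
    values = matrix.to_numpy(float)
    if np.isnan(values).any():
        dist = _pairwise_complete(values, metric)
    else:
        dist = pdist(values, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    leaves = _optimal_leaf_order(Z, squareform(dist))
    labels = matrix.index.tolist()
    return {
        "Z": Z,
        "labels": labels,
        "leaf_order": [labels[i] for i in leaves],
        "dist": dist,
        "matrix": matrix,
    }


def two_cluster_cut(clustering: dict) -> pd.Series:
    """Assign each row to one of the two top-level clusters."""
    flat = hierarchy.fcluster(clustering["Z"], t=2, criterion="maxclust")
    return pd.Series(flat, index=clustering["labels"], name="cluster")


def adjacent_leaf_cost(clustering: dict, order: list[str] | None = None) -> float:
    """Sum of pairwise distances between adjacent leaves in an ordering."""
    labels = clustering["labels"]
    order = clustering["leaf_order"] if order is None else order
    idx = {lab: i for i, lab in enumerate(labels)}
    D = squareform(clustering["dist"])
    return float(
        sum(D[idx[a], idx[b]] for a, b in zip(order[:-1], order[1:]))
    )


def to_newick(clustering: dict) -> str:
    """Serialize the dendrogram as Newick with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(clustering["Z"], clustering["labels"])
    return str(tree)


def export_heatmap(
    clustering: dict,
    out_prefix,
    *,
    render: bool = True,
) -> pd.DataFrame:
    """Write the leaf-ordered matrix (CSV), leaf order, Newick tree and
    (optionally) a heatmap figure; returns the ordered matrix."""
    from pathlib import Path

    matrix: pd.DataFrame = clustering["matrix"]
    order = clustering["leaf_order"]
    if set(order) != set(matrix.index):
        raise ClusterError("dendrogram leaves do not match matrix rows")
    ordered = matrix.loc[order]
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered.to_csv(f"{prefix}_matrix.csv")
    Path(f"{prefix}_leaf_order.txt").write_text("\n".join(order) + "\n")
    Path(f"{prefix}.nwk").write_text(to_newick(clustering))
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(8, max(3, 0.18 * len(ordered))), constrained_layout=True
        )
        vmax = np.nanmax(np.abs(ordered.to_numpy())) or 1.0
        im = ax.imshow(
            ordered.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
            aspect="auto", interpolation="nearest",
        )
        ax.set_xticks(range(ordered.shape[1]))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(ordered.shape[0]))
        ax.set_yticklabels(ordered.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="Z score")
        fig.savefig(f"{prefix}_heatmap.png", dpi=150)
        plt.close(fig)
    return ordered
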