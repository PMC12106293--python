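"""Protein-metabolite co-expression module discovery.

Concatenated log2-normalized omics are clustered with Ward's method (the
ward.D2 convention) on a 1 - Spearman dissimilarity; modules come from a
dynamic hybrid tree cut with a minimum size and an assignment stage for
outlying leaves, close modules are merged on eigengene correlation, and
module eigengenes are correlated against the clinical traits with BH
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata

from .matrix import AbundanceMatrix
from .stats import benjamini_hochberg

log = logging.getLogger(__name__)

UNASSIGNED = 0


@dataclass
class IntegratedMatrix:
    samples: list[str]
    features: list[str]
    values: np.ndarray           # samples x features
    omic_of_feature: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)


@dataclass
class ModuleSet:
    features: list[str]
    assignment: np.ndarray        # module labels; 0 = unassigned
    eigengenes: pd.DataFrame      # modules x samples
    merge_history: list = field(default_factory=list)
    module_sizes: dict = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [f for f, a in zip(self.features, self.assignment) if a == label]


def concatenate_omics(p: AbundanceMatrix, m: AbundanceMatrix) -> IntegratedMatrix:
    """Column-wise concatenation over the common sample set; feature ids are
    prefixed with the omic tag to guarantee uniqueness."""
    for mat in (p, m):
        if mat.mask.any():
            raise ValueError(f"{mat.omic} matrix still has missing cells")
        if mat.scale != "log2":
            raise ValueError(f"{mat.omic} matrix is not log2-scaled")
    common = [s for s in p.samples if s in set(m.samples)]
    if not common:
        raise ValueError("no samples passed preprocessing in both omics")
    pi = [p.samples.index(s) for s in common]
    mi = [m.samples.index(s) for s in common]
    values = np.hstack([p.values[pi], m.values[mi]])
    features = [f"protein:{f}" for f in p.features] + [f"metabolite:{f}" for f in m.features]
    omics = ["protein"] * p.n_features + ["metabolite"] * m.n_features
    return IntegratedMatrix(samples=common, features=features, values=values,
                            omic_of_feature=omics)


def spearman_dissimilarity(x: IntegratedMatrix | np.ndarray) -> np.ndarray:
    """d(a, b) = 1 - Spearman rho(a, b) over features (columns)."""
    vals = x.values if isinstance(x, IntegratedMatrix) else np.asarray(x, dtype=float)
    if vals.shape[0] < 3:
        raise ValueError("need >= 3 samples for rank correlation")
    sd = vals.std(axis=0)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        name = x.features[j] if isinstance(x, IntegratedMatrix) else str(j)
        raise ValueError(f"constant feature {name!r}")
    ranks = np.apply_along_axis(rankdata, 0, vals)
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def ward_cluster(d: np.ndarray) -> np.ndarray:
    """Agglomerative clustering under the Ward variance-minimizing update on
    squared dissimilarities with square-rooted heights (ward.D2); returns a
    scipy linkage matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    return linkage(squareform(d, checks=False), method="ward")


# ---------------------------------------------------------------------------
def _subtree_leaves(Z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf sets for every internal node (indexed n .. 2n-2)."""
    leaves: list = [None] * (2 * n - 1)
    for i in range(n):
        leaves[i] = np.array([i])
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        leaves[n + k] = np.concatenate([leaves[a], leaves[b]])
    return leaves


def _mean_within(d: np.ndarray, idx: np.ndarray) -> float:
    if idx.size < 2:
        return 0.0
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (idx.size * (idx.size - 1)))


def dynamic_tree_cut(Z: np.ndarray, d: np.ndarray, min_cluster_size: int = 45,
                     gap: float = 0.1, max_core_scatter: float = 0.8) -> np.ndarray:
    """Dynamic hybrid cut of a dendrogram.

    Stage 1 walks the tree from the root: a node is split into its children
    when both parts are meaningfully separated (mean cross-dissimilarity
    exceeds the mean within-part dissimilarity by more than ``gap``) and at
    least one child can still host a module; branches of size
    >= ``min_cluster_size`` whose mean internal dissimilarity is below
    ``max_core_scatter`` become modules.  Stage 2 assigns every leftover
    leaf to the nearest module when its average dissimilarity to that module
    is below ``max_core_scatter``; otherwise it stays unassigned (label 0).
    """
    n = d.shape[0]
    if min_cluster_size > n // 2:
        raise ValueError(f"min_cluster_size {min_cluster_size} > n/2 ({n // 2})")
    leaves = _subtree_leaves(Z, n)
    root = 2 * n - 2

    branches: list[np.ndarray] = []
    strays: list[np.ndarray] = []

    def visit(node: int) -> None:
        idx = leaves[node]
        if idx.size < min_cluster_size or node < n:
            strays.append(idx)
            return
        k = node - n
        left, right = int(Z[k, 0]), int(Z[k, 1])
        li, ri = leaves[left], leaves[right]
        mw_node = _mean_within(d, idx)
        mw_l, mw_r = _mean_within(d, li), _mean_within(d, ri)
        cross = float(d[np.ix_(li, ri)].mean())
        separated = cross - 0.5 * (mw_l + mw_r) > gap
        # a node looser than any admissible module core keeps being split;
        # a tight node is split only across a real separation
        descend = (mw_node > max_core_scatter) or separated
        if descend and max(li.size, ri.size) >= min_cluster_size:
            visit(left)
            visit(right)
        elif mw_node <= max_core_scatter:
            branches.append(idx)
        else:
            strays.append(idx)

    visit(root)

    assignment = np.zeros(n, dtype=int)
    label = 0
    for idx in branches:
        if _mean_within(d, idx) <= max_core_scatter:
            label += 1
            assignment[idx] = label
        else:
            strays.append(idx)

    # assignment stage for unassigned leaves
    if label > 0:
        members = {lab: np.flatnonzero(assignment == lab) for lab in range(1, label + 1)}
        pool = np.concatenate(strays) if strays else np.array([], dtype=int)
        for i in pool:
            dists = {lab: d[i, mem].mean() for lab, mem in members.items()}
            best = min(dists, key=dists.get)
            if dists[best] < max_core_scatter:
                assignment[i] = best
    return assignment


def module_eigengene(x: IntegratedMatrix | np.ndarray, members) -> np.ndarray:
    """First right singular vector of the member z-score matrix, unit norm,
    sign-aligned with the member-averaged z-profile."""
    if isinstance(x, IntegratedMatrix):
        cols = [x.features.index(f) if isinstance(f, str) else f for f in members]
        vals = x.values[:, cols]
    else:
        vals = np.asarray(x, dtype=float)[:, list(members)]
    if vals.shape[1] < 2:
        raise ValueError("a module needs >= 2 member features")
    sd = vals.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant feature in module")
    z = (vals - vals.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = u[:, 0]
    mean_profile = z.mean(axis=1)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


def _eigengene_frame(x: IntegratedMatrix, assignment: np.ndarray) -> pd.DataFrame:
    labels = sorted(set(assignment) - {UNASSIGNED})
    rows = {f"M{lab}": module_eigengene(x.values, np.flatnonzero(assignment == lab))
            for lab in labels}
    return pd.DataFrame(rows, index=x.samples).T


def merge_close_modules(x: IntegratedMatrix, assignment: np.ndarray,
                        cut_height: float = 0.4, max_iter: int = 10) -> ModuleSet:
    """Iteratively merge modules whose eigengenes cluster below ``cut_height``
    under average linkage on 1 - Pearson correlation."""
    assignment = assignment.copy()
    history: list = []
    for it in range(max_iter):
        labels = sorted(set(assignment) - {UNASSIGNED})
        if len(labels) <= 1:
            break
        eig = np.vstack([module_eigengene(x.values, np.flatnonzero(assignment == lab))
                         for lab in labels])
        diss = 1.0 - np.corrcoef(eig)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, 2.0)
        Z = average(squareform(diss, checks=False))
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(labels):
            break
        for g in sorted(set(groups)):
            merged = [labels[i] for i in np.flatnonzero(groups == g)]
            if len(merged) > 1:
                history.append({"iteration": it, "merged": merged, "into": merged[0]})
                for lab in merged[1:]:
                    assignment[assignment == lab] = merged[0]
    else:
        log.info("module merging stopped at max_iter=%d", max_iter)

    # relabel 1..k in decreasing size order
    labels = sorted(set(assignment) - {UNASSIGNED},
                    key=lambda lab: -(assignment == lab).sum())
    relabel = {old: new + 1 for new, old in enumerate(labels)}
    relabel[UNASSIGNED] = UNASSIGNED
    assignment = np.array([relabel[a] for a in assignment])
    eigengenes = _eigengene_frame(x, assignment)
    sizes = {f"M{lab}": int((assignment == lab).sum())
             for lab in sorted(set(assignment) - {UNASSIGNED})}
    return ModuleSet(features=list(x.features), assignment=assignment,
                     eigengenes=eigengenes, merge_history=history,
                     module_sizes=sizes)


def module_trait_association(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             alpha: float = 0.05,
                             fdr_family: str = "grid") -> pd.DataFrame:
    """Pearson correlation of every module eigengene with every trait
    (pairwise-complete), BH-adjusted either over the whole grid or per trait.

    ``traits`` is samples x traits and should include ``AMS_degree``.
    Returns a long table (module, trait, n, r, p, p_adj, significant).
    """
    if fdr_family not in ("grid", "per-trait"):
        raise ValueError("fdr_family must be 'grid' or 'per-trait'")
    common = [s for s in eigengenes.columns if s in traits.index]
    rows = []
    for module in eigengenes.index:
        e = eigengenes.loc[module, common].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits.loc[common, trait].to_numpy(dtype=float)
            ok = ~np.isnan(tv) & ~np.isnan(e)
            n = int(ok.sum())
            if n < 4 or np.std(tv[ok]) == 0 or np.std(e[ok]) == 0:
                rows.append((module, trait, n, np.nan, np.nan))
                continue
            r, p = pearsonr(e[ok], tv[ok])
            rows.append((module, trait, n, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["module", "trait", "n", "r", "p"])
    if fdr_family == "grid":
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    else:
        out["p_adj"] = np.nan
        for trait in out["trait"].unique():
            sel = out["trait"] == trait
            out.loc[sel, "p_adj"] = benjamini_hochberg(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def ams_modules(association: pd.DataFrame, degree_trait: str = "AMS_degree") -> list[str]:
    sel = association[(association["trait"] == degree_trait) & association["significant"]]
    return sorted(sel["module"].tolist())
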