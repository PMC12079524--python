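"""Module detection: average-linkage dendrogram, dynamic hybrid tree cut,
module eigengenes, eigengene-based module merging, hub statistics,
module--trait correlation, and the hyperparameter robustness sweep.

Genes are clustered on the TOM dissimilarity 1 - TOM with average linkage.
The dynamic hybrid cut decomposes the dendrogram into branches using a
deep-split-controlled gap criterion, discards branches smaller than the
minimum module size or looser than a core-scatter bound, and (optionally)
rescues unassigned genes with a PAM-like closest-module stage. Modules
whose eigengenes are highly correlated are merged. The unassigned class is
label 0 ("grey") and is excluded from all downstream inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .netcore import AdjacencyMatrix

logger = logging.getLogger("coexmod")

W_ALL_UNASSIGNED = "W301"   # min module size >= number of genes
W_CONSTANT_GENE = "W302"    # constant gene dropped from an eigengene
W_CONSTANT_TRAIT = "W303"   # constant trait: correlation undefined
W_SMALL_MODULE = "W304"     # top-k hub request larger than the module

# Deep-split sensitivity constants, one (max core scatter, min gap) pair per
# deep_split level 0..4. Larger deep split tolerates looser cores and
# smaller gaps, hence splits more aggressively. Gaps and scatters are
# fractions of the (cut height - reference height) range; the reference
# height is the 5th percentile of merge heights.
DEEP_SPLIT_MAX_CORE_SCATTER = (0.64, 0.7175, 0.795, 0.8725, 0.95)
DEEP_SPLIT_MIN_GAP = tuple(0.75 * (1.0 - c) for c in DEEP_SPLIT_MAX_CORE_SCATTER)
REF_HEIGHT_QUANTILE = 0.05

# Module color names assigned by descending size (reporting convention);
# label 0 is always "grey".
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes (scipy linkage encoding)."""

    merges: np.ndarray  # (n-1, 4): child a, child b, height, leaf count
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.merges)


@dataclass
class CutParams:
    """Dynamic hybrid cut settings: deep split 0..4, minimum module size,
    eigengene merge threshold, PAM rescue stage, and the static cut height
    as a fraction of the maximum merge height."""

    deep_split: int = 2
    min_module_size: int = 30
    merge_threshold: float = 0.15
    pam_stage: bool = True
    cut_height: float = 0.99
    pam_respects_dendro: bool = True

    def __post_init__(self) -> None:
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be in 0..4")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")
        if not (0 < self.merge_threshold < 1):
            raise ValueError("merge_threshold must be in (0, 1)")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")


@dataclass
class ModulePartition:
    """Per-gene module labels; 0 means unassigned ("grey"). Labels are
    contiguous 1..Q ordered by descending module size."""

    gene_ids: list[str]
    labels: np.ndarray
    n_stage1_branches: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.gene_ids):
            raise ValueError("labels and gene_ids length mismatch")

    @property
    def module_labels(self) -> list[int]:
        return sorted(l for l in np.unique(self.labels) if l != 0)

    @property
    def sizes(self) -> dict[int, int]:
        return {int(l): int((self.labels == l).sum()) for l in self.module_labels}

    @property
    def colors(self) -> dict[int, str]:
        out = {0: "grey"}
        for i, l in enumerate(self.module_labels):
            out[l] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{l}"
        return out

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def relabeled_by_size(self) -> "ModulePartition":
        order = sorted(self.module_labels,
                       key=lambda l: (-int((self.labels == l).sum()), l))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[0] = 0
        new = np.array([mapping[int(l)] for l in self.labels], dtype=int)
        return ModulePartition(self.gene_ids, new, self.n_stage1_branches)

    def to_frame(self) -> pd.DataFrame:
        colors = self.colors
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "label": self.labels,
            "color": [colors[int(l)] for l in self.labels],
        }).set_index("gene_id")


@dataclass
class EigengeneMatrix:
    """Per-module eigengenes: first principal component of the module's
    standardized expression, unit variance across samples, oriented so the
    mean member correlation is non-negative."""

    values: pd.DataFrame          # samples x modules, columns "ME<label>"
    pve: dict[int, float]         # proportion of member variance explained
    module_labels: list[int]

    def vector(self, label: int) -> np.ndarray:
        return self.values[f"ME{label}"].to_numpy()


@dataclass
class ModuleTraitResult:
    correlation: pd.DataFrame  # modules x traits, Pearson R
    p_values: pd.DataFrame
    samples_used: list[str]


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------

def linkage_tree(d: np.ndarray) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric dissimilarity matrix."""
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dissimilarity matrix contains non-finite values")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    condensed = squareform((d + d.T) / 2.0, checks=False)
    merges = linkage(condensed, method="average")
    return Dendrogram(merges, d.shape[0])


# ---------------------------------------------------------------------------
# Dynamic hybrid cut
# ---------------------------------------------------------------------------

def _subtree_leaves(merges: np.ndarray, n: int) -> list[list[int]]:
    """Leaf lists per node (leaves 0..n-1, internal nodes n..2n-2)."""
    leaves: list[list[int]] = [[i] for i in range(n)]
    for a, b, _h, _c in merges:
        leaves.append(leaves[int(a)] + leaves[int(b)])
    return leaves


def cut_dynamic_hybrid(tree: Dendrogram, d: np.ndarray,
                       params: CutParams) -> ModulePartition:
    """Two-stage adaptive dendrogram cut.

    Stage 1: cut statically at ``cut_height x max merge height``; decompose
    each component into branches wherever the merge gap (merge height minus
    the taller child's top height) reaches the deep-split-dependent minimum
    gap; accept a branch as a module when it has at least
    ``min_module_size`` members and its mean internal merge height (core
    scatter) is below the deep-split-dependent bound. Stage 2 (PAM): each
    unassigned gene joins the module with the smallest average
    dissimilarity to members, provided that average is below the gene's
    average dissimilarity to non-members; with ``pam_respects_dendro``
    (default) only modules in the gene's own static-cut component are
    eligible. Deterministic for fixed inputs.
    """
    n = tree.n_leaves
    gene_ids = [f"g{i}" for i in range(n)]
    merges = tree.merges
    heights = merges[:, 2]
    if params.min_module_size >= n:
        logger.warning("%s min_module_size=%d >= n_genes=%d: all unassigned",
                       W_ALL_UNASSIGNED, params.min_module_size, n)
        return ModulePartition(gene_ids, np.zeros(n, dtype=int), 0)

    h_max = float(heights.max())
    h_cut = params.cut_height * h_max
    h_ref = float(np.quantile(heights, REF_HEIGHT_QUANTILE))
    h_ref = min(h_ref, h_cut)
    h_range = max(h_cut - h_ref, 1e-12)
    min_gap = DEEP_SPLIT_MIN_GAP[params.deep_split] * h_range
    max_scatter = h_ref + DEEP_SPLIT_MAX_CORE_SCATTER[params.deep_split] * h_range

    node_height = np.concatenate([np.zeros(n), heights])
    leaves = _subtree_leaves(merges, n)

    # internal merge heights per node, for core scatter
    merge_hs: list[list[float]] = [[] for _ in range(n)]
    for j, (a, b, h, _c) in enumerate(merges):
        merge_hs.append(merge_hs[int(a)] + merge_hs[int(b)] + [float(h)])

    # --- static cut: component roots are maximal nodes with height <= h_cut
    roots: list[int] = []

    def find_roots(node: int) -> None:
        if node < n or node_height[node] <= h_cut:
            roots.append(node)
            return
        find_roots(int(merges[node - n, 0]))
        find_roots(int(merges[node - n, 1]))

    find_roots(2 * n - 2)

    # mean pairwise dissimilarity (core scatter) per subtree node, built
    # incrementally: each gene pair contributes once, at its join node
    pair_sum = np.zeros(2 * n - 1)
    mean_d = np.zeros(2 * n - 1)
    for j, (a, b, _h, _c) in enumerate(merges):
        a, b = int(a), int(b)
        cross = float(d[np.ix_(leaves[a], leaves[b])].sum())
        node = n + j
        pair_sum[node] = pair_sum[a] + pair_sum[b] + cross
        sz = len(leaves[node])
        mean_d[node] = pair_sum[node] / (sz * (sz - 1) / 2.0)

    # --- gap decomposition within each component (iterative post-order).
    # Branches are whole subtrees, so each is identified by its node id.
    # A merge is a split point when each side is large enough to be a
    # module on its own and the sides are separated by at least the
    # deep-split gap; smaller side-branches are absorbed.
    def decompose(root: int) -> list[int]:
        result: dict[int, list[int]] = {}
        stack: list[tuple[int, bool]] = [(root, False)]
        while stack:
            node, done = stack.pop()
            if node < n:
                result[node] = [node]
                continue
            a, b = int(merges[node - n, 0]), int(merges[node - n, 1])
            if not done:
                stack.append((node, True))
                stack.append((a, False))
                stack.append((b, False))
                continue
            ba, bb = result.pop(a), result.pop(b)
            # gap: how far the joining height (the mean cross-branch
            # dissimilarity under average linkage) stands above the looser
            # side's internal scatter; measured against the scatter rather
            # than the top merge height so that absorbed stragglers cannot
            # blur a genuine between-module separation
            gap = node_height[node] - max(mean_d[a], mean_d[b])
            sizes_ok = (len(leaves[a]) >= params.min_module_size
                        and len(leaves[b]) >= params.min_module_size)
            if (gap >= min_gap and sizes_ok) or len(ba) > 1 or len(bb) > 1:
                result[node] = ba + bb
            else:
                result[node] = [node]
        return result[root]

    labels = np.zeros(n, dtype=int)
    component_of = np.full(n, -1, dtype=int)
    next_label = 1
    n_branches = 0
    for comp_idx, root in enumerate(roots):
        for leaf in leaves[root]:
            component_of[leaf] = comp_idx
        # acceptance: a branch becomes a module when it is large enough and
        # its core scatter (mean pairwise dissimilarity, i.e. the average
        # internal merge height under average linkage) is within the
        # deep-split bound; a too-loose branch is force-split at its top
        # merge and its pieces re-examined.
        pending = decompose(root)
        n_branches += len(pending)
        while pending:
            node = pending.pop()
            if len(leaves[node]) < max(2, params.min_module_size):
                continue
            if mean_d[node] <= max_scatter:
                for leaf in leaves[node]:
                    labels[leaf] = next_label
                next_label += 1
            elif node >= n:
                pending.append(int(merges[node - n, 0]))
                pending.append(int(merges[node - n, 1]))

    # --- stage 2: PAM-like rescue of unassigned genes
    if params.pam_stage and next_label > 1:
        module_lists = {l: np.flatnonzero(labels == l) for l in range(1, next_label)}
        module_comp = {l: int(component_of[idx[0]]) for l, idx in module_lists.items()}
        unassigned = np.flatnonzero(labels == 0)
        new_labels = labels.copy()
        for g in unassigned:
            best_label, best_avg = 0, np.inf
            for l, idx in module_lists.items():
                if params.pam_respects_dendro and module_comp[l] != component_of[g]:
                    continue
                avg = float(d[g, idx].mean())
                if avg < best_avg - 1e-15:
                    best_avg, best_label = avg, l
            if best_label == 0:
                continue
            non_members = np.flatnonzero(labels != best_label)
            non_members = non_members[non_members != g]
            if len(non_members) and best_avg < float(d[g, non_members].mean()):
                new_labels[g] = best_label
        labels = new_labels

    part = ModulePartition(gene_ids, labels, n_branches)
    return part.relabeled_by_size()


def _mean_offdiag(d: np.ndarray, idx: list[int]) -> float:
    sub = d[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def module_eigengenes(expr, part: ModulePartition) -> EigengeneMatrix:
    """First-principal-component summary profile per module.

    Member rows are standardized (mean 0, sd 1); the first right singular
    vector across samples is scaled to unit variance and oriented so the
    mean correlation with member genes is non-negative. pve is the first
    squared singular value over the total.
    """
    vals = expr.values
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    cols: dict[str, np.ndarray] = {}
    pve: dict[int, float] = {}
    labels_present: list[int] = []
    for label in part.module_labels:
        members = [g for g in part.members(label) if g in gene_index]
        rows = vals[[gene_index[g] for g in members]]
        sd = rows.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("%s module %d: dropped %d constant gene(s) from "
                           "its eigengene", W_CONSTANT_GENE, label,
                           int((~keep).sum()))
        rows = rows[keep]
        if rows.shape[0] < 2:
            raise ValueError(f"module {label} has < 2 usable genes")
        z = (rows - rows.mean(axis=1, keepdims=True)) / \
            rows.std(axis=1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        # orient: mean member correlation >= 0
        cors = _rowwise_pearson(z, me)
        if cors.mean() < 0:
            me = -me
        cols[f"ME{label}"] = me
        pve[label] = float(s[0] ** 2 / (s ** 2).sum())
        labels_present.append(label)
    df = pd.DataFrame(cols, index=expr.sample_ids)
    return EigengeneMatrix(df, pve, labels_present)


def _rowwise_pearson(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, rc @ vc / np.where(denom > 0, denom, 1.0), np.nan)


# ---------------------------------------------------------------------------
# Module merging
# ---------------------------------------------------------------------------

def merge_close_modules(expr, part: ModulePartition, me: EigengeneMatrix,
                        h: float) -> tuple[ModulePartition, EigengeneMatrix]:
    """Iteratively merge the closest module pair while their eigengene
    dissimilarity 1 - cor(ME_a, ME_b) is below ``h``, recomputing
    eigengenes after each merge. Labels are finally reassigned by size."""
    if not (0 < h < 1):
        raise ValueError("merge threshold must be in (0, 1)")
    labels = part.labels.copy()
    current = ModulePartition(part.gene_ids, labels, part.n_stage1_branches)
    me_now = me
    while True:
        mods = current.module_labels
        if len(mods) < 2:
            break
        mecors = np.corrcoef(np.column_stack([me_now.vector(l) for l in mods]),
                             rowvar=False)
        diss = 1.0 - mecors
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= h:
            break
        keep, drop = sorted((mods[i], mods[j]))
        labels = current.labels.copy()
        labels[labels == drop] = keep
        current = ModulePartition(current.gene_ids, labels,
                                  current.n_stage1_branches)
        me_now = module_eigengenes(expr, current)
    current = current.relabeled_by_size()
    me_now = module_eigengenes(expr, current)
    return current, me_now


# ---------------------------------------------------------------------------
# Hub statistics
# ---------------------------------------------------------------------------

def gene_module_stats(expr, part: ModulePartition, adj: AdjacencyMatrix,
                      me: EigengeneMatrix) -> pd.DataFrame:
    """Per-gene hub statistics: intramodular connectivity kIM (sum of
    within-module adjacency), module membership kME (correlation with the
    own-module eigengene), and hub_rank (1 = most connected; ties broken by
    descending kME, then gene ID). Unassigned genes get missing values."""
    gene_index = {g: i for i, g in enumerate(adj.gene_ids)}
    expr_index = {g: i for i, g in enumerate(expr.gene_ids)}
    vals = expr.values
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    out = pd.DataFrame(index=pd.Index(part.gene_ids, name="gene_id"))
    out["module"] = part.labels
    out["kIM"] = np.nan
    out["kME"] = np.nan
    out["hub_rank"] = np.nan
    for label in part.module_labels:
        members = part.members(label)
        idx = [gene_index[g] for g in members]
        sub = a[np.ix_(idx, idx)]
        kim = sub.sum(axis=1)
        rows = vals[[expr_index[g] for g in members]]
        kme = _rowwise_pearson(rows, me.vector(label))
        rank_df = pd.DataFrame({"kIM": kim, "kME": kme, "gene": members})
        rank_df = rank_df.sort_values(["kIM", "kME", "gene"],
                                      ascending=[False, False, True],
                                      kind="stable")
        ranks = pd.Series(np.arange(1, len(members) + 1),
                          index=rank_df["gene"]).reindex(members)
        out.loc[members, "kIM"] = kim
        out.loc[members, "kME"] = kme
        out.loc[members, "hub_rank"] = ranks.to_numpy()
    return out


def top_hub_genes(stats: pd.DataFrame, label: int, k: int = 120) -> list[str]:
    """Top-k hub genes of a module by hub_rank; the whole module (with a
    warning) when it has fewer than k genes."""
    sub = stats[stats["module"] == label].sort_values("hub_rank")
    if len(sub) < k:
        logger.warning("%s module %d has %d genes < top-k request %d",
                       W_SMALL_MODULE, label, len(sub), k)
    return list(sub.index[:k])


# ---------------------------------------------------------------------------
# Module-trait correlation
# ---------------------------------------------------------------------------

def module_trait_correlation(me: EigengeneMatrix, traits,
                             sample_subset: list[str] | None = None
                             ) -> ModuleTraitResult:
    """Pearson correlation of each module eigengene with each trait over
    the stated sample subset, with asymptotic p-values."""
    tdf = traits.data if hasattr(traits, "data") else traits
    samples = [s for s in me.values.index if s in tdf.index]
    if sample_subset is not None:
        subset = set(sample_subset)
        samples = [s for s in samples if s in subset]
    if len(samples) < 4:
        raise ValueError(f"need >= 4 overlapping samples, got {len(samples)}")
    mes = me.values.loc[samples]
    tt = tdf.loc[samples]
    rmat = pd.DataFrame(index=me.values.columns, columns=tt.columns, dtype=float)
    pmat = rmat.copy()
    n = len(samples)
    for trait in tt.columns:
        y = tt[trait].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            logger.warning("%s trait %r is constant; correlations undefined",
                           W_CONSTANT_TRAIT, trait)
            continue
        for col in mes.columns:
            x = mes[col].to_numpy()
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 4:
                continue
            r, p = stats.pearsonr(x[mask], y[mask])
            rmat.loc[col, trait] = r
            pmat.loc[col, trait] = p
    return ModuleTraitResult(rmat, pmat, samples)


# ---------------------------------------------------------------------------
# Hyperparameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepReport:
    grid: list[CutParams]
    partitions: list[ModulePartition]
    ari_matrix: np.ndarray
    module_counts: list[int]
    module_sizes: list[dict[int, int]] = field(default_factory=list)

    @property
    def median_pairwise_ari(self) -> float:
        n = len(self.grid)
        vals = [self.ari_matrix[i, j] for i in range(n) for j in range(i + 1, n)]
        return float(np.median(vals)) if vals else 1.0

    def to_json(self) -> str:
        return json.dumps({
            "grid": [vars(p) for p in self.grid],
            "module_counts": self.module_counts,
            "module_sizes": [{str(k): v for k, v in s.items()}
                             for s in self.module_sizes],
            "ari_matrix": self.ari_matrix.tolist(),
            "median_pairwise_ari": self.median_pairwise_ari,
        }, indent=2)


def default_sweep_grid() -> list[CutParams]:
    """Default robustness grid over deep split, minimum module size,
    merge threshold and the PAM stage."""
    grid = []
    for ds in (2, 3):
        for m in (20, 30):
            for h in (0.1, 0.25):
                for pam in (True, False):
                    grid.append(CutParams(deep_split=ds, min_module_size=m,
                                          merge_threshold=h, pam_stage=pam))
    return grid


def hyperparameter_sweep(expr, dissim: np.ndarray,
                         grid: list[CutParams] | None = None,
                         tree: Dendrogram | None = None) -> SweepReport:
    """Run cut + merge at every grid point and report all pairwise adjusted
    Rand indices between the resulting partitions (unassigned genes form
    their own class), plus per-point module counts and sizes."""
    if grid is None:
        grid = default_sweep_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if tree is None:
        tree = linkage_tree(dissim)
    partitions = []
    for params in grid:
        part = cut_dynamic_hybrid(tree, dissim, params)
        part = ModulePartition(expr.gene_ids, part.labels, part.n_stage1_branches)
        if part.module_labels:
            me = module_eigengenes(expr, part)
            part, _ = merge_close_modules(expr, part, me, params.merge_threshold)
        partitions.append(part)
    n = len(grid)
    ari = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ari[i, j] = ari[j, i] = adjusted_rand_score(
                partitions[i].labels, partitions[j].labels)
    return SweepReport(grid, partitions, ari,
                       [len(p.module_labels) for p in partitions],
                       [p.sizes for p in partitions])
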