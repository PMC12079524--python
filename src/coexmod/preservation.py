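"""Permutation module preservation across datasets and differential
co-expression across conditions.

Preservation asks whether a module defined in a reference dataset keeps
its density and connectivity pattern in an independent test dataset.
Seven statistics are computed per module on the gene overlap:

  density   s1 meanCor  mean intramodule correlation (test data)
            s2 meanAdj  mean intramodule adjacency (test data)
            s3 pve      eigengene variance explained (test data)
            s4 meanKME  mean |kME| against the test-data eigengene
  pattern   s5 cor.kIM  correlation of intramodular connectivity, ref vs test
            s6 cor.kME  correlation of module memberships, ref vs test
            s7 cor.cor  correlation of vectorized intramodule correlations

The null replaces the module with random gene sets of equal size drawn
without replacement from the analyzed gene universe; Z = (obs - mean_null)
/ sd_null per statistic, one-sided add-one permutation p, and
Zsummary = median(median(Z1..Z4), median(Z5..Z7)). A module is called
significantly preserved when all seven permutation p-values are < 0.05.

Differential co-expression compares intramodule correlation matrices
between two conditions: D_q = mean |cor^A - cor^B| over member pairs, with
a condition-label permutation null (label swaps within donor pairs when a
pair ID is supplied). A module is "preserved across conditions" when its
permutation p exceeds 0.05.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .netcore import NetworkConfig, _transform_rows

logger = logging.getLogger("coexmod")

W_MODULE_SKIPPED = "W401"   # module overlap too small for preservation
W_DEGENERATE_Z = "W402"     # permutation sd 0: Z undefined

STAT_NAMES = ("meanCor", "meanAdj", "pve", "meanKME",
              "cor.kIM", "cor.kME", "cor.cor")
DENSITY_STATS = STAT_NAMES[:4]
PATTERN_STATS = STAT_NAMES[4:]


def _cor_sub(vals: np.ndarray, method: str) -> np.ndarray:
    """Correlation of complete-data rows (fast path for small submatrices)."""
    t = _transform_rows(vals, method)
    t = np.nan_to_num(t, nan=0.0)
    norms = np.sqrt((t ** 2).sum(axis=1))
    norms = np.where(norms > 0, norms, 1.0)
    c = (t / norms[:, None]) @ (t / norms[:, None]).T
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def _adj_sub(cor: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    if cfg.network_type == "unsigned":
        a = np.abs(cor) ** cfg.beta
    else:
        a = ((1.0 + cor) / 2.0) ** cfg.beta
    np.fill_diagonal(a, 1.0)
    return a


def _eigengene(vals: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of standardized rows: (unit-variance score, pve)."""
    sd = vals.std(axis=1, ddof=1)
    vals = vals[sd > 0]
    z = (vals - vals.mean(axis=1, keepdims=True)) / \
        vals.std(axis=1, ddof=1, keepdims=True)
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    cors = _row_cor(z, me)
    if cors.mean() < 0:
        me = -me
    return me, float(s[0] ** 2 / (s ** 2).sum())


def _row_cor(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, rc @ vc / np.where(denom > 0, denom, 1.0), 0.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _offdiag_mean(m: np.ndarray) -> float:
    q = m.shape[0]
    return float((m.sum() - np.trace(m)) / (q * (q - 1)))


def _robust_row_cor(rows: np.ndarray, v: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row with a vector, using the network's robust
    transform (kME against an eigengene must not be wrecked by single
    contaminated cells)."""
    rt = _transform_rows(rows, method)
    vt = _transform_rows(v[None, :], method)[0]
    denom = np.sqrt((rt ** 2).sum(axis=1) * (vt ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, rt @ vt / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(out, -1.0, 1.0)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation: the cross-dataset comparison of connectivity
    vectors, whose soft-threshold power amplifies sampling noise into
    heavy tails that a product-moment correlation cannot survive."""
    return _pearson(rankdata(x), rankdata(y))


def _seven_stats(ref_vals: np.ndarray, test_vals: np.ndarray,
                 cfg: NetworkConfig) -> np.ndarray:
    """The seven preservation statistics for one gene set."""
    cor_ref = _cor_sub(ref_vals, cfg.method)
    cor_test = _cor_sub(test_vals, cfg.method)
    adj_ref = _adj_sub(cor_ref, cfg)
    adj_test = _adj_sub(cor_test, cfg)
    me_test, pve_test = _eigengene(test_vals)
    me_ref, _ = _eigengene(ref_vals)
    kme_test = _robust_row_cor(test_vals, me_test, cfg.method)
    kme_ref = _robust_row_cor(ref_vals, me_ref, cfg.method)
    kim_ref = adj_ref.sum(axis=1) - 1.0
    kim_test = adj_test.sum(axis=1) - 1.0
    iu = np.triu_indices(cor_ref.shape[0], k=1)
    return np.array([
        _offdiag_mean(cor_test),
        _offdiag_mean(adj_test),
        pve_test,
        float(np.abs(kme_test).mean()),
        _spearman(kim_ref, kim_test),
        _spearman(kme_ref, kme_test),
        _pearson(cor_ref[iu], cor_test[iu]),
    ])


def preservation_stats(ref_expr, test_expr, part, cfg: NetworkConfig,
                       min_overlap_frac: float = 0.5) -> pd.DataFrame:
    """Observed seven statistics per module (rows) on the ref/test overlap.

    Modules with fewer than 3 overlapping genes, or with less than
    ``min_overlap_frac`` of their genes present in the test data, are
    skipped with a warning.
    """
    ref_index = {g: i for i, g in enumerate(ref_expr.gene_ids)}
    test_index = {g: i for i, g in enumerate(test_expr.gene_ids)}
    rows = {}
    for label in part.module_labels:
        members = part.members(label)
        overlap = [g for g in members if g in ref_index and g in test_index]
        if len(overlap) < 3 or len(overlap) < min_overlap_frac * len(members):
            logger.warning("%s module %d skipped: overlap %d of %d genes",
                           W_MODULE_SKIPPED, label, len(overlap), len(members))
            continue
        rv = ref_expr.values[[ref_index[g] for g in overlap]]
        tv = test_expr.values[[test_index[g] for g in overlap]]
        rows[label] = _seven_stats(rv, tv, cfg)
    df = pd.DataFrame(rows, index=STAT_NAMES).T
    df.index.name = "module"
    return df


@dataclass
class PreservationReport:
    """Observed statistics, permutation Z and p, and composite Zsummary per
    module; fully determined by (inputs, seed)."""

    observed: pd.DataFrame       # modules x 7 statistics
    z_scores: pd.DataFrame
    p_values: pd.DataFrame
    z_summary: pd.Series
    preserved: pd.Series         # all seven p < 0.05
    module_sizes: dict[int, int]
    n_permutations: int
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "modules": {
                str(m): {
                    "size": self.module_sizes[m],
                    "observed": self.observed.loc[m].round(10).to_dict(),
                    "z": {k: (None if pd.isna(v) else round(v, 10))
                          for k, v in self.z_scores.loc[m].items()},
                    "p": self.p_values.loc[m].round(10).to_dict(),
                    "z_summary": (None if pd.isna(self.z_summary[m])
                                  else round(float(self.z_summary[m]), 10)),
                    "preserved": bool(self.preserved[m]),
                } for m in self.observed.index
            },
        }, indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        obs = self.observed.add_prefix("obs_")
        z = self.z_scores.add_prefix("Z_")
        p = self.p_values.add_prefix("p_")
        out = pd.concat([obs, z, p], axis=1)
        out["Zsummary"] = self.z_summary
        out["preserved"] = self.preserved
        return out


def permutation_preservation(ref_expr, test_expr, part, cfg: NetworkConfig,
                             n_perm: int = 200, seed: int = 0,
                             min_overlap_frac: float = 0.5
                             ) -> PreservationReport:
    """Permutation test of the seven preservation statistics.

    The null draws, per permutation and module, a random gene set of the
    module's size without replacement from the genes shared by both
    datasets, and evaluates all seven statistics on it. One-sided add-one
    p-values: p = (1 + #{null >= obs}) / (n_perm + 1).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = np.random.default_rng(seed)
    ref_index = {g: i for i, g in enumerate(ref_expr.gene_ids)}
    test_index = {g: i for i, g in enumerate(test_expr.gene_ids)}
    universe = [g for g in ref_expr.gene_ids if g in test_index]
    uni_ref = np.array([ref_index[g] for g in universe])
    uni_test = np.array([test_index[g] for g in universe])
    ref_vals_all = ref_expr.values
    test_vals_all = test_expr.values

    observed = preservation_stats(ref_expr, test_expr, part, cfg,
                                  min_overlap_frac)
    modules = list(observed.index)
    sizes = {}
    for label in modules:
        members = part.members(label)
        sizes[label] = len([g for g in members
                            if g in ref_index and g in test_index])

    null = {m: np.empty((n_perm, 7)) for m in modules}
    for p_i in range(n_perm):
        for m in modules:
            pick = rng.choice(len(universe), size=sizes[m], replace=False)
            rv = ref_vals_all[uni_ref[pick]]
            tv = test_vals_all[uni_test[pick]]
            null[m][p_i] = _seven_stats(rv, tv, cfg)

    z = pd.DataFrame(index=modules, columns=STAT_NAMES, dtype=float)
    pvals = pd.DataFrame(index=modules, columns=STAT_NAMES, dtype=float)
    for m in modules:
        obs = observed.loc[m].to_numpy(dtype=float)
        nl = null[m]
        mean = np.nanmean(nl, axis=0)
        sd = np.nanstd(nl, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zr = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0),
                          np.nan)
        if (sd == 0).any():
            logger.warning("%s module %s: %d statistic(s) with zero "
                           "permutation sd", W_DEGENERATE_Z, m,
                           int((sd == 0).sum()))
        z.loc[m] = zr
        with np.errstate(invalid="ignore"):
            ge = np.nansum(nl >= obs[None, :], axis=0)
        pvals.loc[m] = (1.0 + ge) / (n_perm + 1.0)
    z_summary = pd.Series({
        m: float(np.median([np.nanmedian(z.loc[m, list(DENSITY_STATS)]),
                            np.nanmedian(z.loc[m, list(PATTERN_STATS)])]))
        for m in modules})
    preserved = (pvals < 0.05).all(axis=1)
    return PreservationReport(observed, z, pvals, z_summary, preserved,
                              sizes, n_perm, seed)


# ---------------------------------------------------------------------------
# Differential co-expression
# ---------------------------------------------------------------------------

@dataclass
class DiffCoexReport:
    """Module-level D_q = mean |cor^A - cor^B| with permutation p, and
    per-gene mean absolute correlation change d_i with permutation p."""

    module_stats: pd.DataFrame  # module, size, D, p, preserved_across_conditions
    gene_stats: pd.DataFrame    # gene, module, d, p
    n_permutations: int
    seed: int
    paired: bool

    def to_json(self) -> str:
        return json.dumps({
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "paired": self.paired,
            "modules": self.module_stats.round(10).to_dict(orient="index"),
        }, indent=2, sort_keys=True, default=str)


def _diffcoex_stats(vals: np.ndarray, cond: np.ndarray,
                    method: str) -> tuple[float, np.ndarray]:
    ca = _cor_sub(vals[:, cond == 0], method)
    cb = _cor_sub(vals[:, cond == 1], method)
    diff = np.abs(ca - cb)
    np.fill_diagonal(diff, 0.0)
    q = diff.shape[0]
    d_genes = diff.sum(axis=1) / (q - 1)
    iu = np.triu_indices(q, k=1)
    return float(diff[iu].mean()), d_genes


def diff_coexpression(expr, traits, part, n_perm: int = 200, seed: int = 0,
                      condition: str = "condition", pair: str | None = "pair",
                      method: str = "bicor") -> DiffCoexReport:
    """Condition-label permutation test of intramodule correlation change.

    With a pair column, permutations swap the two condition labels within
    each donor pair (sign-flip null); without one, condition labels are
    permuted freely. Both conditions need at least 4 samples.
    """
    tdf = traits.data if hasattr(traits, "data") else traits
    samples = [s for s in expr.sample_ids if s in tdf.index]
    cond = tdf.loc[samples, condition].to_numpy(dtype=int)
    if (cond == 0).sum() < 4 or (cond == 1).sum() < 4:
        raise ValueError("both conditions need >= 4 samples")
    paired = pair is not None
    if paired:
        if pair not in tdf.columns:
            raise ValueError(f"pair column {pair!r} not in trait table")
        pair_ids = tdf.loc[samples, pair].to_numpy()
        order = {}
        for i, pid in enumerate(pair_ids):
            order.setdefault(pid, []).append(i)
        if any(len(v) != 2 or {cond[v[0]], cond[v[1]]} != {0, 1}
               for v in order.values()):
            raise ValueError("pair-aware permutation needs exactly one sample "
                             "of each condition per pair")
        pair_groups = list(order.values())
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    sample_pos = [expr.sample_ids.index(s) for s in samples]
    vals_all = expr.values[:, sample_pos]

    module_rows = []
    gene_rows = []
    for label in part.module_labels:
        members = [g for g in part.members(label) if g in gene_index]
        if len(members) < 3:
            continue
        vals = vals_all[[gene_index[g] for g in members]]
        d_obs, d_genes = _diffcoex_stats(vals, cond, method)
        ge_mod = 0
        ge_gene = np.zeros(len(members))
        for _ in range(n_perm):
            if paired:
                c = cond.copy()
                flips = rng.random(len(pair_groups)) < 0.5
                for flip, grp in zip(flips, pair_groups):
                    if flip:
                        c[grp[0]], c[grp[1]] = c[grp[1]], c[grp[0]]
            else:
                c = rng.permutation(cond)
            d_null, d_genes_null = _diffcoex_stats(vals, c, method)
            ge_mod += d_null >= d_obs
            ge_gene += d_genes_null >= d_genes
        p_mod = (1.0 + ge_mod) / (n_perm + 1.0)
        p_genes = (1.0 + ge_gene) / (n_perm + 1.0)
        module_rows.append({"module": label, "size": len(members),
                            "D": d_obs, "p": p_mod,
                            "preserved_across_conditions": bool(p_mod > 0.05)})
        for g, d_i, p_i in zip(members, d_genes, p_genes):
            gene_rows.append({"gene_id": g, "module": label, "d": d_i,
                              "p": p_i})
    module_stats = pd.DataFrame(module_rows).set_index("module") \
        if module_rows else pd.DataFrame()
    gene_stats = pd.DataFrame(gene_rows).set_index("gene_id") \
        if gene_rows else pd.DataFrame()
    return DiffCoexReport(module_stats, gene_stats, n_perm, seed, paired)
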