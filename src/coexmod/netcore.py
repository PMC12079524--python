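"""Robust correlation, soft-threshold adjacency, scale-free topology fit
and topological overlap.

The network is built on biweight midcorrelation (bicor), a robust
correlation that downweights outliers with Tukey biweights computed from
each vector's median and median absolute deviation:

    u_i = (x_i - med(x)) / (9 * mad(x))
    w_i = (1 - u_i^2)^2 * 1[|u_i| < 1]
    x~_i = (x_i - med(x)) * w_i
    bicor(x, y) = sum(x~ y~) / sqrt(sum(x~^2) * sum(y~^2))

The 9*mad denominator uses the raw median absolute deviation, no
consistency constant. A vector with zero MAD falls back to Pearson
centering (mean-centered, unit weights) for that vector, which is logged.

Similarity |b_ij| (unsigned) or (1+b_ij)/2 (signed) is raised to a soft
threshold power beta; the power is chosen so the connectivity distribution
approximates scale-free topology (log-log fit R^2 above a target,
conventionally 0.8). The topological overlap matrix (TOM) then credits
shared neighbors:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj

and 1 - TOM is the clustering dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("coexmod")

W_ZERO_MAD = "W201"        # zero-MAD vector fell back to Pearson centering
W_FEW_PAIRS = "W202"       # gene pairs below min_pairs set missing
W_CONSTANT_PAIR = "W203"   # constant vector: undefined correlation set to 0
W_MISSING_ADJ = "W204"     # missing correlations mapped to adjacency 0
W_FEW_BINS = "W205"        # fewer distinct k values than requested bins
W_NO_BETA = "W206"         # no candidate beta reached the fit target
W_ISOLATED_TOM = "W207"    # isolated pair with zero TOM denominator


@dataclass
class NetworkConfig:
    """Network construction settings.

    beta is the soft-threshold power (default 8); network_type selects the
    unsigned |b|^beta or signed ((1+b)/2)^beta similarity; min_pairs is the
    minimum number of pairwise-complete observations for a correlation to
    be defined.
    """

    beta: int = 8
    network_type: str = "unsigned"
    method: str = "bicor"
    min_pairs: int = 3

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_pairs < 3:
            raise ValueError("min_pairs must be >= 3")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if self.method not in ("bicor", "pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray                 # symmetric, unit diagonal, in [-1, 1]
    method: str
    n_pairs: np.ndarray | None = None  # pairwise-complete counts
    p_values: np.ndarray | None = None


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, entries in [0, 1]

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum_{j != i} a_ij (diagonal excluded)."""
        a = self.values.copy()
        np.fill_diagonal(a, 0.0)
        return a.sum(axis=1)


@dataclass
class ScaleFreeFit:
    beta: int
    fit: float          # R^2 of the log-log regression (0 when invalid)
    slope: float
    valid: bool         # False when slope >= 0 or the fit is undefined
    mean_k: float
    median_k: float
    max_k: float


@dataclass
class TOMMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def bicor_vector(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two complete vectors (scalar form)."""
    xt = _bicor_transform_1d(np.asarray(x, dtype=float))
    yt = _bicor_transform_1d(np.asarray(y, dtype=float))
    denom = np.sqrt((xt ** 2).sum() * (yt ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((xt * yt).sum() / denom, -1.0, 1.0))


def _bicor_transform_1d(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - x.mean()
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def _transform_rows_complete(vals: np.ndarray, method: str) -> np.ndarray:
    """Vectorized per-gene transform for matrices without missing values."""
    if method == "spearman":
        vals = stats.rankdata(vals, axis=1)
    if method != "bicor":
        return vals - vals.mean(axis=1, keepdims=True)
    med = np.median(vals, axis=1, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=1, keepdims=True)
    zero = (mad == 0).ravel()
    if zero.any():
        logger.warning("%s %d vector(s) with zero MAD fell back to Pearson "
                       "centering", W_ZERO_MAD, int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (vals - med) / (9.0 * np.where(mad == 0, 1.0, mad))
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    out = (vals - med) * w
    if zero.any():
        out[zero] = vals[zero] - vals[zero].mean(axis=1, keepdims=True)
    return out


def _transform_rows(vals: np.ndarray, method: str) -> np.ndarray:
    """Per-gene robust (or plain) transform; NaNs preserved as NaN."""
    if not np.isnan(vals).any():
        return _transform_rows_complete(np.asarray(vals, dtype=float), method)
    out = np.empty_like(vals)
    n_zero_mad = 0
    for i in range(vals.shape[0]):
        row = vals[i]
        mask = ~np.isnan(row)
        x = row[mask]
        if method == "spearman":
            x = stats.rankdata(x)
        if method == "bicor":
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            if mad == 0:
                n_zero_mad += 1
                t = x - x.mean()
            else:
                u = (x - med) / (9.0 * mad)
                w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
                t = (x - med) * w
        else:  # pearson, or spearman on ranks
            t = x - x.mean()
        out[i] = np.nan
        out[i, mask] = t
    if n_zero_mad:
        logger.warning("%s %d vector(s) with zero MAD fell back to Pearson "
                       "centering", W_ZERO_MAD, n_zero_mad)
    return out


def correlation_matrix(expr, method: str = "bicor",
                       min_pairs: int = 3) -> CorrelationMatrix:
    """All-pairs correlation of gene rows with pairwise-complete handling.

    Per-gene transforms (median/MAD weighting for bicor, centering for
    Pearson, rank-centering for Spearman) are computed on each gene's
    observed values; pair sums run over the common support. Pairs with
    fewer than ``min_pairs`` complete observations are set missing. P-values
    come from the asymptotic t distribution,
    t = r * sqrt((n - 2) / (1 - r^2)).
    """
    vals = expr.values if hasattr(expr, "values") else np.asarray(expr, float)
    if hasattr(expr, "gene_ids"):
        gene_ids = expr.gene_ids
    else:
        gene_ids = [f"g{i}" for i in range(vals.shape[0])]
    t = _transform_rows(vals, method)
    mask = (~np.isnan(t)).astype(float)
    t0 = np.nan_to_num(t, nan=0.0)
    num = t0 @ t0.T
    sq = t0 ** 2
    # sum of x~^2 over the pair's common support
    sx = sq @ mask.T
    sy = mask @ sq.T
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(sx * sy)
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    n_const = int(((denom == 0).sum() - 0) // 2)
    if n_const > 0:
        logger.warning("%s %d pair(s) with zero variance set to correlation 0",
                       W_CONSTANT_PAIR, n_const)
    corr = np.clip(corr, -1.0, 1.0)
    n_pairs = mask @ mask.T
    few = n_pairs < min_pairs
    if few.any():
        logger.warning("%s %d pair(s) below min_pairs=%d set missing",
                       W_FEW_PAIRS, int(few.sum() // 2), min_pairs)
        corr = np.where(few, np.nan, corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = corr * np.sqrt((n_pairs - 2) / np.clip(1.0 - corr ** 2, 1e-300, None))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), np.clip(n_pairs - 2, 1, None))
    np.fill_diagonal(pvals, 0.0)
    return CorrelationMatrix(list(gene_ids), corr, method, n_pairs, pvals)


# ---------------------------------------------------------------------------
# Adjacency, scale-free fit, soft-threshold choice
# ---------------------------------------------------------------------------

def adjacency(cor: CorrelationMatrix, cfg: NetworkConfig) -> AdjacencyMatrix:
    """Soft-threshold adjacency: |b|^beta (unsigned) or ((1+b)/2)^beta (signed).

    Missing correlations map to adjacency 0 (counted and logged).
    """
    b = cor.values
    missing = np.isnan(b)
    if missing.any():
        logger.warning("%s %d missing correlation(s) mapped to adjacency 0",
                       W_MISSING_ADJ, int(missing.sum() // 2))
    if cfg.network_type == "unsigned":
        a = np.abs(np.nan_to_num(b, nan=0.0)) ** cfg.beta
    else:
        a = ((1.0 + np.nan_to_num(b, nan=-1.0)) / 2.0) ** cfg.beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(cor.gene_ids, a)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10,
                   beta: int | None = None) -> ScaleFreeFit:
    """Goodness of fit to scale-free topology.

    Bins connectivity k into ``n_bins`` equal-width bins, regresses
    log10(mean frequency) on log10(mean k) over non-empty bins, and reports
    the coefficient of determination. The fit is flagged invalid when the
    regression slope is >= 0 or when k is degenerate.
    """
    k = adj.connectivity
    mean_k = float(k.mean())
    median_k = float(np.median(k))
    max_k = float(k.max())
    b = 0 if beta is None else beta
    if np.ptp(k) == 0:
        return ScaleFreeFit(b, 0.0, np.nan, False, mean_k, median_k, max_k)
    n_distinct = len(np.unique(k))
    if n_distinct < n_bins:
        logger.warning("%s only %d distinct connectivity values for %d bins",
                       W_FEW_BINS, n_distinct, n_bins)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    n = len(k)
    for bin_i in range(n_bins):
        sel = idx == bin_i
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        mk = k[sel].mean()
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(cnt / n))
    if len(xs) < 3:
        return ScaleFreeFit(b, 0.0, np.nan, False, mean_k, median_k, max_k)
    res = stats.linregress(xs, ys)
    fit = float(res.rvalue ** 2)
    valid = bool(res.slope < 0)
    return ScaleFreeFit(b, fit, float(res.slope), valid, mean_k, median_k, max_k)


def pick_soft_threshold(cor: CorrelationMatrix, betas: list[int],
                        cfg: NetworkConfig | None = None,
                        target: float = 0.8,
                        n_bins: int = 10) -> tuple[int, pd.DataFrame]:
    """Choose the smallest beta whose valid scale-free fit reaches ``target``.

    Falls back to the beta of maximum valid fit (with a warning) when no
    candidate reaches the target. The full per-beta fit table is returned
    either way.
    """
    if not betas:
        raise ValueError("empty candidate beta list")
    if sorted(betas) != list(betas):
        raise ValueError("candidate betas must be ascending")
    cfg = cfg or NetworkConfig()
    rows = []
    fits: list[ScaleFreeFit] = []
    for b in betas:
        a = adjacency(cor, NetworkConfig(beta=b, network_type=cfg.network_type,
                                         method=cfg.method, min_pairs=cfg.min_pairs))
        f = scale_free_fit(a, n_bins=n_bins, beta=b)
        fits.append(f)
        rows.append({"beta": b, "fit": f.fit, "slope": f.slope, "valid": f.valid,
                     "mean_k": f.mean_k, "median_k": f.median_k, "max_k": f.max_k})
    table = pd.DataFrame(rows)
    for f in fits:
        if f.valid and f.fit >= target:
            return f.beta, table
    valid_fits = [f for f in fits if f.valid] or fits
    best = max(valid_fits, key=lambda f: f.fit)
    logger.warning("%s no candidate beta reached fit target %.2f; using "
                   "beta=%d (fit %.3f)", W_NO_BETA, target, best.beta, best.fit)
    return best.beta, table


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap matrix of an adjacency (unsigned TOM).

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj; the diagonal is defined as 1. A zero
    denominator (isolated pair) yields TOM_ij = 0 by convention.
    """
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    if np.nanmin(a) < 0 or np.nanmax(a) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    l = a @ a  # l_ii includes self terms, but the diagonal is overwritten
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    zero = denom <= 0
    if zero.any():
        logger.warning("%s %d isolated pair(s) with TOM denominator 0",
                       W_ISOLATED_TOM, int(zero.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, num / np.where(zero, 1.0, denom))
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(adj.gene_ids, t)


# ---------------------------------------------------------------------------
# Matrix persistence (interchange format between pipeline stages)
# ---------------------------------------------------------------------------

def write_symmetric_matrix(gene_ids: list[str], values: np.ndarray,
                           path: str) -> None:
    df = pd.DataFrame(values, index=gene_ids, columns=gene_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_symmetric_matrix(path: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float)
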