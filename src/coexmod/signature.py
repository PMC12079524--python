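"""Rank-based single-sample signature scoring, cross-dataset signature
validation, driver-anchored candidate prioritization, paired
differential-expression confirmation, and hypergeometric
over-representation analysis.

The signature score is a per-sample fractional-rank mean: within each
sample all G genes are ranked ascending (ties averaged), normalized to
[0, 1], averaged over the S signature genes, and min-max standardized by
the score's attainable extremes. Because only within-sample ranks enter,
the score is exactly invariant under any strictly increasing per-sample
transform of expression — robust to location/scale differences between
samples and datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection
from .netcore import bicor_vector

logger = logging.getLogger("coexmod")

W_MISSING_SIG_GENES = "W501"   # signature genes absent from the matrix
W_FEW_ELIGIBLE = "W502"        # fewer eligible candidates than requested N
W_SELECTION_OUTSIDE = "W503"   # selection genes outside the ORA universe
W_DRIVER_IN_MODULE = "W504"    # driver gene excluded from its own module


@dataclass
class SignatureScore:
    name: str
    scores: pd.Series            # per sample, in [0, 1]
    n_genes_used: int
    n_genes_missing: int


def signature_score(expr, signature: list[str],
                    name: str = "signature") -> SignatureScore:
    """Per-sample fractional-rank signature score in [0, 1].

    With G genes and S present signature genes, a sample's raw score is the
    mean normalized rank (r - 1)/(G - 1) over the signature genes; the
    attainable extremes (S - 1)/(2(G - 1)) and 1 - (S - 1)/(2(G - 1))
    rescale it so a signature occupying the top/bottom S ranks scores
    exactly 1/0.
    """
    present = [g for g in dict.fromkeys(signature) if g in set(expr.gene_ids)]
    missing = len(set(signature)) - len(present)
    if not present:
        raise ValueError(f"no signature gene of {name!r} present in the matrix")
    if missing:
        logger.warning("%s signature %r: %d gene(s) absent from the matrix",
                       W_MISSING_SIG_GENES, name, missing)
    G = expr.n_genes
    S = len(present)
    if S == G:
        raise ValueError("signature covers every gene: score is degenerate")
    vals = expr.values
    ranks = stats.rankdata(vals, axis=0)                 # per-sample columns
    norm = (ranks - 1.0) / (G - 1.0)
    idx = [expr.gene_ids.index(g) for g in present]
    raw = norm[idx].mean(axis=0)
    raw_min = (S - 1.0) / (2.0 * (G - 1.0))
    raw_max = 1.0 - raw_min
    sigma = (raw - raw_min) / (raw_max - raw_min)
    sigma = np.clip(sigma, 0.0, 1.0)
    return SignatureScore(name, pd.Series(sigma, index=expr.sample_ids),
                          S, missing)


def validate_signature(expr_validation, hub_signatures: dict[int, list[str]],
                       reference_signature: list[str]) -> pd.DataFrame:
    """Pearson correlation of each module's hub-gene score with a reference
    signature score across validation samples, ranked by R (descending)."""
    if expr_validation.n_samples < 4:
        raise ValueError("need >= 4 validation samples")
    ref = signature_score(expr_validation, reference_signature, "reference")
    rows = []
    for label, genes in hub_signatures.items():
        sc = signature_score(expr_validation, genes, f"module_{label}_hubs")
        if sc.scores.std() == 0 or ref.scores.std() == 0:
            rows.append({"module": label, "R": np.nan, "p": np.nan,
                         "n_genes": sc.n_genes_used})
            continue
        r, p = stats.pearsonr(sc.scores, ref.scores)
        rows.append({"module": label, "R": r, "p": p,
                     "n_genes": sc.n_genes_used})
    out = pd.DataFrame(rows).set_index("module")
    out = out.sort_values("R", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Candidate prioritization
# ---------------------------------------------------------------------------

def rank_candidates(expr, part, stats_df: pd.DataFrame, module: int,
                    driver: str, direction: str = "negative", N: int = 47,
                    alpha: float = 0.05,
                    sample_subset: list[str] | None = None,
                    hub_weight: float = 0.5,
                    method: str = "bicor") -> pd.DataFrame:
    """Driver-anchored candidate table for one module.

    Each module gene is correlated with the driver gene over the stated
    samples (all samples by default), using the same robust correlation as
    the network (bicor; plain Pearson via ``method``); eligibility requires
    the correlation sign to match ``direction`` and raw p < alpha (BH q is
    reported alongside). Eligible genes are sorted by a composite of the
    fractional hub rank (by kIM) and the fractional |r| rank, weighted
    ``hub_weight`` : ``1 - hub_weight``; the top N are flagged. Ineligible
    genes are listed below the eligible block with their reason.
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    if driver not in expr.gene_ids:
        raise ValueError(f"driver gene {driver!r} absent from the matrix")
    members = part.members(module)
    if not members or module == 0:
        raise ValueError(f"module {module} is empty or the unassigned class")
    if driver in members:
        logger.warning("%s driver %r sits inside module %d; excluded from "
                       "candidates", W_DRIVER_IN_MODULE, driver, module)
        members = [g for g in members if g != driver]
    cols = expr.sample_ids if sample_subset is None else \
        [s for s in expr.sample_ids if s in set(sample_subset)]
    if len(cols) < 4:
        raise ValueError("need >= 4 samples for the driver correlation screen")
    sub = expr.data.loc[members, cols].to_numpy(dtype=float)
    dvec = expr.data.loc[driver, cols].to_numpy(dtype=float)
    n_obs = len(cols)
    r = np.empty(len(members))
    for i in range(len(members)):
        r[i] = bicor_vector(sub[i], dvec) if method == "bicor" \
            else float(stats.pearsonr(sub[i], dvec)[0])
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n_obs - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), n_obs - 2)
    q = multipletests(p, method="fdr_bh")[1]
    sign_ok = (r < 0) if direction == "negative" else (r > 0)
    eligible = sign_ok & (p < alpha)

    out = pd.DataFrame({
        "module": module,
        "kIM": stats_df.loc[members, "kIM"].to_numpy(),
        "hub_rank": stats_df.loc[members, "hub_rank"].to_numpy(),
        "r_driver": r, "p": p, "q": q, "eligible": eligible,
    }, index=pd.Index(members, name="gene_id"))
    out["reason"] = np.where(eligible, "",
                             np.where(~sign_ok, "wrong_sign", "p>=alpha"))

    el = out[out["eligible"]].copy()
    if len(el):
        n_el = len(el)
        hub_fr = stats.rankdata(el["hub_rank"]) / n_el          # low rank = hub
        r_fr = stats.rankdata(-np.abs(el["r_driver"])) / n_el   # strong |r| first
        el["composite"] = hub_weight * hub_fr + (1.0 - hub_weight) * r_fr
        el = el.sort_values(["composite", "hub_rank"], kind="stable")
        el["final_rank"] = np.arange(1, n_el + 1)
    inel = out[~out["eligible"]].copy()
    inel["composite"] = np.nan
    inel = inel.sort_values("hub_rank", kind="stable")
    inel["final_rank"] = np.arange(len(el) + 1, len(out) + 1)
    table = pd.concat([el, inel]) if len(el) else inel
    n_top = min(N, int(table["eligible"].sum()))
    if n_top < N:
        logger.warning("%s only %d eligible candidate(s) for top-%d flag",
                       W_FEW_ELIGIBLE, n_top, N)
    table["top_n"] = table["final_rank"] <= n_top
    return table


def paired_de_test(expr, traits, genes: list[str] | None = None,
                   condition: str = "condition",
                   pair: str = "pair") -> pd.DataFrame:
    """Classical paired t-test of case minus control log2 expression.

    Per gene: t = mean(d) / (sd(d)/sqrt(k)) over the k complete pairs,
    two-sided p from the t distribution with k - 1 df. Zero-variance
    differences are flagged: all-zero differences give t = 0, p = 1; a
    constant nonzero difference gives t = +/-inf, p = 0.
    """
    tdf = traits.data if hasattr(traits, "data") else traits
    samples = [s for s in expr.sample_ids if s in tdf.index]
    cond = tdf.loc[samples, condition]
    pairs = tdf.loc[samples, pair]
    case = {pid: s for s, c, pid in zip(samples, cond, pairs) if c == 1}
    ctrl = {pid: s for s, c, pid in zip(samples, cond, pairs) if c == 0}
    shared = sorted(set(case) & set(ctrl), key=lambda x: str(x))
    genes = list(expr.gene_ids) if genes is None else \
        [g for g in genes if g in set(expr.gene_ids)]
    rows = []
    for g in genes:
        x = expr.data.loc[g]
        d = np.array([x[case[p_]] - x[ctrl[p_]] for p_ in shared], dtype=float)
        d = d[~np.isnan(d)]
        k = len(d)
        if k < 3:
            raise ValueError(f"gene {g!r}: {k} complete pairs < 3")
        mean_d = float(d.mean())
        sd_d = float(d.std(ddof=1))
        if sd_d == 0:
            if mean_d == 0:
                rows.append({"gene_id": g, "t": 0.0, "p": 1.0,
                             "mean_diff": 0.0, "n_pairs": k,
                             "direction": "none", "flag": "degenerate"})
            else:
                t = np.inf if mean_d > 0 else -np.inf
                rows.append({"gene_id": g, "t": t, "p": 0.0,
                             "mean_diff": mean_d, "n_pairs": k,
                             "direction": "up" if mean_d > 0 else "down",
                             "flag": "infinite_t"})
            continue
        t = mean_d / (sd_d / np.sqrt(k))
        p = 2.0 * stats.t.sf(abs(t), k - 1)
        rows.append({"gene_id": g, "t": t, "p": p, "mean_diff": mean_d,
                     "n_pairs": k,
                     "direction": "up" if mean_d > 0 else
                     ("down" if mean_d < 0 else "none"), "flag": ""})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora_hypergeometric(selection: list[str], sets: GeneSetCollection,
                       universe: list[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene selection
    against each gene set, restricted to the universe, with BH adjustment
    across sets."""
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    sel = list(dict.fromkeys(selection))
    outside = [g for g in sel if g not in uni_set]
    if outside:
        logger.warning("%s %d selection gene(s) outside the universe dropped",
                       W_SELECTION_OUTSIDE, len(outside))
        sel = [g for g in sel if g in uni_set]
    M = len(uni)
    N_sel = len(sel)
    sel_set = set(sel)
    rows = []
    for name in sets.names():
        members = [g for g in sets[name] if g in uni_set]
        K = len(members)
        overlap = len(sel_set & set(members))
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N_sel)) if K else 1.0
        rows.append({"set": name, "overlap": overlap, "set_size": K,
                     "selection_size": N_sel, "universe_size": M, "p": p})
    df = pd.DataFrame(rows).set_index("set")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p")
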