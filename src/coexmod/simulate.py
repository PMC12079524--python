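"""Synthetic expression datasets with planted co-expression structure.

A Gaussian latent-factor model generates everything the analysis assumes:
block-correlated modules driven by latent eigengenes, a planted driver
gene with specified module correlations, a planted anti-correlated hub
candidate upregulated in the case condition of a paired design, an
independent validation cohort sharing the module structure, and
heavy-tailed outlier contamination to exercise robust correlation.

The model is anchored on a latent driver factor D ~ N(0,1): a module with
target driver correlation c gets eigengene e_q = c*D + sqrt(1-c^2)*xi_q,
so cor(D, e_q) = c exactly in population for any |c| <= 1, and module
eigengenes acquire the mutual correlations (c_q * c_q') that real module
summaries show. Modules outside the driver plan get independent
eigengenes. Members load as x_i = sqrt(rho)*e_q + sqrt(1-rho)*eps_i, so
cor(x_i, e_q) = sqrt(rho). Every planted quantity maps to a closed-form
population target, which is what makes parameter-recovery testing
possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, TraitTable
from .module_detect import ModulePartition

logger = logging.getLogger("coexmod")

DRIVER_GENE = "G-DRIVER"
CANDIDATE_GENE = "G-CAND"


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the generator.

    Defaults mirror the scaled-down plaque-cohort scenario: 2000 genes
    (5 modules of 200/150/100/60/40 members plus background), 40 samples in
    20 case/control pairs, a driver gene correlated +0.90 / -0.70 / +0.66
    with modules 1-3, and a hub candidate in module 2 anti-correlated with
    the driver as strongly as its module eigengene (r = -0.70) and
    upregulated by delta = 0.5 log2 units in cases. Outlier contamination
    replaces 1% of cells with 6-SD values.
    """

    n_samples: int = 40
    module_sizes: tuple[int, ...] = (200, 150, 100, 60, 40)
    # smaller modules are tighter: at soft power 8 and 40 samples the
    # detectability floor for a 40-gene module sits near rho ~ 0.7
    rho: tuple[float, ...] = (0.72, 0.70, 0.75, 0.78, 0.80)
    n_background: int = 1448  # total 2000 genes with driver and candidate
    driver_plan: tuple[tuple[int, float], ...] = ((1, 0.90), (2, -0.70), (3, 0.66))
    candidate_plan: tuple[int, float, float, float] = (2, 0.90, -0.70, 0.5)
    # (module label, hub rho, driver correlation, case shift delta in log2)
    rho_jitter: float = 0.15  # per-member signal share rho_i spread
    paired: bool = True
    pair_effect_sd: float = 0.3
    de_targets: str = "candidate_and_module"  # or "candidate_only", "none"
    outlier_frac: float = 0.01
    outlier_magnitude: float = 6.0
    collapse_in_cases: tuple[int, ...] = ()  # modules decohered in cases
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != len(self.rho):
            raise ValueError("module_sizes and rho must have equal length")
        if not all(0.0 <= r <= 1.0 for r in self.rho):
            raise ValueError("rho values must lie in [0, 1]")
        for q, c in self.driver_plan:
            if not (1 <= q <= len(self.module_sizes)):
                raise ValueError(f"driver plan references unknown module {q}")
            if abs(c) > 1:
                raise ValueError(f"driver correlation {c} is unrealizable (|c| > 1)")
        if len({q for q, _ in self.driver_plan}) != len(self.driver_plan):
            raise ValueError("driver plan lists a module twice")
        mq, hub_rho, gamma, delta = self.candidate_plan
        if not (0 <= hub_rho <= 1) or abs(gamma) > 1 or not np.isfinite(delta):
            raise ValueError("invalid candidate plan")
        c_m = dict(self.driver_plan).get(mq, 0.0)
        alpha = np.sqrt(hub_rho)
        resid = np.sqrt(max(1.0 - c_m ** 2, 1e-12))
        b = (gamma - alpha * c_m) / resid
        if alpha ** 2 + b ** 2 > 1.0 + 1e-12:
            raise ValueError(
                "unrealizable candidate plan: hub strength and driver "
                f"correlation need loading norm {alpha**2 + b**2:.3f} > 1"
            )
        if self.paired and self.n_samples % 2:
            raise ValueError("paired design needs an even sample count")


@dataclass
class SyntheticDataset:
    """Generated expression + traits + ground truth."""

    expr: ExpressionMatrix
    traits: TraitTable
    truth: ModulePartition
    driver_gene: str
    candidate_gene: str
    spec: SyntheticSpec
    eigengenes: pd.DataFrame = field(repr=False, default=None)  # latent e_q
    member_rho: pd.Series = field(repr=False, default=None)  # planted rho_i


def _assemble_ids(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    """Gene IDs and truth labels, module blocks first, then driver, then
    background. The candidate is an extra member of its module; the driver
    is assigned to its strongest-|correlation| module (like a driver gene
    sitting inside the module it anchors)."""
    ids: list[str] = []
    labels: list[int] = []
    cand_module = spec.candidate_plan[0]
    for q, size in enumerate(spec.module_sizes, start=1):
        for i in range(size):
            ids.append(f"M{q}-{i:03d}")
            labels.append(q)
        if q == cand_module:
            ids.append(CANDIDATE_GENE)
            labels.append(q)
    ids.append(DRIVER_GENE)
    if spec.driver_plan:
        labels.append(max(spec.driver_plan, key=lambda t: abs(t[1]))[0])
    else:
        labels.append(0)
    for i in range(spec.n_background):
        ids.append(f"BG-{i:04d}")
        labels.append(0)
    return ids, np.array(labels, dtype=int)


def simulate_dataset(spec: SyntheticSpec, seed: int | None = None,
                     member_rho_override: pd.Series | None = None
                     ) -> SyntheticDataset:
    """Draw one dataset from the latent-factor model.

    Deterministic given (spec, seed); ``seed`` overrides ``spec.seed``.
    ``member_rho_override`` reuses another dataset's per-member signal
    shares (the validation-cohort case: shared structure, fresh samples).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    Q = len(spec.module_sizes)
    driver_cor = dict(spec.driver_plan)

    D = rng.standard_normal(n)
    eig = np.empty((Q, n))
    for q in range(1, Q + 1):
        c = driver_cor.get(q, 0.0)
        xi = rng.standard_normal(n)
        eig[q - 1] = c * D + np.sqrt(1.0 - c ** 2) * xi

    ids, labels = _assemble_ids(spec)
    n_genes = len(ids)
    X = np.empty((n_genes, n))
    row_of = {g: i for i, g in enumerate(ids)}

    member_rho = np.full(n_genes, np.nan)
    for q, (size, rho) in enumerate(zip(spec.module_sizes, spec.rho), start=1):
        member_rows = [row_of[f"M{q}-{i:03d}"] for i in range(size)]
        # heterogeneous membership strengths give modules genuine hubs and
        # a decaying connectivity spectrum
        lo = max(rho - spec.rho_jitter, 0.1)
        hi = min(rho + 0.05, 0.92)
        if member_rho_override is not None:
            rho_i = member_rho_override.loc[
                [f"M{q}-{i:03d}" for i in range(size)]].to_numpy()
        elif spec.rho_jitter > 0:
            rho_i = rng.uniform(lo, hi, size)
        else:
            rho_i = np.full(size, rho)
        member_rho[member_rows] = rho_i
        noise = rng.standard_normal((size, n))
        X[member_rows] = (np.sqrt(rho_i)[:, None] * eig[q - 1]
                          + np.sqrt(1.0 - rho_i)[:, None] * noise)

    # candidate: hub of its module plus a tuned driver-orthogonal component
    mq, hub_rho, gamma, _delta = spec.candidate_plan
    c_m = driver_cor.get(mq, 0.0)
    alpha = np.sqrt(hub_rho)
    resid_sd = np.sqrt(max(1.0 - c_m ** 2, 1e-12))
    u = (D - c_m * eig[mq - 1]) / resid_sd  # unit-variance, orthogonal to e_mq
    b = (gamma - alpha * c_m) / resid_sd
    eps_sd = np.sqrt(max(1.0 - alpha ** 2 - b ** 2, 0.0))
    X[row_of[CANDIDATE_GENE]] = (alpha * eig[mq - 1] + b * u
                                 + eps_sd * rng.standard_normal(n))
    member_rho[row_of[CANDIDATE_GENE]] = hub_rho

    X[row_of[DRIVER_GENE]] = D

    bg_rows = [row_of[f"BG-{i:04d}"] for i in range(spec.n_background)]
    if bg_rows:
        X[bg_rows] = rng.standard_normal((len(bg_rows), n))

    # paired two-condition design: samples (2p, 2p+1) share a pair ID;
    # the second of each pair is the case condition
    condition = np.tile([0, 1], n // 2) if spec.paired \
        else (np.arange(n) >= n // 2).astype(int)
    pair = np.repeat(np.arange(1, n // 2 + 1), 2) if spec.paired \
        else np.zeros(n, dtype=int)

    de_rows: list[int] = []
    if spec.de_targets == "candidate_and_module":
        de_rows = [row_of[f"M{mq}-{i:03d}"] for i in range(spec.module_sizes[mq - 1])]
        de_rows.append(row_of[CANDIDATE_GENE])
    elif spec.de_targets == "candidate_only":
        de_rows = [row_of[CANDIDATE_GENE]]
    if de_rows and spec.paired:
        pair_effect = rng.standard_normal(n // 2) * spec.pair_effect_sd
        X[de_rows] += pair_effect[pair - 1]
    if de_rows:
        X[de_rows] += spec.candidate_plan[3] * condition

    # optional decoherence of chosen modules in the case condition
    for q in spec.collapse_in_cases:
        member_rows = [row_of[f"M{q}-{i:03d}"]
                       for i in range(spec.module_sizes[q - 1])]
        case = condition == 1
        X[np.ix_(member_rows, np.flatnonzero(case))] = \
            rng.standard_normal((len(member_rows), int(case.sum())))

    # log2-scale baseline per gene
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    X = X + baseline[:, None]

    # heavy-tailed contamination: replace cells with mean +/- magnitude*SD.
    # The driver gene is the trait anchor and is left uncontaminated.
    if spec.outlier_frac > 0:
        row_sd = X.std(axis=1, ddof=1)
        row_mean = X.mean(axis=1)
        mask = rng.random((n_genes, n)) < spec.outlier_frac
        mask[row_of[DRIVER_GENE]] = False
        signs = np.where(rng.random((n_genes, n)) < 0.5, -1.0, 1.0)
        X = np.where(mask, row_mean[:, None] + signs * spec.outlier_magnitude
                     * row_sd[:, None], X)

    sample_ids = [f"S{j + 1:02d}" for j in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(X, index=ids, columns=sample_ids))
    tdf = pd.DataFrame({
        "condition": condition,
        "pair": pair,
        "driver": X[row_of[DRIVER_GENE]],
    }, index=pd.Index(sample_ids, name="sample_id"))
    traits = TraitTable(tdf)
    truth = ModulePartition(ids, labels)
    return SyntheticDataset(expr, traits, truth, DRIVER_GENE, CANDIDATE_GENE,
                            spec, pd.DataFrame(eig.T, index=sample_ids,
                                               columns=[f"E{q}" for q in
                                                        range(1, Q + 1)]),
                            pd.Series(member_rho, index=ids))


def make_validation_cohort(spec: SyntheticSpec, base: SyntheticDataset,
                           n_new_samples: int, seed: int | None = None,
                           distort: bool = False) -> SyntheticDataset:
    """Independent cohort sharing the base dataset's module structure.

    Same memberships and rho, fresh samples. With ``distort``, per-gene
    location/scale shifts emulate platform differences (the reason for
    rank-based signature scoring).
    """
    if n_new_samples <= 0:
        raise ValueError("validation cohort needs at least one sample")
    from dataclasses import replace
    vspec = replace(spec, n_samples=n_new_samples,
                    seed=(spec.seed + 7919 if seed is None else seed))
    ds = simulate_dataset(vspec, member_rho_override=base.member_rho)
    if distort:
        rng = np.random.default_rng(vspec.seed + 1)
        loc = rng.normal(0.0, 1.0, size=ds.expr.n_genes)
        scale = rng.uniform(0.5, 2.0, size=ds.expr.n_genes)
        newvals = ds.expr.values * scale[:, None] + loc[:, None]
        ds = SyntheticDataset(
            ExpressionMatrix(pd.DataFrame(newvals, index=ds.expr.gene_ids,
                                          columns=ds.expr.sample_ids)),
            ds.traits, ds.truth, ds.driver_gene, ds.candidate_gene, vspec,
            ds.eigengenes, ds.member_rho)
    return ds
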