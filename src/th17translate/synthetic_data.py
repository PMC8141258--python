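"""Seeded generators producing inputs with the statistical structure each
pipeline stage assumes: multi-study DEG tables sharing a latent effect,
cohorts with a planted signature-high subgroup, compendium mixtures with a
known weight vector, rankings with markers planted at known depths, and
dose-response tables from a known Hill curve.

Every generator is a pure function of its config (seed included); all
randomness flows through one ``numpy.random.default_rng(seed)`` per call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dcq_deconvolution import DCQInput, make_dcq_input
from .io_formats import (
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    CellCompendium,
    DEGTable,
    ExpressionMatrix,
    PDTable,
    ValidationError,
)

DEFAULT_SIGNATURE = ("CXCL1", "CXCL2", "CXCL3", "IL8")


@dataclass
class HillTruth:
    i_max: float = 100.0
    ec50: float = 120.0
    h: float = 1.5

    def inhibition(self, exposure: float) -> float:
        return self.i_max * exposure**self.h / (self.ec50**self.h + exposure**self.h)


@dataclass
class GeneratorConfig:
    """One config object for every generator; only the relevant fields are
    read by each. The seed is mandatory."""

    seed: int
    # gen_deg_studies
    n_genes: int = 2000
    n_studies: int = 2
    latent_effect_sd: float = 1.0
    cross_study_rho: float = 0.7
    deg_se: float = 0.5  # standard error used by the p-value z-model
    species: str = "human"
    # gen_cohort_matrix
    n_samples: int = 60
    planted_high_fraction: float = 0.4
    signature_shift: float = 2.0
    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE
    cohort_n_genes: int = 500
    cohort_noise_sd: float = 1.0
    # gen_mixture_foldchange
    n_cell_types: int = 10
    markers_per_type: int = 50
    w_true: Mapping[str, float] | None = None  # default: 2-sparse (+3.0, -2.0)
    mixture_noise_sd: float = 0.0
    # gen_ranked_planting
    ranking_n_genes: int = 2500
    planted_ranks: tuple[int, ...] = tuple(range(1, 31))
    planted_cell_type: str = "GD_TCELL"
    # gen_pd_table
    pd_endpoints: tuple[str, ...] = ("IL-17", "IL-22", "neutrophils", "eosinophils")
    pd_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"IL-17": 10.0, "IL-22": 20.0, "neutrophils": 50.0, "eosinophils": 80.0}
    )
    pd_induction: Mapping[str, float] = field(
        default_factory=lambda: {"IL-17": 100.0, "IL-22": 80.0, "neutrophils": 200.0, "eosinophils": 150.0}
    )
    pd_hill_truth: Mapping[str, HillTruth] = field(
        default_factory=lambda: {
            "IL-17": HillTruth(ec50=120.0, h=1.5),
            "IL-22": HillTruth(ec50=600.0, h=1.5),
            "neutrophils": HillTruth(ec50=150.0, h=1.5),
        }
    )
    pd_doses: Mapping[str, float] = field(
        default_factory=lambda: {"3mpk": 40.0, "10mpk": 120.0, "30mpk": 400.0, "100mpk": 1200.0}
    )
    pd_n_negative: int = 6
    pd_n_positive: int = 8
    pd_n_treated: int = 8
    pd_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("latent_effect_sd", "deg_se", "cohort_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.planted_high_fraction <= 1):
            raise ValidationError("planted_high_fraction must be in [0, 1]")


def _gene_names(n: int, prefix: str = "GENE") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def gen_deg_studies(config: GeneratorConfig) -> list[DEGTable]:
    """DEG tables whose log-ratios share a latent per-gene effect.

    Study k's log-ratio is ``sd * (sqrt(rho)*latent + sqrt(1-rho)*noise_k)``
    so the population Pearson correlation between any two studies is exactly
    ``cross_study_rho``. Raw p-values come from a two-sided z-model with
    standard error ``deg_se``; adjusted p-values are Benjamini-Hochberg.
    """
    rho = config.cross_study_rho
    if not (0 <= rho < 1):
        raise ValidationError(f"cross_study_rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    latent = rng.standard_normal(config.n_genes)
    tables = []
    for k in range(config.n_studies):
        noise = rng.standard_normal(config.n_genes)
        log_ratio = config.latent_effect_sd * (np.sqrt(rho) * latent + np.sqrt(1 - rho) * noise)
        z = log_ratio / config.deg_se
        p = 2 * stats.norm.sf(np.abs(z))
        p_adj = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame({"gene": genes, "log_ratio": log_ratio, "p": p, "p_adj_fdr": p_adj})
        tables.append(DEGTable(study_id=f"study{k + 1}", species=config.species, data=df))
    return tables


def gen_cohort_matrix(config: GeneratorConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression cohort with a planted signature-high subpopulation.

    Baseline values are Normal(0, cohort_noise_sd); the first
    ``round(fraction * n_samples)`` samples get ``signature_shift`` added on
    the signature genes. Returns the matrix and the true high/low labels.
    """
    n_planted = int(round(config.planted_high_fraction * config.n_samples))
    if n_planted < 1:
        raise ValidationError("planted fraction times n_samples is below 1")
    rng = np.random.default_rng(config.seed)
    signature = [g.upper() for g in config.signature_genes]
    n_filler = config.cohort_n_genes - len(signature)
    if n_filler < 0:
        raise ValidationError("cohort_n_genes smaller than the signature")
    genes = signature + _gene_names(n_filler, prefix="BG")
    samples = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    values = rng.normal(0.0, config.cohort_noise_sd, size=(len(genes), len(samples)))
    planted = np.zeros(len(samples), dtype=bool)
    planted[:n_planted] = True
    values[: len(signature), planted] += config.signature_shift
    truth = pd.Series(np.where(planted, "high", "low"), index=samples, name="truth")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_group={s: ("planted" if planted[i] else "background") for i, s in enumerate(samples)},
    )
    return matrix, truth


def gen_mixture_foldchange(config: GeneratorConfig) -> tuple[DCQInput, pd.Series]:
    """Fold-change vector built as compendium @ w_true plus optional noise.

    The compendium has orthogonal columns scaled to unit variance (a random
    Gaussian matrix orthonormalized by QR), each dominated by
    ``markers_per_type`` distinctive genes, so coefficient recovery is on the
    same scale as ``w_true``. Default truth is 2-sparse: +3.0 on the first
    cell type and -2.0 on the second.
    """
    n_genes = config.n_cell_types * config.markers_per_type
    if n_genes <= config.n_cell_types:
        raise ValidationError("need more genes than cell types")
    rng = np.random.default_rng(config.seed)
    cell_types = [f"CT{i:02d}" for i in range(1, config.n_cell_types + 1)]
    genes = _gene_names(n_genes, prefix="MG")
    raw = rng.standard_normal((n_genes, config.n_cell_types))
    # marker boost keeps each column recognisably cell-type specific
    for j in range(config.n_cell_types):
        block = slice(j * config.markers_per_type, (j + 1) * config.markers_per_type)
        raw[block, j] += 5.0
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    ref = q * np.sqrt(n_genes)  # unit population variance, exactly orthogonal columns
    compendium = CellCompendium(reference=pd.DataFrame(ref, index=genes, columns=cell_types))
    if config.w_true is None:
        w = pd.Series(0.0, index=cell_types)
        w.iloc[0] = 3.0
        w.iloc[1] = -2.0
    else:
        w = pd.Series(0.0, index=cell_types)
        for ct, val in config.w_true.items():
            if ct not in w.index:
                raise ValidationError(f"w_true names unknown cell type {ct!r}")
            w[ct] = float(val)
    fold_change = pd.Series(ref @ w.to_numpy(), index=genes, name="fold_change")
    if config.mixture_noise_sd > 0:
        fold_change = fold_change + rng.normal(0.0, config.mixture_noise_sd, size=n_genes)
    w.name = "w_true"
    return make_dcq_input(fold_change, compendium), w


def gen_ranked_planting(config: GeneratorConfig) -> tuple[DEGTable, pd.Series]:
    """DEG table whose fold changes place chosen marker genes at known ranks.

    A strictly decreasing fold-change ladder is drawn, marker symbols are
    assigned to the requested rank positions, and the row order is shuffled
    so the ranking step has real work to do. Returns the table and a
    marker -> planted-rank series.
    """
    n = config.ranking_n_genes
    ranks = sorted(set(int(r) for r in config.planted_ranks))
    if not ranks:
        raise ValidationError("no planted ranks given")
    if ranks[0] < 1 or ranks[-1] > n:
        raise ValidationError(f"planted ranks must lie in [1, {n}]")
    rng = np.random.default_rng(config.seed)
    fold = np.sort(rng.normal(0.0, 2.0, size=n))[::-1]
    names = _gene_names(n, prefix="RG")
    markers = [f"{config.planted_cell_type}_M{i:03d}" for i in range(1, len(ranks) + 1)]
    for marker, rank in zip(markers, ranks):
        names[rank - 1] = marker
    p = rng.uniform(0.0, 1.0, size=n)
    df = pd.DataFrame(
        {
            "gene": names,
            "log_ratio": fold,
            "p": p,
            "p_adj_fdr": multipletests(p, method="fdr_bh")[1],
        }
    )
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    table = DEGTable(study_id="planted_ranking", species="mouse", data=df)
    planted = pd.Series(ranks, index=markers, name="planted_rank")
    return table, planted


def gen_pd_table(config: GeneratorConfig) -> tuple[PDTable, dict]:
    """Dose-response PD table from known Hill truths per endpoint.

    Group means: negative control = baseline; positive control = baseline +
    induction; a treated arm = baseline + induction * (1 - inhibition/100)
    with inhibition taken from that endpoint's Hill truth at the dose's
    trough exposure (endpoints without a Hill truth are uninhibited).
    Per-animal values add Normal(0, pd_noise_sd) noise, clipped at 0.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_inhibition: dict[str, dict[str, float]] = {}

    def add_group(group: str, n: int, exposure: float | None) -> None:
        for endpoint in config.pd_endpoints:
            base = config.pd_baseline[endpoint]
            induction = config.pd_induction[endpoint]
            if group == NEGATIVE_CONTROL:
                mean = base
            elif group == POSITIVE_CONTROL:
                mean = base + induction
            else:
                hill = config.pd_hill_truth.get(endpoint)
                inhibition = hill.inhibition(exposure) if hill is not None else 0.0
                truth_inhibition.setdefault(endpoint, {})[group] = inhibition
                mean = base + induction * (1.0 - inhibition / 100.0)
            noise = rng.normal(0.0, config.pd_noise_sd, size=n) if config.pd_noise_sd > 0 else np.zeros(n)
            values = np.clip(mean + noise, 0.0, None)
            for i in range(n):
                rows.append(
                    {
                        "animal_id": f"{group}_{endpoint}_{i + 1}",
                        "group": group,
                        "endpoint": endpoint,
                        "value": values[i],
                        "trough_exposure": exposure if exposure is not None else np.nan,
                    }
                )

    add_group(NEGATIVE_CONTROL, config.pd_n_negative, None)
    add_group(POSITIVE_CONTROL, config.pd_n_positive, None)
    for dose, exposure in config.pd_doses.items():
        add_group(f"treated:{dose}", config.pd_n_treated, exposure)
    table = PDTable(data=pd.DataFrame(rows))
    truth = {
        "inhibition": truth_inhibition,
        "hill": {e: h for e, h in config.pd_hill_truth.items()},
        "exposures": dict(config.pd_doses),
    }
    return table, truth
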