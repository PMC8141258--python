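"""Pairwise Pearson correlation of DEG log-ratios across studies after
FDR filtering and ortholog harmonization."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    DEGTable,
    OrthologMap,
    ValidationError,
    merge_duplicate_genes,
)

log = logging.getLogger(__name__)

MIN_SHARED_GENES = 3


@dataclass
class CorrelationCell:
    study_a: str
    study_b: str
    n: int
    r: float  # NaN when n < MIN_SHARED_GENES
    p: float

    @property
    def missing(self) -> bool:
        return self.n < MIN_SHARED_GENES


@dataclass
class CorrelationMatrixResult:
    cells: list[CorrelationCell]
    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"study_a": c.study_a, "study_b": c.study_b, "n": c.n, "r": c.r, "p": c.p}
                for c in self.cells
            ]
        )


def filter_degs(table: DEGTable, alpha: float = 0.05) -> DEGTable:
    """Keep rows with p_adj_fdr <= alpha (closed boundary), order preserved."""
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    kept = table.data[table.data["p_adj_fdr"] <= alpha].reset_index(drop=True)
    log.info("study %s: %d of %d rows pass p_adj_fdr <= %g", table.study_id, len(kept), len(table), alpha)
    return DEGTable(study_id=table.study_id, species=table.species, data=kept)


def harmonize(table: DEGTable, orthologs: OrthologMap, target_species: str) -> DEGTable:
    """Translate gene symbols to the target species via the ortholog map.

    Same-species calls are identity. Unmapped genes are dropped and counted;
    many-to-one translations collapse by the mean-dedup rule. An empty result
    is an error.
    """
    if table.species == target_species:
        return table
    if table.species == "mouse" and target_species == "human":
        mapping = orthologs.mouse_to_human()
    elif table.species == "human" and target_species == "mouse":
        mapping = orthologs.human_to_mouse()
    else:
        raise ValidationError(f"cannot harmonize {table.species} -> {target_species}")
    df = table.data.copy()
    translated = df["gene"].map(mapping)
    n_dropped = int(translated.isna().sum())
    df = df.assign(gene=translated).dropna(subset=["gene"]).reset_index(drop=True)
    if n_dropped:
        log.info("study %s: dropped %d genes without orthologs", table.study_id, n_dropped)
    if df.empty:
        raise ValidationError(f"study {table.study_id!r}: no genes left after ortholog mapping")
    df, n_merged = merge_duplicate_genes(df)
    return DEGTable(study_id=table.study_id, species=target_species, data=df, n_merged=n_merged)


def correlate_pair(a: DEGTable, b: DEGTable) -> CorrelationCell:
    """Pearson r of log-ratios on the inner join of gene symbols.

    Pairs sharing fewer than 3 genes come back as a missing cell (NaN r/p),
    not an exception.
    """
    joined = pd.merge(
        a.data[["gene", "log_ratio"]],
        b.data[["gene", "log_ratio"]],
        on="gene",
        suffixes=("_a", "_b"),
    )
    n = len(joined)
    if n < MIN_SHARED_GENES:
        log.warning("pair (%s, %s): only %d shared genes, cell reported missing", a.study_id, b.study_id, n)
        return CorrelationCell(study_a=a.study_id, study_b=b.study_id, n=n, r=float("nan"), p=float("nan"))
    x = joined["log_ratio_a"].to_numpy(float)
    y = joined["log_ratio_b"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationCell(study_a=a.study_id, study_b=b.study_id, n=n, r=float("nan"), p=float("nan"))
    res = stats.pearsonr(x, y)  # two-sided t-approximation p-value
    return CorrelationCell(study_a=a.study_id, study_b=b.study_id, n=n, r=float(res.statistic), p=float(res.pvalue))


def correlation_matrix(tables: Sequence[DEGTable]) -> CorrelationMatrixResult:
    """All unordered pairs, computed once; symmetric with unit diagonal."""
    if len(tables) < 2:
        raise ValidationError("need at least 2 studies")
    ids = [t.study_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate study ids: {ids}")
    r = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    n = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    p = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, t in enumerate(tables):
        n.iloc[i, i] = len(t)
    cells: list[CorrelationCell] = []
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            cell = correlate_pair(tables[i], tables[j])
            cells.append(cell)
            r.iloc[i, j] = r.iloc[j, i] = cell.r
            n.iloc[i, j] = n.iloc[j, i] = cell.n
            p.iloc[i, j] = p.iloc[j, i] = cell.p
    return CorrelationMatrixResult(cells=cells, r=r, n=n, p=p)


def write_correlation_tsv(result: CorrelationMatrixResult, path) -> None:
    """Long-form TSV (study_a, study_b, n, r, p); missing cells stay NA."""
    result.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def plot_correlation_heatmap(result: CorrelationMatrixResult, path) -> None:
    """Render the r matrix as a red/blue heat map (diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(result.r) + 2, 1.2 * len(result.r) + 1))
    im = ax.imshow(result.r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(result.r)), result.r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(result.r)), result.r.index)
    for i in range(len(result.r)):
        for j in range(len(result.r)):
            val = result.r.iloc[i, j]
            if not np.isnan(val):
                ax.text(j, i, f"{val:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
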