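"""Fold-change-ranked sliding-window overlap and the 100-gene-block
weighted enrichment score for cell-type marker lists.

The weighted score assigns weight 20 to markers in ranks 1-100, 19 to
ranks 101-200, down to weight 1 for ranks 1901-2000; markers beyond rank
2000 contribute nothing. The size-200 window scan is a separate
diagnostic view of the same ranking.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DEGTable, GeneSetCollection, ValidationError, normalize_symbols

log = logging.getLogger(__name__)

BLOCK_SIZE = 100
N_BLOCKS = 20
MAX_RANK = BLOCK_SIZE * N_BLOCKS  # 2000
MAX_WEIGHT = N_BLOCKS  # 20


@dataclass
class RankedGeneList:
    """Genes ordered by fold change (rank 1 = strongest)."""

    genes: list[str]
    values: np.ndarray  # ranking value (fold change) aligned with genes

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.values):
            raise ValidationError("genes and values length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self) -> dict[str, int]:
        """1-based rank per gene."""
        return {g: i + 1 for i, g in enumerate(self.genes)}


@dataclass
class EnrichmentScore:
    cell_type: str
    weighted_score: int
    n_markers: int
    windowed_overlaps: pd.DataFrame | None = None

    @property
    def normalized(self) -> float:
        return self.weighted_score / (MAX_WEIGHT * self.n_markers)


def rank_genes(table: DEGTable, top_n: int = MAX_RANK, absolute: bool = False) -> RankedGeneList:
    """Sort descending by (signed or absolute) log-ratio, ties broken
    lexicographically by symbol, truncated to ``top_n``."""
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    if len(table) == 0:
        raise ValidationError("cannot rank an empty DEG table")
    df = table.data[["gene", "log_ratio"]].copy()
    key = df["log_ratio"].abs() if absolute else df["log_ratio"]
    df = df.assign(_key=key).sort_values(["_key", "gene"], ascending=[False, True], kind="mergesort")
    df = df.head(top_n)
    return RankedGeneList(genes=list(df["gene"]), values=df["log_ratio"].to_numpy(float))


def weight_at_rank(rank: int) -> int:
    """Block weight of a 1-based rank: 20 for 1-100 ... 1 for 1901-2000, else 0."""
    if rank < 1:
        raise ValidationError(f"rank must be >= 1, got {rank}")
    if rank > MAX_RANK:
        return 0
    return MAX_WEIGHT + 1 - int(np.ceil(rank / BLOCK_SIZE))


def _clean_markers(markers: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for m in normalize_symbols(markers):
        seen.setdefault(m, None)
    cleaned = list(seen)
    if not cleaned:
        raise ValidationError("empty marker list")
    return cleaned


def windowed_overlap(
    ranked: RankedGeneList,
    markers: Sequence[str],
    window: int = 200,
    step: int = BLOCK_SIZE,
) -> pd.DataFrame:
    """Marker count inside each window [start, start+window) of the ranking.

    Returns a frame with 1-based window ``start``/``end`` coordinates and the
    overlap count. Diagnostic companion to :func:`weighted_score`.
    """
    if window > len(ranked):
        raise ValidationError(f"window {window} exceeds ranked list length {len(ranked)}")
    marker_set = set(_clean_markers(markers))
    in_marker = np.fromiter((g in marker_set for g in ranked.genes), dtype=int, count=len(ranked))
    csum = np.concatenate([[0], np.cumsum(in_marker)])
    rows = []
    for start in range(1, len(ranked) - window + 2, step):
        end = start + window - 1
        rows.append({"start": start, "end": end, "overlap": int(csum[end] - csum[start - 1])})
    return pd.DataFrame(rows)


def weighted_score(
    ranked: RankedGeneList,
    markers: Sequence[str],
    cell_type: str = "cell_type",
    with_windows: bool = False,
) -> EnrichmentScore:
    """Sum of block weights over marker ranks (input truncated to rank 2000)."""
    if len(ranked) > MAX_RANK:
        log.warning("ranked list has %d genes; truncating to %d", len(ranked), MAX_RANK)
        ranked = RankedGeneList(genes=ranked.genes[:MAX_RANK], values=ranked.values[:MAX_RANK])
    cleaned = _clean_markers(markers)
    rank_of = ranked.rank_of()
    score = sum(weight_at_rank(rank_of[m]) for m in cleaned if m in rank_of)
    windows = None
    if with_windows:
        win = min(200, len(ranked))
        windows = windowed_overlap(ranked, cleaned, window=win)
    return EnrichmentScore(
        cell_type=cell_type,
        weighted_score=int(score),
        n_markers=len(cleaned),
        windowed_overlaps=windows,
    )


def score_all_cell_types(
    ranked: RankedGeneList, collections: GeneSetCollection
) -> pd.DataFrame:
    """One weighted score per cell-type list, sorted descending.

    Emits both the raw score and the per-marker normalization
    ``score / (20 * n_markers)``.
    """
    if len(collections) == 0:
        raise ValidationError("no cell-type gene lists given")
    rows = []
    for gs in collections:
        es = weighted_score(ranked, gs.genes, cell_type=gs.name)
        rows.append(
            {
                "cell_type": es.cell_type,
                "weighted_score": es.weighted_score,
                "n_markers": es.n_markers,
                "normalized_score": es.normalized,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["weighted_score", "cell_type"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
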