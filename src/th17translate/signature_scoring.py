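"""Per-sample signature scores by mean-centering and averaging, cut-off
cluster assignment, and cluster prevalence summaries."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    normalize_symbols,
)

log = logging.getLogger(__name__)


@dataclass
class SignatureScoreResult:
    """Per-sample scores, one column per signature.

    ``n_genes_used`` counts the signature genes actually found in the matrix.
    """

    scores: pd.DataFrame  # index = samples, columns = signature names
    n_genes_used: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class ClusterAssignment:
    """High/low calls per signature and a composite per-sample label."""

    per_signature: pd.DataFrame  # index = samples, columns = signatures, values high/low
    labels: pd.Series  # composite label per sample
    cutoff: float


def mean_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples. Requires >= 2 samples."""
    if matrix.shape[1] < 2:
        raise ValidationError("mean centering needs at least 2 samples")
    centered = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    return ExpressionMatrix(values=centered, sample_group=dict(matrix.sample_group))


def signature_score(
    matrix: ExpressionMatrix,
    signature: Sequence[str],
    name: str = "signature",
    min_genes: int = 1,
) -> SignatureScoreResult:
    """Score one signature: mean of mean-centered expression over its genes."""
    return score_signatures(matrix, {name: list(signature)}, min_genes=min_genes)


def score_signatures(
    matrix: ExpressionMatrix,
    signatures: GeneSetCollection | Mapping[str, Sequence[str]],
    min_genes: int = 1,
) -> SignatureScoreResult:
    """Score each signature independently on the same centered matrix.

    Scoring uses the intersection of the signature with the matrix genes; an
    empty intersection (or one below ``min_genes``) is an error naming the
    missing genes.
    """
    centered = mean_center(matrix)
    if isinstance(signatures, GeneSetCollection):
        sig_map = {gs.name: gs.genes for gs in signatures}
    else:
        sig_map = {name: list(genes) for name, genes in signatures.items()}
    if not sig_map:
        raise ValidationError("no signatures given")
    gene_index = set(centered.genes)
    columns: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for name, genes in sig_map.items():
        wanted = normalize_symbols(genes)
        found = [g for g in wanted if g in gene_index]
        if len(found) < max(min_genes, 1):
            missing = [g for g in wanted if g not in gene_index]
            raise ValidationError(
                f"signature {name!r}: only {len(found)} of {len(wanted)} genes found "
                f"(need >= {max(min_genes, 1)}); missing: {missing}"
            )
        columns[name] = centered.values.loc[found].mean(axis=0).to_numpy()
        n_used[name] = len(found)
    scores = pd.DataFrame(columns, index=centered.samples)
    return SignatureScoreResult(scores=scores, n_genes_used=n_used)


def assign_clusters(result: SignatureScoreResult, cutoff: float = 0.0) -> ClusterAssignment:
    """Label each sample high/low per signature at the cut-off.

    A score exactly equal to the cut-off is "low". With several signatures the
    composite label joins the per-signature calls, e.g. ``Th2-low/Th17-high``.
    """
    calls = result.scores.apply(lambda col: np.where(col > cutoff, "high", "low"))
    per_signature = pd.DataFrame(calls, index=result.scores.index, columns=result.scores.columns)
    if per_signature.shape[1] == 1:
        labels = per_signature.iloc[:, 0].copy()
    else:
        labels = per_signature.apply(
            lambda row: "/".join(f"{sig}-{row[sig]}" for sig in per_signature.columns), axis=1
        )
    labels.name = "label"
    return ClusterAssignment(per_signature=per_signature, labels=labels, cutoff=cutoff)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cluster_prevalence(assignment: ClusterAssignment | Iterable[str]) -> pd.DataFrame:
    """Counts and percentages per cluster label.

    Accepts a :class:`ClusterAssignment` or any iterable of labels. Percents
    are reported at full precision and rounded half-away-from-zero to match
    printed integer percentages.
    """
    if isinstance(assignment, ClusterAssignment):
        labels = list(assignment.labels)
    else:
        labels = list(assignment)
    if not labels:
        raise ValidationError("no samples to summarize")
    counts = pd.Series(labels).value_counts()
    total = len(labels)
    out = pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total,
        }
    )
    out["percent_rounded"] = [_round_half_away(p) for p in out["percent"]]
    return out.reset_index(drop=True)
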