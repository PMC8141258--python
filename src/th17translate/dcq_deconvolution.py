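"""Digital cell quantification: elastic-net regression of a fold-change
vector on a cell-type reference compendium, with gene-subsampled repeats,
group averaging, an absolute-quantity filter and a per-cell-type z-score
transform for heat-map display.

The penalty follows the glmnet parameterization
``(1/2n)*RSS + lambda*[(1-a)/2*||w||^2 + a*||w||_1]`` with a
ridge-leaning mixing weight ``a`` (default 0.05) and the regression
evaluated at the raw penalty value ``lambda = lambda_min`` (default 0.2).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .io_formats import CellCompendium, ValidationError

log = logging.getLogger(__name__)

MIN_SHARED_GENES = 10
DEFAULT_LAMBDA_MIN = 0.2
DEFAULT_L1_RATIO = 0.05
DEFAULT_SUBSAMPLE = 0.5
DEFAULT_FILTER_THRESHOLD = 2.0


@dataclass
class DCQInput:
    """Fold-change vector and compendium restricted to their shared genes."""

    fold_change: pd.Series  # index = genes
    compendium: CellCompendium

    def __post_init__(self) -> None:
        if list(self.fold_change.index) != self.compendium.genes:
            raise ValidationError("fold_change and compendium gene order differ")
        n_genes, n_types = self.compendium.reference.shape
        if n_genes < MIN_SHARED_GENES:
            raise ValidationError(f"only {n_genes} shared genes, need >= {MIN_SHARED_GENES}")
        if n_genes <= n_types:
            raise ValidationError(f"{n_genes} genes for {n_types} cell types: underdetermined")
        sds = self.compendium.reference.std(axis=0, ddof=0)
        degenerate = list(sds.index[sds.to_numpy() == 0])
        if degenerate:
            raise ValidationError(f"constant compendium column(s): {degenerate}")
        if not np.isfinite(self.fold_change.to_numpy(float)).all():
            raise ValidationError("non-finite fold changes")


def make_dcq_input(fold_change: pd.Series, compendium: CellCompendium) -> DCQInput:
    """Intersect the fold-change genes with the compendium genes."""
    shared = [g for g in compendium.genes if g in set(fold_change.index)]
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(f"only {len(shared)} shared genes, need >= {MIN_SHARED_GENES}")
    return DCQInput(
        fold_change=fold_change.loc[shared].astype(float),
        compendium=CellCompendium(reference=compendium.reference.loc[shared]),
    )


@dataclass
class CellQuantities:
    """Signed relative cell-abundance changes (standardized-compendium scale)."""

    quantities: pd.Series  # index = cell types
    per_repeat: pd.DataFrame  # repeats x cell types
    repeats_used: int

    def support(self, rel_threshold: float = 0.1) -> list[str]:
        """Cell types whose |quantity| is >= rel_threshold * max |quantity|."""
        q = self.quantities.abs()
        if q.max() == 0:
            return []
        return list(q.index[q >= rel_threshold * q.max()])


def dcq(
    dcq_input: DCQInput,
    repeats: int = 3,
    lambda_min: float = DEFAULT_LAMBDA_MIN,
    l1_ratio: float = DEFAULT_L1_RATIO,
    subsample: float = DEFAULT_SUBSAMPLE,
    seed: int | None = None,
) -> CellQuantities:
    """Elastic-net fit repeated on random gene subsamples, coefficients averaged.

    Compendium columns are centered and scaled to unit variance before
    fitting (coefficients are reported on that standardized scale); each
    repeat fits on a seeded without-replacement subsample of the genes, and
    the reported quantity is the mean coefficient across repeats.
    Deterministic for a fixed seed.
    """
    if repeats < 1:
        raise ValidationError(f"repeats must be >= 1, got {repeats}")
    if not (0 < subsample <= 1):
        raise ValidationError(f"subsample fraction must be in (0, 1], got {subsample}")
    if lambda_min <= 0:
        raise ValidationError(f"lambda_min must be > 0, got {lambda_min}")
    ref = dcq_input.compendium.reference
    X = ref.to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    y = dcq_input.fold_change.to_numpy(float)
    n_genes = X.shape[0]
    n_sub = max(int(round(subsample * n_genes)), X.shape[1] + 1)
    rng = np.random.default_rng(seed)
    coefs = np.empty((repeats, X.shape[1]))
    for rep in range(repeats):
        idx = rng.choice(n_genes, size=n_sub, replace=False) if n_sub < n_genes else np.arange(n_genes)
        model = ElasticNet(
            alpha=lambda_min,
            l1_ratio=l1_ratio,
            fit_intercept=True,
            max_iter=50_000,
            tol=1e-8,
        )
        model.fit(X[idx], y[idx])
        coefs[rep] = model.coef_
    per_repeat = pd.DataFrame(coefs, columns=ref.columns)
    quantities = per_repeat.mean(axis=0)
    quantities.name = "quantity"
    return CellQuantities(quantities=quantities, per_repeat=per_repeat, repeats_used=repeats)


def group_average_and_filter(
    per_sample: Mapping[str, CellQuantities],
    groups: Mapping[str, str],
    threshold: float = DEFAULT_FILTER_THRESHOLD,
    signed: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Mean quantity per (group, cell type), then drop flat cell types.

    A cell type survives if any group mean reaches the threshold; by default
    the comparison is on |mean| so down-regulated cell types are kept, with
    ``signed=True`` restoring the literal one-sided reading. The boundary is
    closed: a mean of exactly ``threshold`` is retained. Returns the filtered
    group x cell-type frame and the removed cell-type labels.
    """
    if not per_sample:
        raise ValidationError("no samples given")
    ungrouped = [s for s in per_sample if s not in groups]
    if ungrouped:
        raise ValidationError(f"samples without group labels: {ungrouped}")
    by_group: dict[str, list[pd.Series]] = {}
    for sample, cq in per_sample.items():
        by_group.setdefault(groups[sample], []).append(cq.quantities)
    for group, members in by_group.items():
        if not members:
            raise ValidationError(f"group {group!r} is empty")
    means = pd.DataFrame({g: pd.concat(m, axis=1).mean(axis=1) for g, m in by_group.items()}).T
    means.index.name = "group"
    crit = means if signed else means.abs()
    keep = crit.max(axis=0) >= threshold
    removed = list(means.columns[~keep])
    if removed:
        log.info("filtered %d cell types below %g: %s", len(removed), threshold, removed)
    return means.loc[:, keep], removed


def zscore_by_celltype(per_group: pd.DataFrame) -> pd.DataFrame:
    """Z-score each cell type across groups (sample sd); heat-map matrix.

    Input is groups x cell types (as from :func:`group_average_and_filter`);
    output is cell types x groups. Cell types with zero spread across groups
    are dropped with a warning.
    """
    if per_group.shape[0] < 2:
        raise ValidationError("z-scoring needs >= 2 groups")
    mat = per_group.T  # cell types x groups
    sds = mat.std(axis=1, ddof=1)
    flat = list(mat.index[sds.to_numpy() == 0])
    if flat:
        log.warning("dropping %d constant cell-type rows: %s", len(flat), flat)
        mat = mat.drop(index=flat)
        sds = sds.drop(index=flat)
    return mat.sub(mat.mean(axis=1), axis=0).div(sds, axis=0)


def plot_quantity_heatmap(zscores: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 * zscores.shape[1] + 3, 0.3 * zscores.shape[0] + 2))
    im = ax.imshow(zscores.to_numpy(), aspect="auto", cmap="PuOr_r")
    ax.set_xticks(range(zscores.shape[1]), zscores.columns, rotation=45, ha="right")
    ax.set_yticks(range(zscores.shape[0]), zscores.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
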