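"""Delimited-text readers/writers and the domain types they validate.

All gene symbols are normalized on ingestion (whitespace-stripped,
uppercased) so human/mouse symbol case differences never break joins.
Duplicate gene symbols are merged by the arithmetic mean of the numeric
columns; merges are counted and logged, never silent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_SPECIES = ("human", "mouse")

DEG_COLUMNS = ("gene", "log_ratio", "p", "p_adj_fdr")

PD_COLUMNS = ("animal_id", "group", "endpoint", "value", "trough_exposure")

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"


class FormatError(ValueError):
    """The file does not follow the expected layout (columns, field counts)."""


class ValidationError(ValueError):
    """The file parses but violates a domain invariant (bounds, groups...)."""


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def normalize_symbols(values: Iterable[str]) -> list[str]:
    return [normalize_symbol(v) for v in values]


def sniff_sep(path: str | Path, default: str = "\t") -> str:
    """Auto-detect tab vs comma from the first non-empty line."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "\t" in line:
                    return "\t"
                if "," in line:
                    return ","
                break
    return default


def merge_duplicate_genes(df: pd.DataFrame, key: str = "gene") -> tuple[pd.DataFrame, int]:
    """Average numeric columns over duplicated symbols, keep first-seen order."""
    if not df[key].duplicated().any():
        return df.reset_index(drop=True), 0
    merged = df.groupby(key, sort=False, as_index=False).mean(numeric_only=True)
    n_merged = len(df) - len(merged)
    log.warning("merged %d duplicate rows on %r by arithmetic mean", n_merged, key)
    return merged, n_merged


# ---------------------------------------------------------------------------
# DEGTable


@dataclass
class DEGTable:
    """Per-study differential-expression records.

    ``data`` holds one row per gene with columns ``gene``, ``log_ratio``,
    ``p`` and ``p_adj_fdr``.
    """

    study_id: str
    species: str
    data: pd.DataFrame
    n_merged: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValidationError(f"species must be one of {VALID_SPECIES}, got {self.species!r}")
        missing = [c for c in DEG_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"DEG table missing columns: {missing}")
        df = self.data
        if (df["gene"].astype(str).str.strip() == "").any():
            raise ValidationError("empty gene symbol in DEG table")
        if df["gene"].duplicated().any():
            raise ValidationError("duplicate gene symbols in DEG table (apply merge_duplicate_genes)")
        for col in ("p", "p_adj_fdr"):
            vals = df[col].to_numpy(float)
            if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
                raise ValidationError(f"{col} outside [0, 1] in study {self.study_id!r}")
        if not np.isfinite(df["log_ratio"].to_numpy(float)).all():
            raise ValidationError(f"non-finite log_ratio in study {self.study_id!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> list[str]:
        return list(self.data["gene"])


def read_deg_table(
    path: str | Path,
    study_id: str,
    species: str,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> DEGTable:
    """Read a delimited DEG table.

    ``columns`` maps canonical names (gene, log_ratio, p, p_adj_fdr) to the
    header names actually present in the file.
    """
    sep = sep or sniff_sep(path)
    raw = pd.read_csv(path, sep=sep)
    colmap = {c: c for c in DEG_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (have {list(raw.columns)})")
    df = pd.DataFrame({canon: raw[actual] for canon, actual in colmap.items()})
    df["gene"] = normalize_symbols(df["gene"])
    df, n_merged = merge_duplicate_genes(df)
    table = DEGTable(study_id=study_id, species=species, data=df, n_merged=n_merged)
    log.info("read %d DEG rows for study %s (%d merged)", len(table), study_id, n_merged)
    return table


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ExpressionMatrix


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a group label per sample."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    sample_group: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValidationError("non-finite values in expression matrix")
        ungrouped = [s for s in self.values.columns if s not in self.sample_group]
        if ungrouped:
            raise ValidationError(f"samples without a group label: {ungrouped}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_matrix(
    path: str | Path, groups_path: str | Path, sep: str | None = None
) -> ExpressionMatrix:
    """Read a genes-in-rows matrix plus a two-column sample -> group file."""
    sep = sep or sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = normalize_symbols(raw.index)
    df = raw.reset_index(names="gene")
    df, n_merged = merge_duplicate_genes(df)
    values = df.set_index("gene")
    values.index.name = None
    gsep = sniff_sep(groups_path)
    groups_df = pd.read_csv(groups_path, sep=gsep)
    if groups_df.shape[1] < 2:
        raise FormatError(f"{groups_path}: expected two columns (sample, group)")
    sample_group = dict(zip(groups_df.iloc[:, 0].astype(str), groups_df.iloc[:, 1].astype(str)))
    matrix = ExpressionMatrix(values=values, sample_group=sample_group)
    log.info("read %dx%d expression matrix (%d duplicate genes merged)", *matrix.shape, n_merged)
    return matrix


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path | None = None
) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if groups_path is not None:
        pd.DataFrame(
            {"sample": matrix.samples, "group": [matrix.sample_group[s] for s in matrix.samples]}
        ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Ordered named gene lists (signatures, cell-type marker lists)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, genes: Sequence[str], description: str = "") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        seen: dict[str, None] = {}
        for g in normalize_symbols(genes):
            seen.setdefault(g, None)
        deduped = list(seen)
        if not deduped:
            raise ValidationError(f"gene set {name!r} is empty")
        if len(deduped) < len(list(genes)):
            log.warning("gene set %s: removed %d duplicate symbols", name, len(list(genes)) - len(deduped))
        self.sets[name] = GeneSet(name=name, description=description, genes=deduped)


def read_gmt(path: str | Path) -> GeneSetCollection:
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            collection.add(name, genes, description)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# OrthologMap


@dataclass
class OrthologMap:
    """Two-column mouse -> human symbol map (normalized, first mapping wins)."""

    data: pd.DataFrame  # columns mouse_symbol, human_symbol

    def __post_init__(self) -> None:
        for col in ("mouse_symbol", "human_symbol"):
            if col not in self.data.columns:
                raise FormatError(f"ortholog map missing column {col!r}")
            if (self.data[col].astype(str).str.strip() == "").any():
                raise ValidationError(f"empty symbol in ortholog map column {col!r}")
        if self.data["mouse_symbol"].duplicated().any():
            raise ValidationError("mouse symbol maps to multiple human symbols (dedup first)")

    def mouse_to_human(self) -> dict[str, str]:
        return dict(zip(self.data["mouse_symbol"], self.data["human_symbol"]))

    def human_to_mouse(self) -> dict[str, str]:
        # many mouse -> one human: first mapping wins for the reverse direction
        out: dict[str, str] = {}
        for m, h in zip(self.data["mouse_symbol"], self.data["human_symbol"]):
            out.setdefault(h, m)
        return out


def read_ortholog_map(path: str | Path, sep: str | None = None) -> OrthologMap:
    sep = sep or sniff_sep(path)
    raw = pd.read_csv(path, sep=sep)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (mouse_symbol, human_symbol)")
    df = pd.DataFrame(
        {
            "mouse_symbol": normalize_symbols(raw.iloc[:, 0]),
            "human_symbol": normalize_symbols(raw.iloc[:, 1]),
        }
    )
    before = len(df)
    df = df.drop_duplicates(subset="mouse_symbol", keep="first").reset_index(drop=True)
    if len(df) < before:
        log.warning("ortholog map: dropped %d duplicate mouse-symbol rows (first kept)", before - len(df))
    return OrthologMap(data=df)


def write_ortholog_map(orthologs: OrthologMap, path: str | Path) -> None:
    orthologs.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CellCompendium


@dataclass
class CellCompendium:
    """Reference matrix of cell-type-characteristic profiles (genes x types)."""

    reference: pd.DataFrame  # index = genes, columns = cell types

    def __post_init__(self) -> None:
        if self.reference.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in compendium")
        if self.reference.columns.duplicated().any():
            raise ValidationError("duplicate cell-type labels in compendium")
        if not np.isfinite(self.reference.to_numpy(float)).all():
            raise ValidationError("non-finite values in compendium")

    @property
    def genes(self) -> list[str]:
        return list(self.reference.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.reference.columns)


def read_compendium(path: str | Path, sep: str | None = None) -> CellCompendium:
    sep = sep or sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = normalize_symbols(raw.index)
    df = raw.reset_index(names="gene")
    df, _ = merge_duplicate_genes(df)
    ref = df.set_index("gene")
    ref.index.name = None
    return CellCompendium(reference=ref)


def write_compendium(compendium: CellCompendium, path: str | Path) -> None:
    out = compendium.reference.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PDTable


@dataclass
class PDTable:
    """Per-animal endpoint values with group labels and trough exposures.

    Groups are ``negative_control``, ``positive_control`` or ``treated:<dose>``;
    ``trough_exposure`` may be NaN for control animals.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PD_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"PD table missing columns: {missing}")
        vals = self.data["value"].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite endpoint values in PD table")
        if (vals < 0).any():
            raise ValidationError("negative endpoint values in PD table")
        for endpoint, sub in self.data.groupby("endpoint"):
            groups = set(sub["group"])
            for required in (NEGATIVE_CONTROL, POSITIVE_CONTROL):
                if required not in groups:
                    raise ValidationError(f"endpoint {endpoint!r} lacks a {required} row")

    @property
    def endpoints(self) -> list[str]:
        return list(dict.fromkeys(self.data["endpoint"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    def group_mean(self, endpoint: str, group: str) -> float:
        sub = self.data[(self.data["endpoint"] == endpoint) & (self.data["group"] == group)]
        if sub.empty:
            raise ValidationError(f"no rows for endpoint {endpoint!r}, group {group!r}")
        return float(sub["value"].mean())


def read_pd_table(path: str | Path, sep: str | None = None) -> PDTable:
    sep = sep or sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return PDTable(data=df[list(PD_COLUMNS)].copy())


def write_pd_table(table: PDTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fold-change vectors (DCQ input)


def read_fold_change(path: str | Path, sep: str | None = None) -> pd.Series:
    """Two-column gene -> log fold change file used by the deconvolution CLI."""
    sep = sep or sniff_sep(path)
    raw = pd.read_csv(path, sep=sep)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene, fold_change)")
    df = pd.DataFrame({"gene": normalize_symbols(raw.iloc[:, 0]), "fold_change": raw.iloc[:, 1]})
    df, _ = merge_duplicate_genes(df)
    series = df.set_index("gene")["fold_change"].astype(float)
    if not np.isfinite(series.to_numpy()).all():
        raise ValidationError(f"{path}: non-finite fold changes")
    return series


def write_fold_change(values: pd.Series, path: str | Path) -> None:
    out = values.rename("fold_change").to_frame()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
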