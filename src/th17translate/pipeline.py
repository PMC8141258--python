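"""Config-driven orchestration: simulate inputs, then run scoring,
cross-study correlation, cell enrichment, deconvolution and the PD layer,
recording a run manifest sufficient to reproduce the run."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .cell_enrichment import rank_genes, score_all_cell_types
from .cross_study_correlation import correlation_matrix, filter_degs, write_correlation_tsv
from .dcq_deconvolution import DCQInput, dcq, group_average_and_filter, zscore_by_celltype
from .io_formats import GeneSetCollection, write_deg_table, write_expression_matrix, write_fold_change, write_pd_table
from .pharmacodynamics import efficacy_profile, exposure_response_points, fit_hill
from .signature_scoring import assign_clusters, cluster_prevalence, score_signatures
from .synthetic_data import GeneratorConfig, gen_cohort_matrix, gen_deg_studies, gen_mixture_foldchange, gen_pd_table, gen_ranked_planting

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run config violates the schema; raised before any stage runs."""


@dataclass
class StageRecord:
    name: str
    inputs: list[str]
    outputs: list[str]
    rows: dict[str, int]
    seconds: float


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[StageRecord] = field(default_factory=list)
    wall_clock_seconds: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


_NUMERIC_PARAMS = {
    # key: (default, lower, upper) -- closed bounds
    "alpha": (0.05, 1e-12, 1.0),
    "cutoff": (0.0, float("-inf"), float("inf")),
    "top_n": (2000, 1, 10**7),
    "window": (200, 1, 10**6),
    "repeats": (3, 1, 1000),
    "lambda_min": (0.2, 1e-12, float("inf")),
    "filter_threshold": (2.0, 0.0, float("inf")),
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Schema check; returns the config with parameter defaults filled in."""
    problems: list[str] = []
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in config or not isinstance(config["seed"], int):
        problems.append("config requires an integer 'seed'")
    if "outdir" not in config or not isinstance(config["outdir"], str):
        problems.append("config requires a string 'outdir'")
    params = dict(config.get("params") or {})
    for key, (default, lo, hi) in _NUMERIC_PARAMS.items():
        val = params.get(key, default)
        if not isinstance(val, (int, float)) or not (lo <= val <= hi):
            problems.append(f"params.{key} must be a number in [{lo}, {hi}], got {val!r}")
        params[key] = val
    unknown = set(params) - set(_NUMERIC_PARAMS)
    if unknown:
        problems.append(f"unknown params keys: {sorted(unknown)}")
    for path_key in ("inputs",):
        for name, path in (config.get(path_key) or {}).items():
            if not Path(path).exists():
                problems.append(f"{path_key}.{name}: no such file {path!r}")
    generator = dict(config.get("generator") or {})
    known_fields = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(generator) - known_fields
    if unknown:
        problems.append(f"unknown generator keys: {sorted(unknown)}")
    if problems:
        raise ConfigError("; ".join(problems))
    out = dict(config)
    out["params"] = params
    out["generator"] = generator
    return out


def _hash_config(config: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict[str, Any], base_dir: str | Path | None = None) -> RunManifest:
    """Run simulate -> score -> xcorr -> cellenrich -> dcq -> pd.

    All stage outputs land under ``outdir``; the manifest (written to
    ``outdir/manifest.json``) lists every output file with its row count.
    Deterministic stages are byte-identical across runs of the same config.
    """
    config = validate_config(config)
    t0 = time.perf_counter()
    outdir = Path(base_dir or ".") / config["outdir"]
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    params = config["params"]
    gen_kwargs = dict(config["generator"])
    gen_kwargs.setdefault("seed", seed)
    gcfg = GeneratorConfig(**gen_kwargs)
    manifest = RunManifest(config_hash=_hash_config(config), seed=seed, version=__version__)

    def record(name: str, inputs: list[Path], outputs: list[Path], rows: dict[str, int], t: float) -> None:
        manifest.stages.append(
            StageRecord(
                name=name,
                inputs=[str(p) for p in inputs],
                outputs=[str(p) for p in outputs],
                rows=rows,
                seconds=round(time.perf_counter() - t, 4),
            )
        )

    # --- simulate -----------------------------------------------------------
    t = time.perf_counter()
    studies = gen_deg_studies(gcfg)
    cohort, truth_labels = gen_cohort_matrix(gcfg)
    mixture, w_true = gen_mixture_foldchange(gcfg)
    ranking_table, planted_ranks = gen_ranked_planting(gcfg)
    pd_table, pd_truth = gen_pd_table(gcfg)

    sim_outputs = []
    for table in studies:
        path = outdir / f"deg_{table.study_id}.tsv"
        write_deg_table(table, path)
        sim_outputs.append(path)
    matrix_path, groups_path = outdir / "cohort_matrix.tsv", outdir / "cohort_groups.tsv"
    write_expression_matrix(cohort, matrix_path, groups_path)
    truth_path = outdir / "cohort_truth.tsv"
    truth_labels.rename_axis("sample").to_frame().to_csv(truth_path, sep="\t")
    fc_path = outdir / "mixture_foldchange.tsv"
    write_fold_change(mixture.fold_change, fc_path)
    comp_path = outdir / "compendium.tsv"
    mixture.compendium.reference.rename_axis("gene").to_csv(comp_path, sep="\t")
    wtruth_path = outdir / "mixture_w_true.tsv"
    w_true.rename_axis("cell_type").to_frame().to_csv(wtruth_path, sep="\t")
    ranking_path = outdir / "deg_ranking.tsv"
    write_deg_table(ranking_table, ranking_path)
    planted_path = outdir / "planted_ranks.tsv"
    planted_ranks.rename_axis("marker").to_frame().to_csv(planted_path, sep="\t")
    pd_path = outdir / "pd_table.tsv"
    write_pd_table(pd_table, pd_path)
    sim_outputs += [matrix_path, groups_path, truth_path, fc_path, comp_path, wtruth_path, ranking_path, planted_path, pd_path]
    record(
        "simulate",
        [],
        sim_outputs,
        {"deg_rows": sum(len(s) for s in studies), "cohort_samples": cohort.shape[1], "pd_rows": len(pd_table.data)},
        t,
    )

    # --- signature scoring --------------------------------------------------
    t = time.perf_counter()
    signature = {"TH17SIG": list(gcfg.signature_genes)}
    scores = score_signatures(cohort, signature)
    assignment = assign_clusters(scores, cutoff=params["cutoff"])
    prevalence = cluster_prevalence(assignment)
    scores_path = outdir / "signature_scores.tsv"
    out = scores.scores.copy()
    out["label"] = assignment.labels
    out.rename_axis("sample").to_csv(scores_path, sep="\t")
    prev_path = outdir / "cluster_prevalence.tsv"
    prevalence.to_csv(prev_path, sep="\t", index=False)
    record("score", [matrix_path, groups_path], [scores_path, prev_path], {"samples": len(out)}, t)

    # --- cross-study correlation -------------------------------------------
    t = time.perf_counter()
    filtered = [filter_degs(s, alpha=params["alpha"]) for s in studies]
    corr = correlation_matrix(filtered)
    corr_path = outdir / "cross_study_correlation.tsv"
    write_correlation_tsv(corr, corr_path)
    record("xcorr", [outdir / f"deg_{s.study_id}.tsv" for s in studies], [corr_path], {"pairs": len(corr.cells)}, t)

    # --- cell enrichment ----------------------------------------------------
    t = time.perf_counter()
    ranked = rank_genes(ranking_table, top_n=int(params["top_n"]))
    markers = GeneSetCollection()
    markers.add(gcfg.planted_cell_type, list(planted_ranks.index))
    enrich = score_all_cell_types(ranked, markers)
    enrich_path = outdir / "cell_enrichment.tsv"
    enrich.to_csv(enrich_path, sep="\t", index=False)
    record("cellenrich", [ranking_path], [enrich_path], {"cell_types": len(enrich)}, t)

    # --- deconvolution ------------------------------------------------------
    t = time.perf_counter()
    quantities = dcq(mixture, repeats=int(params["repeats"]), lambda_min=params["lambda_min"], seed=seed)
    dcq_path = outdir / "dcq_quantities.tsv"
    quantities.quantities.rename_axis("cell_type").to_frame().to_csv(dcq_path, sep="\t")
    # two pseudo-groups from sign-flipped input give the z-score stage work
    flipped = dcq(
        DCQInput(fold_change=-mixture.fold_change, compendium=mixture.compendium),
        repeats=int(params["repeats"]),
        lambda_min=params["lambda_min"],
        seed=seed,
    )
    means, removed = group_average_and_filter(
        {"case": quantities, "reversed": flipped},
        {"case": "case", "reversed": "reversed"},
        threshold=params["filter_threshold"],
    )
    z = zscore_by_celltype(means) if not means.empty else pd.DataFrame()
    z_path = outdir / "dcq_zscores.tsv"
    z.rename_axis("cell_type").to_csv(z_path, sep="\t")
    record("dcq", [fc_path, comp_path], [dcq_path, z_path], {"cell_types": len(quantities.quantities), "filtered_out": len(removed)}, t)

    # --- pharmacodynamics ---------------------------------------------------
    t = time.perf_counter()
    profile = efficacy_profile(pd_table)
    profile_path = outdir / "pd_profile.tsv"
    profile.display.rename_axis("endpoint").to_csv(profile_path, sep="\t")
    hill_rows = []
    for endpoint in ("IL-17", "IL-22"):
        if endpoint in pd_table.endpoints:
            points = exposure_response_points(pd_table, endpoint)
            if len({c for c, _ in points}) >= 3:
                fit = fit_hill(points)
                hill_rows.append({"endpoint": endpoint, "ec50": fit.ec50, "h": fit.h, "i_max": fit.i_max, "rss": fit.rss})
    hill_path = outdir / "pd_hill_fits.tsv"
    pd.DataFrame(hill_rows).to_csv(hill_path, sep="\t", index=False)
    record("pd", [pd_path], [profile_path, hill_path], {"endpoints": len(profile.raw)}, t)

    manifest.wall_clock_seconds = round(time.perf_counter() - t0, 4)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
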