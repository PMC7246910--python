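"""End-to-end pipeline: fixtures -> DE selection -> network -> subnetworks ->
activation -> enrichment -> cohort statistics, driven by one YAML config.

Stages communicate only through files in the results directory, so any stage
can be re-run from its declared inputs.  A manifest records the config hash,
the seed, and a checksum for every artifact; deterministic stages reproduce
identical checksums under an identical config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as adio
from . import __version__
from .cohort import fisher_rx2, group_compare, incidence, lesion_length, summarize
from .diffexpr import Contrast, DEGConfig, contrast_from_conditions, select_genes
from .enrich import cluster_terms, enrich
from .network import BNConfig, coupling_matrix, layout, learn_structure
from .subnet import (
    DEFAULT_CALL_THRESHOLD,
    DEFAULT_MIN_SIZE,
    DEFAULT_RESOLUTION,
    activation_table,
    detect_subnetworks,
)
from .synth import (
    DEFAULT_COHORT_CONFIG,
    DEFAULT_EXPR_CONFIG,
    generate_cohort,
    generate_expression,
)

logger = logging.getLogger("adnet")

__all__ = ["derive_seed", "load_config", "validate_config", "run",
           "write_fixtures", "DEFAULT_CONFIG", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding a stage never perturbs the others."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "paths": {
        "expression": "expression.tsv",
        "sample_sheet": "samples.tsv",
        "gmt": None,
        "cohort": None,
        "lesions": None,
        "output_dir": "results",
    },
    "contrasts": [
        {"name": "BA_vs_DMSO", "group_a": "BA", "group_b": "DMSO"},
        {"name": "Rapa_vs_DMSO", "group_a": "Rapa", "group_b": "DMSO"},
        {"name": "Rapa_effect", "group_a": "BA+Rapa", "group_b": "BA"},
    ],
    "deg": {"p_threshold": 0.01, "fc_upper": 4.0, "fc_lower": 0.25},
    "network": {
        "max_parents": 3,
        "n_restarts": 10,
        "edge_inclusion_threshold": 0.6,
        "layout_iterations": 100,
    },
    "subnetworks": {
        "min_size": DEFAULT_MIN_SIZE,
        "resolution": DEFAULT_RESOLUTION,
        "call_threshold": DEFAULT_CALL_THRESHOLD,
    },
    "enrichment": {"kappa_threshold": 0.5},
    "stats": {"alpha": 0.05},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise adio.FormatError(f"{path}: invalid YAML ({exc})") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise adio.FormatError(f"{path}: config must be a mapping")
    return _merge(DEFAULT_CONFIG, raw)


def validate_config(config: dict, base_dir: str | Path = ".") -> list[str]:
    """Exhaustive validation; an empty list means the config is runnable."""
    base = Path(base_dir)
    problems: list[str] = []
    paths = config.get("paths", {})

    expr_path = paths.get("expression")
    sheet_path = paths.get("sample_sheet")
    for label, p in (("expression", expr_path), ("sample_sheet", sheet_path)):
        if not p:
            problems.append(f"paths.{label} is required")
        elif not (base / p).exists():
            problems.append(f"paths.{label}: file not found: {base / p}")
    for label in ("gmt", "cohort", "lesions"):
        p = paths.get(label)
        if p and not (base / p).exists():
            problems.append(f"paths.{label}: file not found: {base / p}")

    deg = config.get("deg", {})
    if not 0 < deg.get("p_threshold", 0.01) < 1:
        problems.append("deg.p_threshold must lie in (0, 1)")
    if not deg.get("fc_lower", 0.25) < 1:
        problems.append("deg.fc_lower must be < 1")
    if not deg.get("fc_upper", 4.0) > 1:
        problems.append("deg.fc_upper must be > 1")

    net = config.get("network", {})
    if net.get("max_parents", 3) < 1:
        problems.append("network.max_parents must be >= 1")
    if not 0 < net.get("edge_inclusion_threshold", 0.6) < 1:
        problems.append("network.edge_inclusion_threshold must lie in (0, 1)")

    sub = config.get("subnetworks", {})
    if sub.get("call_threshold", DEFAULT_CALL_THRESHOLD) <= 0:
        problems.append("subnetworks.call_threshold must be > 0")

    if not config.get("contrasts"):
        problems.append("at least one contrast is required")

    # contrast labels must resolve against the sample sheet
    if sheet_path and (base / sheet_path).exists():
        try:
            sheet = adio.read_sample_sheet(base / sheet_path)
        except adio.FormatError as exc:
            problems.append(str(exc))
        else:
            known = set(sheet.unique())
            for c in config.get("contrasts", []):
                for side in ("group_a", "group_b"):
                    cond = c.get(side)
                    if cond not in known:
                        problems.append(
                            f"contrast {c.get('name', '?')!r}: "
                            f"unknown condition {cond!r}"
                        )
    return problems


def write_fixtures(
    directory: str | Path,
    seed: int = 0,
    expr_config=None,
    cohort_config=None,
) -> dict[str, Path]:
    """Materialize the default synthetic bundle (expression, sheet, truth,
    cohort, lesions, GMT built from the planted modules, and a ready config).

    ``expr_config``/``cohort_config`` override the default generator settings
    (their seeds are replaced by ones derived from ``seed``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    expr_cfg = dataclasses.replace(
        expr_config or DEFAULT_EXPR_CONFIG, seed=derive_seed(seed, "expr")
    )
    expr, sheet, modules = generate_expression(expr_cfg)
    cohort_cfg = dataclasses.replace(
        cohort_config or DEFAULT_COHORT_CONFIG, seed=derive_seed(seed, "cohort")
    )
    table, records = generate_cohort(cohort_cfg)

    paths = {
        "expression": directory / "expression.tsv",
        "sample_sheet": directory / "samples.tsv",
        "modules": directory / "true_modules.tsv",
        "gmt": directory / "modules.gmt",
        "cohort": directory / "cohort.tsv",
        "lesions": directory / "lesions.tsv",
        "config": directory / "config.yaml",
    }
    adio.write_expression(expr, paths["expression"])
    adio.write_sample_sheet(sheet, paths["sample_sheet"])
    adio.write_module_assignment(modules, paths["modules"])
    adio.write_cohort_table(table, paths["cohort"])
    adio.write_lesion_records(records, paths["lesions"])

    with open(paths["gmt"], "w") as fh:
        for m in range(1, len(expr_cfg.module_sizes) + 1):
            genes = "\t".join(modules.index[modules == m])
            fh.write(f"MODULE{m}\tplanted module {m}\t{genes}\n")

    config = _merge(
        DEFAULT_CONFIG,
        {
            "seed": seed,
            "paths": {
                "expression": paths["expression"].name,
                "sample_sheet": paths["sample_sheet"].name,
                "gmt": paths["gmt"].name,
                "cohort": paths["cohort"].name,
                "lesions": paths["lesions"].name,
                "output_dir": "results",
            },
        },
    )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: dict, base_dir: str | Path = ".") -> dict:
    """Execute all configured stages; returns the manifest dict.

    Stage order: deg -> network -> subnetworks -> activation -> enrichment
    (if a GMT is configured) -> cohort (if cohort tables are configured).
    Partial results stay on disk if a stage fails; the manifest (written
    last on success) records per-artifact checksums.
    """
    problems = validate_config(config, base_dir)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))

    base = Path(base_dir)
    paths = config["paths"]
    out_dir = base / paths.get("output_dir", "results")
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    def emit(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    stage = "load"
    try:
        expr = adio.read_expression(base / paths["expression"])
        sheet = adio.read_sample_sheet(base / paths["sample_sheet"])
        missing = [s for s in expr.columns if s not in sheet.index]
        if missing:
            raise PipelineError(f"samples missing from sheet: {missing[:5]}")
        record(stage, genes=expr.shape[0], samples=expr.shape[1])

        stage = "deg"
        deg_cfg = DEGConfig(**config["deg"])
        contrasts = [
            contrast_from_conditions(sheet, c["group_a"], c["group_b"], c.get("name"))
            for c in config["contrasts"]
        ]
        selected, de_table = select_genes(expr, sheet, contrasts, deg_cfg)
        de_path = out_dir / "de_results.tsv"
        de_table.to_csv(de_path, sep="\t", index=False, float_format="%.6g")
        emit("de_results", de_path)
        record(stage, selected_genes=len(selected), contrasts=len(contrasts))
        if len(selected) < 2:
            raise PipelineError("fewer than 2 genes selected; nothing to learn")

        stage = "network"
        net_conf = config["network"]
        bn_cfg = BNConfig(
            max_parents=net_conf["max_parents"],
            n_restarts=net_conf["n_restarts"],
            edge_inclusion_threshold=net_conf["edge_inclusion_threshold"],
            seed=derive_seed(seed, "network"),
        )
        coup = coupling_matrix(expr, selected)
        network = learn_structure(expr, selected, coup, bn_cfg)
        net_path = out_dir / "network.graphml"
        adio.write_network(network, net_path, dialect="graphml")
        adio.write_network(network, out_dir / "network.sif", dialect="sif")
        emit("network", net_path)
        coords = layout(
            network,
            seed=derive_seed(seed, "layout"),
            iterations=net_conf.get("layout_iterations", 100),
        )
        layout_path = out_dir / "layout.tsv"
        pd.DataFrame(
            [(g, x, y) for g, (x, y) in sorted(coords.items())],
            columns=["gene", "x", "y"],
        ).to_csv(layout_path, sep="\t", index=False, float_format="%.6g")
        emit("layout", layout_path)
        record(stage, nodes=network.number_of_nodes(), edges=network.number_of_edges())

        stage = "subnetworks"
        sub_conf = config["subnetworks"]
        partition = detect_subnetworks(
            network,
            min_size=sub_conf["min_size"],
            resolution=sub_conf["resolution"],
            seed=derive_seed(seed, "subnet"),
        )
        part_path = out_dir / "subnetworks.tsv"
        partition.to_csv(part_path, sep="\t")
        emit("subnetworks", part_path)
        sizes = partition[partition > 0].value_counts().sort_index().to_dict()
        record(stage, subnetworks={int(k): int(v) for k, v in sizes.items()})

        stage = "activation"
        act = activation_table(
            expr, sheet, partition, contrasts, threshold=sub_conf["call_threshold"]
        )
        act_path = out_dir / "activation.tsv"
        act.to_csv(act_path, sep="\t", index=False, float_format="%.6g")
        emit("activation", act_path)
        record(stage, calls=len(act))

        if paths.get("gmt"):
            stage = "enrichment"
            gmt = adio.read_gmt(base / paths["gmt"])
            universe = set(expr.index)
            kappa = config["enrichment"]["kappa_threshold"]
            enr_rows, cluster_rows = [], []
            for sub in sorted(partition[partition > 0].unique()):
                query = set(partition.index[partition == sub])
                results = enrich(query, gmt, universe)
                for _, row in results.iterrows():
                    enr_rows.append((int(sub), *row.drop("members").tolist()))
                for rank, cl in enumerate(cluster_terms(results, kappa), start=1):
                    cluster_rows.append(
                        (int(sub), rank, cl.enrichment_score, ";".join(cl.term_ids))
                    )
            enr_path = out_dir / "enrichment.tsv"
            pd.DataFrame(
                enr_rows,
                columns=[
                    "subnetwork", "term_id", "term_name", "query_size",
                    "universe_size", "term_size", "overlap", "p_value", "p_adjusted",
                ],
            ).to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
            emit("enrichment", enr_path)
            clu_path = out_dir / "annotation_clusters.tsv"
            pd.DataFrame(
                cluster_rows,
                columns=["subnetwork", "cluster", "enrichment_score", "terms"],
            ).to_csv(clu_path, sep="\t", index=False, float_format="%.6g")
            emit("annotation_clusters", clu_path)
            record(stage, terms=len(enr_rows), clusters=len(cluster_rows))

        if paths.get("cohort"):
            stage = "cohort"
            table = adio.read_cohort_table(base / paths["cohort"])
            inc = incidence(table)
            lines = [
                "Incidence (%): "
                + "  ".join(f"{g}: {v}" for g, v in inc.items()),
                f"Exact test over all groups (Freeman-Halton): p = "
                f"{fisher_rx2(table):.4g}",
            ]
            if paths.get("lesions"):
                records = adio.read_lesion_records(base / paths["lesions"])
                lengths: dict[str, list[float]] = {}
                for rec in records:
                    lengths.setdefault(rec.group, []).append(
                        lesion_length(rec)["total"]
                    )
                groups = [g for g in table.groups if len(lengths.get(g, [])) >= 3]
                for g in groups:
                    mean, sem, n = summarize(lengths[g])
                    lines.append(
                        f"Lesion length {g}: {mean:.2f} +/- {sem:.2f} mm (n = {n})"
                    )
                if len(groups) >= 2:
                    report = group_compare(
                        [np.asarray(lengths[g]) for g in groups],
                        names=groups,
                        alpha=config["stats"]["alpha"],
                    )
                    lines.append(f"Severity comparison path: {report.path}")
                    lines.append(f"Omnibus p = {report.omnibus_p:.4g}")
                    pw_path = out_dir / "severity_pairwise.tsv"
                    report.pairwise.to_csv(
                        pw_path, sep="\t", index=False, float_format="%.6g"
                    )
                    emit("severity_pairwise", pw_path)
            cohort_path = out_dir / "cohort_report.txt"
            cohort_path.write_text("\n".join(lines) + "\n")
            emit("cohort_report", cohort_path)
            record(stage, groups=len(table.groups))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
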