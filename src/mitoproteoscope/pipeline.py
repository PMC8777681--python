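"""End-to-end orchestration: simulate -> diff -> rca -> enrich -> assays.

A run is driven by one YAML/JSON config document with per-stage sections,
validated up front (no stage runs on a bad config).  Every output file is a
TSV, PNG image, or JSON and is listed with its SHA-256 digest in the run
manifest, together with the tool version, the config hash, the seeds and all
effective parameters — a run is self-describing and, under a fixed seed,
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import compare_intensity, normalize_growth, quantify_image
from .complex_abundance import paint_structure, rca, read_chain_map
from .core_io import (
    COMMENT_HEADER,
    ValidationError,
    default_complex_definitions,
    log2_transform,
    read_complex_definitions,
    write_annotations,
    write_complex_definitions,
    write_design,
    write_quant_matrix,
)
from .differential import classify_volcano, differential_test, subset_mito, volcano_table
from .enrichment import enrich
from .plots import growth_plot, rca_plot, volcano_plot
from .synthetic import (
    DiseaseProfile,
    ImageDesign,
    PlateDesign,
    default_design,
    generate_annotations,
    generate_growth_plate,
    generate_intensity_image,
    generate_quant_matrix,
)


class ConfigError(ValidationError):
    """The run config violates the schema; raised before any stage runs."""


_STAGES = ("simulate", "differential", "rca", "enrich", "mapstruct", "assays")


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    return config


def validate_config(config: dict) -> dict:
    """Check the config against the schema; returns it with defaults filled."""
    problems: list[str] = []
    known = set(_STAGES) | {"seed", "report"}
    for key in config:
        if key not in known:
            problems.append(f"unknown section {key!r}")
    if "seed" not in config or not isinstance(config["seed"], int):
        problems.append("an integer 'seed' is mandatory")
    sim = config.get("simulate", {})
    if not isinstance(sim, dict):
        problems.append("'simulate' must be a mapping")
        sim = {}
    n_proteins = sim.get("n_proteins", 2000)
    if not isinstance(n_proteins, int) or n_proteins < 1:
        problems.append("simulate.n_proteins must be a positive integer")
    diff = config.get("differential", {})
    if diff.get("variant", "student") not in ("student", "welch"):
        problems.append("differential.variant must be student|welch")
    for key in ("fc_log2", "p_max"):
        value = diff.get(key)
        if value is not None and (not isinstance(value, (int, float)) or value <= 0):
            problems.append(f"differential.{key} must be > 0")
    enr = config.get("enrich", {})
    if enr.get("query", "nominal_down") not in ("down", "up", "nominal_down", "nominal_up"):
        problems.append("enrich.query must be down|up|nominal_down|nominal_up")
    ms = config.get("mapstruct")
    if ms is not None:
        for key in ("structure", "chain_map"):
            if key not in ms:
                problems.append(f"mapstruct.{key} is required when mapstruct is set")
            elif not Path(ms[key]).exists():
                problems.append(f"mapstruct.{key}: no such file {ms[key]!r}")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(COMMENT_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=index_label is not None,
                     index_label=index_label, lineterminator="\n")


def run_pipeline(config: dict, outdir: str | Path, make_plots: bool = True) -> dict:
    """Execute all requested stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``); on a stage
    failure the partial manifest marking completed stages is still written.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    manifest: dict = {
        "tool": "mitoproteoscope",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "started_unix": time.time(),
        "stages": {},
        "outputs": {},
        "counts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    try:
        _run_stages(config, outdir, seed, manifest, record, make_plots)
    finally:
        manifest["finished_unix"] = time.time()
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
        )
    return manifest


def _run_stages(config, outdir: Path, seed, manifest, record, make_plots) -> None:
    sim = config.get("simulate", {})
    diff_cfg = config.get("differential", {})
    enr_cfg = config.get("enrich", {})
    assay_cfg = config.get("assays", {})

    # --- simulate ---------------------------------------------------------
    n_proteins = sim.get("n_proteins", 2000)
    profile = DiseaseProfile(**sim.get("profile", {}))
    complex_defs = (
        read_complex_definitions(sim["complex_definitions"])
        if "complex_definitions" in sim
        else default_complex_definitions()
    )
    design = default_design()
    matrix, truth = generate_quant_matrix(
        n_proteins, design, profile, seed=seed, complex_defs=complex_defs,
        mnar=sim.get("mnar", False),
    )
    annotations = generate_annotations(
        n_proteins,
        complex_defs,
        n_terms=sim.get("n_terms", 50),
        term_size_range=tuple(sim.get("term_size_range", (10, 40))),
        seed=seed + 1,
    )
    write_quant_matrix(matrix, outdir / "quant_matrix.tsv")
    write_design(design, outdir / "design.tsv")
    write_annotations(annotations, outdir / "terms.tsv", outdir / "mito.tsv")
    write_complex_definitions(complex_defs, outdir / "complexes.tsv")
    _write_tsv(truth, outdir / "truth.tsv")
    for name in ("quant_matrix", "design", "terms", "mito", "complexes", "truth"):
        record(name, outdir / f"{name}.tsv")
    manifest["stages"]["simulate"] = {
        "n_proteins": n_proteins,
        "profile": asdict(profile),
        "n_missing": matrix.n_missing,
    }

    # --- differential -----------------------------------------------------
    log2 = log2_transform(matrix)
    result = differential_test(log2, design, variant=diff_cfg.get("variant", "student"))
    result = classify_volcano(
        result,
        fc_log2=diff_cfg.get("fc_log2", 1.0),
        p_max=diff_cfg.get("p_max", 0.05),
    )
    if diff_cfg.get("mito_only", False):
        result = subset_mito(result, annotations)
    _write_tsv(result, outdir / "differential.tsv", index_label="accession")
    record("differential", outdir / "differential.tsv")
    counts = result["class"].value_counts()
    manifest["stages"]["differential"] = {
        "variant": result.attrs["variant"],
        "fc_log2": result.attrs["fc_log2"],
        "p_max": result.attrs["p_max"],
    }
    manifest["counts"]["differential"] = {
        "input": int(len(result)),
        "tested": int((result["class"] != "filtered").sum()),
        "down": int(counts.get("down", 0)),
        "up": int(counts.get("up", 0)),
    }
    if make_plots:
        volcano_plot(volcano_table(result), outdir / "volcano.png", "volcano")
        record("volcano_png", outdir / "volcano.png")

    # --- rca --------------------------------------------------------------
    rca_table = rca(result, complex_defs, ci_level=config.get("rca", {}).get("ci_level", 0.95))
    _write_tsv(rca_table, outdir / "rca.tsv", index_label="complex_id")
    record("rca", outdir / "rca.tsv")
    manifest["stages"]["rca"] = {"ci_level": rca_table.attrs["ci_level"]}
    if make_plots:
        rca_plot(rca_table, outdir / "rca.png", "relative complex abundance")
        record("rca_png", outdir / "rca.png")

    # --- enrich -----------------------------------------------------------
    background = set(result.index[result["class"] != "filtered"])
    query_kind = enr_cfg.get("query", "nominal_down")
    if query_kind in ("down", "up"):
        query = set(result.index[result["class"] == query_kind])
    else:
        direction = result["log2_diff"] < 0 if query_kind.endswith("down") else result["log2_diff"] > 0
        query = set(
            result.index[
                (result["class"] != "filtered")
                & (result["p_value"] <= result.attrs["p_max"])
                & direction
            ]
        )
    enr_table = enrich(
        query, background, annotations,
        min_term_size=enr_cfg.get("min_term_size", 5),
    )
    _write_tsv(enr_table, outdir / "enrichment.tsv")
    record("enrichment", outdir / "enrichment.tsv")
    manifest["stages"]["enrich"] = {"query": query_kind, "n_query": len(query)}
    manifest["counts"]["enrich"] = {
        "background": len(background),
        "query": len(query),
        "terms_tested": int(len(enr_table)),
    }

    # --- mapstruct (optional) --------------------------------------------
    ms = config.get("mapstruct")
    if ms is not None:
        chain_map = read_chain_map(ms["chain_map"])
        residue_map, unmapped = paint_structure(
            result, ms["structure"], chain_map,
            palette_range=tuple(ms.get("palette_range", (-2.0, 2.0))),
            out_path=outdir / "painted_structure.pdb",
        )
        _write_tsv(residue_map, outdir / "structure_map.tsv")
        (outdir / "unmapped_chains.json").write_text(
            json.dumps(unmapped, indent=2) + "\n", encoding="utf-8"
        )
        record("painted_structure", outdir / "painted_structure.pdb")
        record("structure_map", outdir / "structure_map.tsv")
        record("unmapped_chains", outdir / "unmapped_chains.json")
        manifest["stages"]["mapstruct"] = {"n_unmapped_chains": len(unmapped)}

    # --- assays -----------------------------------------------------------
    plate = PlateDesign(**assay_cfg.get("plate", {}))
    growth_params = {
        ("patient", "galactose"): (0.5, 800.0),
        ("patient", "galactose+azide"): (0.3, 600.0),
    }
    growth = generate_growth_plate(
        plate, growth_params, noise_sd=assay_cfg.get("growth_noise_sd", 10.0),
        seed=seed + 2,
    )
    growth = normalize_growth(growth)
    _write_tsv(growth, outdir / "growth.tsv")
    record("growth", outdir / "growth.tsv")
    if make_plots:
        growth_plot(growth, outdir / "growth.png")
        record("growth_png", outdir / "growth.png")

    image_design = ImageDesign(**assay_cfg.get("image", {}))
    n_images = assay_cfg.get("images_per_group", 3)
    mask_rows = []
    for group in sorted(image_design.intensity):
        for i in range(n_images):
            img, _ = generate_intensity_image(
                image_design, group=group, seed=seed + 10 + hash_free(group) + i
            )
            png = outdir / f"image_{group}_{i}.png"
            iio.imwrite(png, np.round(img).astype(np.uint16))
            record(f"image_{group}_{i}", png)
            mask_rows.append(
                quantify_image(img, image_id=png.stem, cell_line=group)
            )
    masks = pd.concat(mask_rows, ignore_index=True)
    _write_tsv(masks, outdir / "mask_intensity.tsv")
    record("mask_intensity", outdir / "mask_intensity.tsv")
    intensity_report = compare_intensity(masks)
    manifest["stages"]["assays"] = {
        "plate": asdict(plate),
        "image": {**asdict(image_design)},
        "intensity_p_overall": intensity_report["p_overall"],
        "intensity_group_means": intensity_report["group_means"],
    }

    # --- report -----------------------------------------------------------
    if config.get("report", True):
        write_report(outdir, manifest)
        record("report", outdir / "report.md")


def hash_free(text: str) -> int:
    """Deterministic small integer from a string (hash() is salted)."""
    return int(hashlib.sha256(text.encode()).hexdigest()[:6], 16) % 1000


def write_report(outdir: Path, manifest: dict) -> None:
    """A Markdown report whose numbers are read back from the stage TSVs."""
    diff = pd.read_csv(outdir / "differential.tsv", sep="\t", comment="#")
    rca_table = pd.read_csv(outdir / "rca.tsv", sep="\t", comment="#")
    enr = pd.read_csv(outdir / "enrichment.tsv", sep="\t", comment="#")
    masks = pd.read_csv(outdir / "mask_intensity.tsv", sep="\t", comment="#")
    counts = diff["class"].value_counts()
    lines = [
        f"# mitoproteoscope run report (v{manifest['version']})",
        "",
        f"Seed: {manifest['seed']}  |  config sha256: `{manifest['config_sha256'][:12]}`",
        "",
        "## Differential abundance",
        f"- proteins: {len(diff)}; tested: {int((diff['class'] != 'filtered').sum())}; "
        f"down: {int(counts.get('down', 0))}; up: {int(counts.get('up', 0))}",
        "",
        "## Relative complex abundance (% of control)",
        "",
        "```",
        rca_table[
            ["complex_id", "n_subunits_used", "ratio_percent",
             "ci_low_percent", "ci_high_percent", "paired_p", "stars"]
        ].round(3).to_string(index=False),
        "```",
        "",
        "## Top enriched terms",
        "",
        "```",
        enr.head(10)[
            ["term_id", "K", "k", "fold_enrichment", "p_one_sided", "q_bh"]
        ].round(4).to_string(index=False),
        "```",
        "",
        "## Superoxide-probe intensity",
        "",
        "```",
        masks.groupby("cell_line")["mean_intensity"].agg(["count", "mean"])
        .round(2).to_string(),
        "```",
        "",
    ]
    (outdir / "report.md").write_text("\n".join(lines), encoding="utf-8")
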