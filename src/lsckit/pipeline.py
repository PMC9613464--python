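"""End-to-end synthetic pipeline driver with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .cnv import (
    compare_adjacent_segments,
    detect_subclonal_pattern,
    gain_pattern_from_means,
    project_segments,
    segment_track,
)
from .cores import build_catalog, call_cores, detection_matrix, rank_predictability
from .lda import estimate_frequency
from .simulate import (
    SimConfig,
    simulate_cn_tracks,
    simulate_expression,
    simulate_lda_assay,
    simulate_peak_atlas,
)
from .stemness import score_hierarchy

__all__ = ["run_pipeline", "simulate_to_dir"]

HIERARCHY = ("tier1", "tier2", "tier3", "tier4")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input the pipeline consumes to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    assay = simulate_lda_assay(
        config.lda_truth, config.lda_doses, config.lda_mice_per_dose, seed=config.seed
    )
    paths["assay"] = outdir / "lda_assay.csv"
    io.write_assay(assay, paths["assay"])

    ref, query = simulate_cn_tracks(config.cn_profile, seed=config.seed)
    paths["cn_reference"] = outdir / "cn_reference.tsv"
    paths["cn_query"] = outdir / "cn_query.tsv"
    io.write_cn(ref, paths["cn_reference"])
    io.write_cn(query, paths["cn_query"])

    atlas, groups = simulate_peak_atlas(config)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    sheet_rows = []
    for sample_id, cres in atlas.items():
        p = peak_dir / f"{sample_id}.bed"
        io.write_bed(cres.peaks, p)
        # paths relative to the sheet keep the directory relocatable and
        # the outputs byte-identical across run locations
        sheet_rows.append(f"{sample_id}\tpeaks/{sample_id}.bed\t{groups[sample_id]}")
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    paths["sample_sheet"].write_text(
        "sample_id\tpath\tgroup\n" + "\n".join(sheet_rows) + "\n"
    )
    paths["groups"] = outdir / "groups.json"
    io.write_groups(groups, paths["groups"])

    matrix, signature, reference, fractions = simulate_expression(
        config.expression_block, seed=config.seed
    )
    paths["expression"] = outdir / "expression.tsv"
    io.write_matrix(matrix, paths["expression"])
    paths["signature"] = outdir / "signature.gmt"
    io.write_gmt({signature.name: signature}, paths["signature"])
    paths["reference"] = outdir / "reference_profile.tsv"
    reference.rename_axis("gene").to_csv(paths["reference"], sep="\t", header=["value"])
    paths["fractions"] = outdir / "fractions.json"
    io.write_groups(fractions, paths["fractions"])
    return paths


def run_pipeline(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate inputs, run every stage, and write outputs plus a manifest.

    The manifest records the package version, the full configuration, the
    seed and a SHA-256 per output file; identical (config, seed) pairs
    reproduce byte-identical outputs and therefore an identical manifest
    hash.
    """
    outdir = Path(outdir)
    inputs = simulate_to_dir(config, outdir / "inputs")
    results_dir = outdir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # limiting dilution
    assay = io.read_assay(inputs["assay"])
    est = estimate_frequency(assay)
    outputs["lda"] = results_dir / "lda_estimate.json"
    outputs["lda"].write_text(
        json.dumps(
            {
                "f_hat": est.f_hat,
                "denom_hat": est.denom_hat,
                "ci_denom": est.ci_denom,
                "se_log_f": est.se_log_f,
                "boundary_flag": est.boundary_flag,
            },
            indent=1,
        )
        + "\n"
    )

    # subclone detection
    ref = io.read_cn(inputs["cn_reference"])
    query = io.read_cn(inputs["cn_query"])
    segments = segment_track(ref)
    ref_proj, _ = project_segments(segments, ref)
    ref_means = [float(np.mean(v)) for _l, _s, _e, v in ref_proj]
    pattern = gain_pattern_from_means(ref_means)
    projection, _ = project_segments(segments, query)
    comparisons = compare_adjacent_segments(projection)
    verdict = detect_subclonal_pattern(comparisons, pattern)
    outputs["cnv"] = results_dir / "adjacent_comparisons.tsv"
    pd.DataFrame(
        [
            {
                "pair": c.pair,
                "p_value": c.p_value,
                "significance": c.significance,
                "direction": c.direction,
            }
            for c in comparisons
        ]
    ).to_csv(outputs["cnv"], sep="\t", index=False)
    outputs["cnv_verdict"] = results_dir / "subclone_verdict.json"
    outputs["cnv_verdict"].write_text(json.dumps(verdict, indent=1) + "\n")

    # CORE discovery and discrimination
    sheet = io.read_sample_sheet(inputs["sample_sheet"])
    groups = {row["sample_id"]: row["group"] for row in sheet}
    per_sample = {}
    for row in sheet:
        cres = io.read_cre_set(row["path"], row["sample_id"], row["group"])
        per_sample[row["sample_id"]] = call_cores(cres)
    catalog = build_catalog(per_sample)
    dm = detection_matrix(catalog, per_sample, groups)
    ranking = rank_predictability(dm)
    outputs["cores"] = results_dir / "core_predictability.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in ranking]).to_csv(
        outputs["cores"], sep="\t", index=False
    )

    # stemness scoring
    matrix = io.read_matrix(inputs["expression"])
    signature = next(iter(io.read_gmt(inputs["signature"]).values()))
    reference = pd.read_csv(inputs["reference"], sep="\t", index_col=0)["value"]
    fractions = io.read_groups(inputs["fractions"])
    scores, monotone = score_hierarchy(
        matrix, fractions, signature, reference, HIERARCHY, weighted_missing="drop"
    )
    outputs["stemness"] = results_dir / "stemness_scores.tsv"
    scores.to_csv(outputs["stemness"], sep="\t")
    outputs["stemness_monotone"] = results_dir / "stemness_monotonicity.json"
    outputs["stemness_monotone"].write_text(json.dumps(monotone, indent=1) + "\n")

    manifest = {
        "lsckit_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "files": {
            name: _file_hash(path)
            for name, path in sorted({**inputs, **outputs}.items())
        },
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
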