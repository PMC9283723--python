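"""End-to-end orchestration of the dual-enzyme screen analysis.

Stages run in assay order — QC -> stack correction -> normalization ->
concentration-response fitting -> hit calling -> cross-enzyme selectivity —
with two independent branches: substrate-depletion kinetics and
chemical-space enrichment.  A failure inside one branch is recorded in the
run manifest and does not abort the others.  Every output CSV carries the
config hash and seed in its header; reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemspace, crc, depletion, plates, selectivity, synthetic
from .config import ENZYMES, PipelineConfig
from .io import plates_to_frame, write_csv

logger = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    """In-memory results of one pipeline run, plus the output manifest."""

    config: PipelineConfig
    ground_truth: pd.DataFrame | None = None
    qc: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    crc_results: pd.DataFrame | None = None
    selectivity: pd.DataFrame | None = None
    kinetics: pd.DataFrame | None = None
    substrate_classes: pd.DataFrame | None = None
    substrate_summary: dict | None = None
    enrichment: pd.DataFrame | None = None
    descriptor_summary: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> ResultBundle:
    """Run the full synthetic-mode pipeline under ``config``.

    When ``outdir`` is given, every stage's table is written as CSV and a
    ``manifest.json`` records seed, config hash, per-stage row counts and any
    branch failures.
    """
    cfg_hash = config.config_hash()
    seeds = _child_seeds(config.seed, 6)
    bundle = ResultBundle(config=config)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "stages": {},
        "errors": {},
    }
    syn = config.synthetic

    # -- generation ------------------------------------------------------
    library = synthetic.generate_library(
        n_compounds=syn.n_compounds,
        n_clusters=syn.n_clusters,
        seed=seeds[0],
        n_bits=syn.n_fingerprint_bits,
    )
    bundle.ground_truth = synthetic.ground_truth_table(library)

    spec = synthetic.PlateSpec(
        n_rows=syn.wells_per_plate_rows,
        n_cols=syn.wells_per_plate_cols,
        concentration_series=config.titration.concentrations(),
        n_dmso_plates_leading=syn.n_dmso_plates_leading,
        n_dmso_plates_trailing=syn.n_dmso_plates_trailing,
        noise_cv=syn.noise_cv,
    )

    # -- inhibition branch ----------------------------------------------
    try:
        qc_frames, norm_frames = [], []
        stacks = {}
        for i, enzyme in enumerate(ENZYMES):
            stack = synthetic.generate_plate_stack(
                library, spec, enzyme, mu_dmso=syn.mu_dmso, mu_pos=syn.mu_pos,
                seed=seeds[1] + i,
            )
            stacks[enzyme] = stack
            qc_frames.append(plates.qc_report(stack, config.qc))
            corrected = plates.correct_plate_stack(stack)
            norm_frames.append(plates.normalize_stack(corrected))
        bundle.qc = pd.concat(qc_frames, ignore_index=True)
        bundle.normalized = pd.concat(norm_frames, ignore_index=True)
        series = plates.assemble_concentration_series(bundle.normalized)
        bundle.crc_results = crc.analyze_series(series, config.hit)
        bundle.selectivity = selectivity.selectivity_table(
            bundle.crc_results, config.selectivity
        )
        manifest["stages"]["crc"] = len(bundle.crc_results)
        manifest["stages"]["selectivity"] = len(bundle.selectivity)
    except Exception as exc:  # branch isolation
        logger.exception("inhibition branch failed")
        manifest["errors"]["inhibition"] = repr(exc)

    # -- depletion branch ------------------------------------------------
    try:
        panel = synthetic.generate_depletion_panel(
            library,
            time_points_min=config.depletion.time_points_min,
            noise_cv=syn.noise_cv,
            seed=seeds[2],
        )
        bundle.kinetics = depletion.fit_depletion_panel(
            panel, config.substrate, config.depletion
        )
        bundle.substrate_classes = depletion.substrate_classification_table(
            bundle.kinetics, config.substrate
        )
        bundle.substrate_summary = depletion.summarize_substrate_table(
            bundle.substrate_classes, config.substrate
        )
        manifest["stages"]["kinetics"] = len(bundle.kinetics)
    except Exception as exc:
        logger.exception("depletion branch failed")
        manifest["errors"]["depletion"] = repr(exc)

    # -- chemical-space branch -------------------------------------------
    try:
        ids, fp = synthetic.fingerprint_matrix(library)
        rows, cols = chemspace.grid_shape_for(len(ids), config.som)
        grid = chemspace.train_som(
            fp, rows, cols, topology=config.som.topology,
            epochs=config.som.epochs, seed=seeds[3],
        )
        assignment = chemspace.assign_clusters(fp, grid)
        if bundle.crc_results is not None and len(bundle.crc_results):
            res7 = bundle.crc_results[bundle.crc_results["enzyme"] == "CYP3A7"]
            active_map = dict(zip(res7["compound_id"], res7["activity"] == "active"))
            active = np.array([bool(active_map.get(c, False)) for c in ids])
        else:
            truth = {c.compound_id: c.truth["CYP3A7"].direction != "inactive" for c in library}
            active = np.array([truth[c] for c in ids])
        bundle.enrichment = chemspace.fisher_enrichment(assignment, active, grid)
        desc = synthetic.generate_descriptor_table(library, seed=seeds[4])
        with_groups = desc[desc["group"].isin(["common", "CYP3A4", "CYP3A7"])]
        bundle.descriptor_summary, _ = chemspace.compare_descriptor_groups(
            with_groups.drop(columns=["compound_id"]), group_col="group"
        )
        manifest["stages"]["enrichment"] = len(bundle.enrichment)
    except Exception as exc:
        logger.exception("chemical-space branch failed")
        manifest["errors"]["chemspace"] = repr(exc)

    # -- persist ---------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "ground_truth.csv": bundle.ground_truth,
            "plate_qc.csv": bundle.qc,
            "normalized_wells.csv": bundle.normalized,
            "crc_results.csv": bundle.crc_results,
            "selectivity.csv": bundle.selectivity,
            "depletion_kinetics.csv": bundle.kinetics,
            "substrate_classes.csv": bundle.substrate_classes,
            "cluster_enrichment.csv": bundle.enrichment,
            "descriptor_groups.csv": bundle.descriptor_summary,
        }
        for name, df in tables.items():
            if df is not None:
                write_csv(df, outdir / name, cfg_hash, config.seed)
                manifest["stages"][name] = len(df)
        if bundle.substrate_summary is not None:
            (outdir / "substrate_summary.json").write_text(
                json.dumps(bundle.substrate_summary, indent=2, sort_keys=True)
            )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle.manifest = manifest
    return bundle


def simulate_to_csv(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the synthetic inputs only (no analysis) and write them."""
    outdir = Path(outdir)
    seeds = _child_seeds(config.seed, 6)
    syn = config.synthetic
    library = synthetic.generate_library(
        n_compounds=syn.n_compounds, n_clusters=syn.n_clusters,
        seed=seeds[0], n_bits=syn.n_fingerprint_bits,
    )
    spec = synthetic.PlateSpec(
        n_rows=syn.wells_per_plate_rows,
        n_cols=syn.wells_per_plate_cols,
        concentration_series=config.titration.concentrations(),
        n_dmso_plates_leading=syn.n_dmso_plates_leading,
        n_dmso_plates_trailing=syn.n_dmso_plates_trailing,
        noise_cv=syn.noise_cv,
    )
    cfg_hash = config.config_hash()
    paths = {}
    for i, enzyme in enumerate(ENZYMES):
        stack = synthetic.generate_plate_stack(
            library, spec, enzyme, mu_dmso=syn.mu_dmso, mu_pos=syn.mu_pos,
            seed=seeds[1] + i,
        )
        paths[f"plates_{enzyme}"] = write_csv(
            plates_to_frame(stack), outdir / f"plates_{enzyme}.csv", cfg_hash, config.seed
        )
    panel = synthetic.generate_depletion_panel(
        library, time_points_min=config.depletion.time_points_min,
        noise_cv=syn.noise_cv, seed=seeds[2],
    )
    paths["depletion"] = write_csv(panel, outdir / "depletion_panel.csv", cfg_hash, config.seed)
    ids, fp = synthetic.fingerprint_matrix(library)
    fp_df = pd.DataFrame(
        {"compound_id": ids, "fingerprint": ["".join(map(str, row)) for row in fp]}
    )
    paths["fingerprints"] = write_csv(fp_df, outdir / "fingerprints.csv", cfg_hash, config.seed)
    desc = synthetic.generate_descriptor_table(library, seed=seeds[4])
    paths["descriptors"] = write_csv(desc, outdir / "descriptors.csv", cfg_hash, config.seed)
    paths["ground_truth"] = write_csv(
        synthetic.ground_truth_table(library), outdir / "ground_truth.csv", cfg_hash, config.seed
    )
    return paths
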