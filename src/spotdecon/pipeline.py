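"""End-to-end orchestration of the five pipeline stages.

reference -> nucleus assignment -> deconvolution -> decomposition ->
imputation, driven by a single JSON config. Every stochastic stage gets a
seed derived deterministically from the master seed and the stage name so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from spotdecon import __version__
from spotdecon.decomposition import (
    composition_from_counts,
    composition_from_threshold,
    decompose_all,
    annotate_in_spot_nuclei,
)
from spotdecon.deconvolution import fit_deconvolution
from spotdecon.evaluation import merge_iscrna_to_pseudo_spots
from spotdecon.geometry import assign_nuclei_to_spots
from spotdecon.imputation import (
    annotate_out_spot_nuclei,
    export_pseudo_image,
    fit_proportion_field,
    impute_out_spot_cells,
)
from spotdecon.io import (
    PipelineConfig,
    cpm_normalize,
    intersect_genes,
    read_counts,
    read_nuclei,
    read_spot_geometry,
    write_counts,
)
from spotdecon.reference import build_signature, select_markers

logger = logging.getLogger("spotdecon")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    return (master_seed + zlib.crc32(stage.encode())) % (2**31)


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict[str, str]
    outputs: dict[str, str]
    seeds: dict[str, int]
    version: str

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Run all stages; returns the manifest written to ``out_dir``.

    Required config keys: ``st_mtx``, ``st_rows``, ``st_genes``,
    ``positions_csv``, ``scalefactors_json``, ``scrna_mtx``,
    ``scrna_rows``, ``scrna_genes``, ``labels_csv``. Optional:
    ``nuclei_csv`` (absent -> image-free threshold branch), ``seed`` and
    any :class:`PipelineConfig` field under ``params``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = PipelineConfig(**config.get("params", {}))
    master_seed = int(config.get("seed", params.seed))
    seeds = {
        s: stage_seed(master_seed, s)
        for s in ("deconvolution", "decomposition", "imputation")
    }

    input_keys = [
        "st_mtx", "st_rows", "st_genes", "positions_csv", "scalefactors_json",
        "scrna_mtx", "scrna_rows", "scrna_genes", "labels_csv",
    ]
    missing = [k for k in input_keys if k not in config]
    if missing:
        raise ValueError(f"config missing keys: {missing}")
    hashes = {k: _file_hash(config[k]) for k in input_keys if Path(config[k]).exists()}
    if "nuclei_csv" in config:
        hashes["nuclei_csv"] = _file_hash(config["nuclei_csv"])

    outputs: dict[str, str] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # --- stage 1: reference -------------------------------------------------
    _stage("reference")
    X = read_counts(config["st_mtx"], config["st_rows"], config["st_genes"])
    Y = read_counts(
        config["scrna_mtx"], config["scrna_rows"], config["scrna_genes"],
        labels_path=config["labels_csv"],
    )
    X, Y = intersect_genes(X, Y)
    Y_cpm = cpm_normalize(Y)
    stats_table, markers = select_markers(
        Y_cpm,
        l_fold=params.l_fold,
        l_lambda=params.l_lambda,
        l_cover=params.l_cover,
        v=params.v,
        n_select=params.n_select,
    )
    sig_m = build_signature(Y, markers)
    sig_full = build_signature(Y)
    stats_table.to_csv(out / "marker_stats.csv", index=False)
    sig_m.to_csv(out / "signature_markers.csv")
    sig_full.to_csv(out / "signature_full.csv")
    outputs["signature_markers"] = str(out / "signature_markers.csv")
    outputs["signature_full"] = str(out / "signature_full.csv")

    # --- stage 2: geometry / nuclei ----------------------------------------
    _stage("assignment")
    geometry = read_spot_geometry(config["positions_csv"], config["scalefactors_json"])
    assignment = None
    if "nuclei_csv" in config:
        nuclei = read_nuclei(config["nuclei_csv"])
        assignment = assign_nuclei_to_spots(nuclei, geometry)

    # --- stage 3: deconvolution --------------------------------------------
    _stage("deconvolution")
    X_m = X.subset_genes([g for g in sig_m.gene_ids])
    dconf = PipelineConfig(
        **{**config.get("params", {}), "seed": seeds["deconvolution"]}
    )
    result = fit_deconvolution(X_m.matrix, sig_m, dconf, spot_ids=X.row_ids)
    prop = pd.DataFrame(result.P, index=X.row_ids, columns=sig_m.type_ids)
    prop.to_csv(out / "proportions.csv")
    pd.DataFrame({"gene": sig_m.gene_ids, "r": result.r}).to_csv(
        out / "batch_effects.csv", index=False
    )
    outputs["proportions"] = str(out / "proportions.csv")
    outputs["batch_effects"] = str(out / "batch_effects.csv")

    # --- stage 4: decomposition --------------------------------------------
    _stage("decomposition")
    if assignment is not None:
        composition = composition_from_counts(
            assignment, result.P, X.row_ids, sig_m.type_ids
        )
        typed_nuclei = annotate_in_spot_nuclei(
            assignment, composition, seed=seeds["decomposition"]
        )
        decomposed, cells = decompose_all(
            X.matrix, composition, sig_full, nuclei=typed_nuclei,
            mode=params.cell_mode, seed=seeds["decomposition"],
        )
        write_counts(
            _cells_to_counts(cells), out, prefix="iscrna"
        )
        cells.to_frame().to_csv(out / "iscrna_cells.csv", index=False)
        outputs["iscrna_cells"] = str(out / "iscrna_cells.csv")
        pseudo = merge_iscrna_to_pseudo_spots(cells)
        outputs["pseudo_spots"] = str(write_counts(pseudo, out, prefix="pseudo")["mtx"])
    else:
        # image-free branch: thresholded proportions, spot-level decomposition
        composition = composition_from_threshold(
            result.P, X.row_ids, sig_m.type_ids, params.l_p
        )
        typed_nuclei = None
        decomposed, _ = decompose_all(
            X.matrix, composition, sig_full, nuclei=None, mode="expected",
            seed=seeds["decomposition"],
        )
        pd.DataFrame(
            composition.p_tilde, index=X.row_ids, columns=sig_m.type_ids
        ).to_csv(out / "proportions_thresholded.csv")
        outputs["proportions_thresholded"] = str(out / "proportions_thresholded.csv")

    # --- stage 5: imputation ------------------------------------------------
    if assignment is not None:
        _stage("imputation")
        field = fit_proportion_field(geometry, composition, params)
        typed_all = annotate_out_spot_nuclei(
            typed_nuclei, field, seed=seeds["imputation"]
        )
        imputed = impute_out_spot_cells(
            typed_all, decomposed, composition, geometry, sig_full.gene_ids, params
        )
        imputed.to_frame().to_csv(out / "imputed_cells.csv", index=False)
        palette = {t: f"C{i % 10}" for i, t in enumerate(sig_m.type_ids)}
        export_pseudo_image(typed_all, palette, out / "nuclei_typed.csv")
        outputs["nuclei_typed"] = str(out / "nuclei_typed.csv")
        outputs["imputed_cells"] = str(out / "imputed_cells.csv")

    manifest = RunManifest(
        config={**config, "params": asdict(params), "seed": master_seed},
        input_hashes=hashes,
        outputs=outputs,
        seeds=seeds,
        version=__version__,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _cells_to_counts(cells):
    from spotdecon.io import AnnotatedCounts

    return AnnotatedCounts(
        matrix=cells.expression,
        row_ids=list(cells.cell_ids),
        gene_ids=list(cells.gene_ids),
    )
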