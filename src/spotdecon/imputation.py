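"""Spatial imputation for nuclei outside capture areas.

Cell-type proportions are carried to arbitrary coordinates by one Gaussian
process per type over spot centers (squared-exponential kernel, shared
hyperparameters), clipped and renormalized to a simplex. Expression for
out-spot nuclei is imputed by Gaussian-kernel smoothing of per-cell
expected type profiles from nearby spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from spotdecon.decomposition import CellProfileSet, DecomposedSpot, SpotComposition
from spotdecon.io import NucleusSet, PipelineConfig, SpotGeometry, ValidationError

logger = logging.getLogger("spotdecon")


@dataclass
class ProportionField:
    """Per-type GP regressions over 2-D spot coordinates."""

    models: list[GaussianProcessRegressor]
    type_ids: list[str]
    length_scale_px: float
    noise: float
    slide_average: np.ndarray  # fallback simplex

    def predict_raw(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return np.column_stack([m.predict(coords) for m in self.models])


def default_length_scale(geometry: SpotGeometry) -> float:
    """Twice the spot pitch (median nearest-neighbor center distance)."""
    if geometry.n_spots < 2:
        return geometry.spot_diameter_px * 2
    tree = cKDTree(geometry.centers)
    d, _ = tree.query(geometry.centers, k=2)
    pitch = float(np.median(d[:, 1]))
    return 2.0 * pitch


def fit_proportion_field(
    geometry: SpotGeometry,
    composition: SpotComposition,
    config: PipelineConfig | None = None,
) -> ProportionField:
    """Fit one GP per cell type with targets p_tilde at spot centers."""
    config = config or PipelineConfig()
    keep = geometry.in_tissue
    centers = geometry.centers[keep]
    if centers.shape[0] < 10:
        raise ValidationError("need >= 10 in-tissue spots to fit the field")
    if np.allclose(centers, centers[0]):
        raise ValidationError("degenerate geometry: all spot centers identical")
    spot_index = {s: i for i, s in enumerate(composition.spot_ids)}
    rows = [spot_index[s] for s, k in zip(geometry.spot_ids, keep) if k]
    targets = composition.p_tilde[rows]

    ls = config.gp_length_scale or default_length_scale(geometry)
    kernel = ConstantKernel(1.0, constant_value_bounds=(1e-3, 1e3)) * RBF(
        length_scale=ls, length_scale_bounds=(ls * 0.1, ls * 10)
    )
    optimizer = "fmin_l_bfgs_b" if config.optimize_gp else None
    models = []
    for t in range(targets.shape[1]):
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=max(config.gp_noise, 1e-12),
            optimizer=optimizer,
            normalize_y=True,
            random_state=0,
        )
        gp.fit(centers, targets[:, t])
        models.append(gp)
    avg = targets.mean(axis=0)
    avg = avg / avg.sum() if avg.sum() > 0 else np.full_like(avg, 1 / len(avg))
    return ProportionField(
        models=models,
        type_ids=list(composition.type_ids),
        length_scale_px=float(ls),
        noise=float(config.gp_noise),
        slide_average=avg,
    )


def predict_proportions(field: ProportionField, coords: np.ndarray) -> np.ndarray:
    """Simplex-valued predictions at query coordinates.

    Per-type GP means are clipped to [0, 1] then renormalized; all-zero
    rows fall back to the slide-average composition.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.all(np.isfinite(coords)):
        raise ValidationError("query coordinates must be finite")
    raw = np.clip(field.predict_raw(coords), 0.0, 1.0)
    totals = raw.sum(axis=1)
    degenerate = totals <= 0
    if degenerate.any():
        logger.info(
            "predict_proportions: %d all-zero predictions fell back to slide average",
            int(degenerate.sum()),
        )
        raw[degenerate] = field.slide_average
        totals = raw.sum(axis=1)
    return raw / totals[:, None]


def annotate_out_spot_nuclei(
    nuclei: NucleusSet, field: ProportionField, seed: int = 0
) -> NucleusSet:
    """Draw a type for every out-spot nucleus from its predicted simplex."""
    rng = np.random.default_rng(seed)
    types = list(nuclei.assigned_type) if nuclei.assigned_type else [None] * nuclei.n_nuclei
    out_idx = [
        i
        for i, s in enumerate(nuclei.assigned_spot or [None] * nuclei.n_nuclei)
        if s is None
    ]
    if out_idx:
        probs = predict_proportions(field, nuclei.coords[out_idx])
        for row, i in enumerate(out_idx):
            types[i] = field.type_ids[rng.choice(len(field.type_ids), p=probs[row])]
    return NucleusSet(
        nucleus_ids=list(nuclei.nucleus_ids),
        coords=nuclei.coords.copy(),
        assigned_spot=list(nuclei.assigned_spot) if nuclei.assigned_spot else None,
        assigned_type=types,
    )


def impute_cell_expression(
    coord: np.ndarray,
    cell_type: str,
    decomposed: list[DecomposedSpot],
    composition: SpotComposition,
    geometry: SpotGeometry,
    config: PipelineConfig | None = None,
    bandwidth: Optional[float] = None,
) -> np.ndarray:
    """Kernel-smoothed expected per-cell profile of ``cell_type`` at ``coord``.

    Averages the expected per-cell profiles (U_t / n_t) of the k nearest
    spots containing the type, with Gaussian weights of the given bandwidth
    (default: the GP length scale default for this geometry).
    """
    config = config or PipelineConfig()
    if cell_type not in composition.type_ids:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    t = composition.type_ids.index(cell_type)
    spot_pos = {s: geometry.centers[i] for i, s in enumerate(geometry.spot_ids)}
    profiles = []
    centers = []
    for i, d in enumerate(decomposed):
        if composition.n[i, t] > 0:
            profiles.append(d.U[t] / composition.n[i, t])
            centers.append(spot_pos[d.spot_id])
    if not profiles:
        raise ValidationError(f"type {cell_type!r} absent from every decomposed spot")
    profiles = np.vstack(profiles)
    centers = np.vstack(centers)
    h = bandwidth if bandwidth is not None else (
        config.gp_length_scale or default_length_scale(geometry)
    )
    coord = np.asarray(coord, dtype=float).reshape(2)
    dist = np.linalg.norm(centers - coord[None, :], axis=1)
    k = min(config.k_neighbors, len(dist))
    nearest = np.argsort(dist)[:k]
    d_near = dist[nearest]
    w = np.exp(-0.5 * (d_near / max(h, 1e-12)) ** 2)
    if w.sum() <= 0:
        w = np.ones_like(w)  # far-field: plain average of the k nearest
    w = w / w.sum()
    return w @ profiles[nearest]


def impute_out_spot_cells(
    nuclei: NucleusSet,
    decomposed: list[DecomposedSpot],
    composition: SpotComposition,
    geometry: SpotGeometry,
    gene_ids: list[str],
    config: PipelineConfig | None = None,
) -> CellProfileSet:
    """Impute expression for every typed out-spot nucleus."""
    config = config or PipelineConfig()
    ids, types, coords, rows = [], [], [], []
    for i, s in enumerate(nuclei.assigned_spot or []):
        if s is not None:
            continue
        t_label = nuclei.assigned_type[i]
        rows.append(
            impute_cell_expression(
                nuclei.coords[i], t_label, decomposed, composition, geometry, config
            )
        )
        ids.append(nuclei.nucleus_ids[i])
        types.append(t_label)
        coords.append(tuple(nuclei.coords[i]))
    expression = np.vstack(rows) if rows else np.empty((0, len(gene_ids)))
    return CellProfileSet(
        cell_ids=ids,
        spots=[None] * len(ids),
        types=types,
        coords=np.asarray(coords, dtype=float).reshape(-1, 2),
        expression=expression,
        gene_ids=list(gene_ids),
        provenance=["imputed"] * len(ids),
    )


def export_pseudo_image(
    nuclei: NucleusSet,
    palette: dict[str, str],
    out_csv,
    out_png=None,
    provenance: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Write the typed nucleus table and optionally a rendered overlay."""
    if nuclei.assigned_type is None or any(t is None for t in nuclei.assigned_type):
        raise ValidationError("all nuclei must be typed before export")
    missing = sorted(set(nuclei.assigned_type) - set(palette))
    if missing:
        raise ValidationError(f"palette missing types: {missing}")
    table = pd.DataFrame(
        {
            "nucleus_id": nuclei.nucleus_ids,
            "x": nuclei.coords[:, 0],
            "y": nuclei.coords[:, 1],
            "assigned_spot": [
                "" if s is None else s
                for s in (nuclei.assigned_spot or [None] * nuclei.n_nuclei)
            ],
            "assigned_type": nuclei.assigned_type,
            "provenance": provenance
            or [
                "decomposed" if s is not None else "imputed"
                for s in (nuclei.assigned_spot or [None] * nuclei.n_nuclei)
            ],
        }
    )
    table.to_csv(out_csv, index=False)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for t, color in palette.items():
            mask = np.asarray(nuclei.assigned_type) == t
            ax.scatter(
                nuclei.coords[mask, 0], nuclei.coords[mask, 1], s=4, c=color, label=t
            )
        ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.legend(markerscale=3, fontsize=6)
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return table
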