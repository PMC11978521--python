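"""Synthetic spatial transcriptomics with known ground truth.

Builds slide geometry with planted per-spot type counts, scatters nuclei
inside and outside spots, samples annotated scRNA cells into spots, and
corrupts the counts with gene-wise batch effects, artificial zeros and
multiplicative noise at three severity presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from spotdecon.io import AnnotatedCounts, NucleusSet, SpotGeometry, ValidationError

# (sigma_r, pi_0, sigma_n) per severity level
NOISE_PRESETS: dict[str, tuple[float, float, float]] = {
    "none": (0.0, 0.0, 0.0),
    "small": (0.1, 0.05, 0.05),
    "medium": (0.3, 0.10, 0.10),
    "large": (0.5, 0.20, 0.20),
}


@dataclass
class TruthPattern:
    """Planted slide layout: geometry, per-spot type counts and nuclei."""

    geometry: SpotGeometry
    n: np.ndarray  # (S, T) integer type counts
    type_ids: list[str]
    nuclei: NucleusSet  # typed, spot-assigned where inside a spot
    seed: int
    expected_weights: Optional[np.ndarray] = None  # (S, T) smooth pattern field

    @property
    def P_true(self) -> np.ndarray:
        totals = self.n.sum(axis=1, keepdims=True)
        P = np.divide(self.n, totals, out=np.zeros_like(self.n, dtype=float), where=totals > 0)
        return P


@dataclass
class SimulationTruth:
    """Bookkeeping recorded while simulating spot counts."""

    sampled_cells: list[list[int]]  # per spot: row indices into Y
    n: np.ndarray  # (S, T)
    P_true: np.ndarray
    r_true: np.ndarray  # (G,) planted log2 batch effects
    zero_mask_rate: float
    noise_level: str
    seed: int
    type_ids: list[str] = field(default_factory=list)
    clean_matrix: Optional[np.ndarray] = None  # pre-corruption spot sums


def hex_grid(S: int, pitch_px: float = 100.0) -> np.ndarray:
    """Approximately square arrangement of ``S`` hex-packed centers."""
    cols = int(np.ceil(np.sqrt(S)))
    centers = []
    row = 0
    while len(centers) < S:
        offset = (pitch_px / 2) if row % 2 else 0.0
        for c in range(cols):
            if len(centers) >= S:
                break
            centers.append((offset + c * pitch_px, row * pitch_px * np.sqrt(3) / 2))
        row += 1
    return np.asarray(centers, dtype=float) + pitch_px  # margin from origin


def generate_truth_pattern(
    S: int,
    T: int,
    pattern: str = "uniform",
    seed: int = 0,
    mean_cells_per_spot: float = 10.0,
    pitch_px: float = 100.0,
    spot_diameter_px: float = 65.0,
    microns_per_px: float = 0.65,
    out_spot_density: float = 0.3,
    grid: str = "hex",
) -> TruthPattern:
    """Plant a spatial cell-type pattern on a slide.

    ``pattern`` is one of ``uniform`` (every spot the same expected
    composition), ``blocks`` (left/right halves restricted to overlapping
    type windows) or ``gaussian-bumps`` (each type concentrated around a
    random center). Nuclei are scattered uniformly inside each spot to
    match its planted count, plus out-spot nuclei at
    ``out_spot_density`` x (nuclei per spot area) elsewhere.
    """
    if S < 4:
        raise ValidationError("need at least 4 spots")
    if pattern not in ("uniform", "blocks", "gaussian-bumps"):
        raise ValidationError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    if grid == "hex":
        centers = hex_grid(S, pitch_px)
    elif grid == "square":
        cols = int(np.ceil(np.sqrt(S)))
        centers = np.asarray(
            [((i % cols) * pitch_px, (i // cols) * pitch_px) for i in range(S)],
            dtype=float,
        ) + pitch_px
    else:
        raise ValidationError(f"unknown grid {grid!r}")
    type_ids = [f"type{t}" for t in range(T)]

    N = rng.poisson(mean_cells_per_spot, size=S)
    N = np.maximum(N, 1)
    weights = np.zeros((S, T))
    if pattern == "uniform":
        weights[:] = 1.0 / T
    elif pattern == "blocks":
        mid = np.median(centers[:, 0])
        window = max(T - 1, 1)  # types per block; adjacent blocks overlap
        for s in range(S):
            block = 0 if centers[s, 0] <= mid else 1
            allowed = range(block, min(block + window, T))
            for t in allowed:
                weights[s, t] = 1.0
        weights /= weights.sum(axis=1, keepdims=True)
    else:  # gaussian-bumps
        span = centers.max(axis=0) - centers.min(axis=0)
        # bump centers kept away from the margin; narrow width gives each
        # type a clearly localized territory
        bump_centers = centers.min(axis=0) + rng.uniform(0.1, 0.9, size=(T, 2)) * span
        width = max(span.max(), 1.0) / 5.0
        for t in range(T):
            d2 = ((centers - bump_centers[t]) ** 2).sum(axis=1)
            weights[:, t] = np.exp(-0.5 * d2 / width**2) + 0.02
        weights /= weights.sum(axis=1, keepdims=True)

    n = np.vstack([rng.multinomial(N[s], weights[s]) for s in range(S)])

    geometry = SpotGeometry(
        spot_ids=[f"spot{s}" for s in range(S)],
        centers=centers,
        spot_diameter_px=spot_diameter_px,
        microns_per_px=microns_per_px,
    )
    nuclei = _scatter_nuclei(geometry, n, type_ids, out_spot_density, rng)
    return TruthPattern(
        geometry=geometry, n=n, type_ids=type_ids, nuclei=nuclei, seed=seed,
        expected_weights=weights,
    )


def _scatter_nuclei(geometry, n, type_ids, out_density, rng) -> NucleusSet:
    radius = geometry.radius_px * 0.9  # stay clear of the boundary
    ids, coords, spots, types = [], [], [], []
    for s in range(geometry.n_spots):
        for t, count in enumerate(n[s]):
            for _ in range(int(count)):
                ang = rng.uniform(0, 2 * np.pi)
                rad = radius * np.sqrt(rng.uniform())
                coords.append(
                    (
                        geometry.centers[s, 0] + rad * np.cos(ang),
                        geometry.centers[s, 1] + rad * np.sin(ang),
                    )
                )
                ids.append(f"nuc{len(ids)}")
                spots.append(geometry.spot_ids[s])
                types.append(type_ids[t])
    # out-spot nuclei over the bounding box, rejected if inside any spot
    lo = geometry.centers.min(axis=0) - geometry.spot_diameter_px
    hi = geometry.centers.max(axis=0) + geometry.spot_diameter_px
    n_out = int(out_density * n.sum().item() / max(geometry.n_spots, 1) * geometry.n_spots)
    placed = 0
    attempts = 0
    from scipy.spatial import cKDTree

    tree = cKDTree(geometry.centers)
    while placed < n_out and attempts < 50 * max(n_out, 1):
        attempts += 1
        pt = rng.uniform(lo, hi)
        d, _ = tree.query(pt)
        if d <= geometry.radius_px * 1.1:
            continue
        coords.append(tuple(pt))
        ids.append(f"nuc{len(ids)}")
        spots.append(None)
        types.append(None)
        placed += 1
    return NucleusSet(
        nucleus_ids=ids,
        coords=np.asarray(coords, dtype=float).reshape(-1, 2),
        assigned_spot=spots,
        assigned_type=types,
    )


def simulate_spots(
    Y: AnnotatedCounts,
    truth_pattern: TruthPattern,
    noise_level: str = "none",
    seed: int = 0,
    noise_params: Optional[tuple[float, float, float]] = None,
) -> tuple[AnnotatedCounts, SimulationTruth]:
    """Sample scRNA cells into spots and corrupt the summed counts.

    Per spot, ``n[s, t]`` cells of each type are drawn with replacement
    from ``Y`` and their raw counts summed. Corruptions, in order:
    (1) gene-wise batch effect ``2**r_g`` with ``r_g ~ N(0, sigma_r)``;
    (2) each nonzero entry zeroed with probability ``pi_0``;
    (3) each entry scaled by ``LogNormal(0, sigma_n)``; then rounding.
    """
    if Y.labels is None:
        raise ValidationError("scRNA input must carry cell-type labels")
    if Y.normalized != "raw":
        raise ValidationError("simulation samples raw counts")
    if noise_level not in NOISE_PRESETS:
        raise ValidationError(f"unknown noise level {noise_level!r}")
    labels = np.asarray(Y.labels)
    pools: dict[str, np.ndarray] = {}
    for t in truth_pattern.type_ids:
        pool = np.flatnonzero(labels == t)
        if pool.size == 0:
            raise ValidationError(f"type {t!r} absent from scRNA labels")
        pools[t] = pool

    rng = np.random.default_rng(seed)
    S = truth_pattern.geometry.n_spots
    G = Y.n_genes
    X = np.zeros((S, G))
    sampled: list[list[int]] = []
    for s in range(S):
        chosen: list[int] = []
        for t_idx, t in enumerate(truth_pattern.type_ids):
            k = int(truth_pattern.n[s, t_idx])
            if k:
                picks = rng.choice(pools[t], size=k, replace=True)
                chosen.extend(int(c) for c in picks)
        sampled.append(chosen)
        if chosen:
            X[s] = Y.matrix[chosen].sum(axis=0)
    clean = X.copy()

    sigma_r, pi_0, sigma_n = (
        noise_params if noise_params is not None else NOISE_PRESETS[noise_level]
    )
    r_true = rng.normal(0, sigma_r, size=G) if sigma_r > 0 else np.zeros(G)
    if sigma_r > 0:
        X = X * np.exp2(r_true)[None, :]
    if pi_0 > 0:
        mask = (X > 0) & (rng.uniform(size=X.shape) < pi_0)
        X[mask] = 0.0
    if sigma_n > 0:
        X = X * rng.lognormal(0.0, sigma_n, size=X.shape)
    X = np.round(X)

    X_sim = AnnotatedCounts(
        matrix=X,
        row_ids=list(truth_pattern.geometry.spot_ids),
        gene_ids=list(Y.gene_ids),
    )
    truth = SimulationTruth(
        sampled_cells=sampled,
        n=truth_pattern.n.copy(),
        P_true=truth_pattern.P_true,
        r_true=r_true,
        zero_mask_rate=pi_0,
        noise_level=noise_level,
        seed=seed,
        type_ids=list(truth_pattern.type_ids),
        clean_matrix=clean,
    )
    return X_sim, truth


def synthetic_reference(
    T: int = 5,
    cells_per_type: int = 40,
    n_genes: int = 200,
    markers_per_type: int = 40,
    fold: float = 8.0,
    base_rate: float = 2.0,
    seed: int = 0,
    depth_spread: float = 0.0,
) -> AnnotatedCounts:
    """Poisson scRNA reference with planted per-type marker blocks.

    Each type elevates its own ``markers_per_type`` gene block by
    ``fold``; ``depth_spread`` > 0 additionally scales per-type library
    sizes by ``1 + depth_spread * t / (T-1)`` so transcript-contribution
    and cell-number proportions differ.
    """
    rng = np.random.default_rng(seed)
    rates = np.full((T, n_genes), base_rate)
    for t in range(T):
        lo = (t * markers_per_type) % n_genes
        hi = min(lo + markers_per_type, n_genes)
        rates[t, lo:hi] *= fold
    rows, labels = [], []
    for t in range(T):
        scale = 1.0 + (depth_spread * t / max(T - 1, 1))
        block = rng.poisson(rates[t][None, :] * scale, size=(cells_per_type, n_genes))
        rows.append(block)
        labels.extend([f"type{t}"] * cells_per_type)
    Y = np.vstack(rows).astype(float)
    return AnnotatedCounts(
        matrix=Y,
        row_ids=[f"cell{i}" for i in range(Y.shape[0])],
        gene_ids=[f"gene{g}" for g in range(n_genes)],
        labels=labels,
    )


def truth_tables(truth: SimulationTruth, spot_ids: list[str]) -> dict[str, pd.DataFrame]:
    """Ground-truth tables for export: n_st, proportions, r, manifest."""
    n_df = pd.DataFrame(truth.n, index=spot_ids, columns=truth.type_ids)
    p_df = pd.DataFrame(truth.P_true, index=spot_ids, columns=truth.type_ids)
    r_df = pd.DataFrame({"gene_index": np.arange(len(truth.r_true)), "r": truth.r_true})
    manifest = pd.DataFrame(
        {
            "spot": np.repeat(spot_ids, [len(c) for c in truth.sampled_cells]),
            "cell_row": np.concatenate([c for c in truth.sampled_cells if c] or [[]]).astype(int)
            if any(truth.sampled_cells)
            else np.array([], dtype=int),
        }
    )
    return {"n": n_df, "proportions": p_df, "r": r_df, "manifest": manifest}
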