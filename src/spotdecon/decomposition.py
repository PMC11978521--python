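"""Integer cell apportionment and decomposition of spot counts to cells.

Given proportions and a per-spot nucleus count, integer type counts are
chosen to minimize the L1 distance between realized and estimated
proportions (largest-remainder apportionment). Each spot's full-genome
counts are then split across types by posterior-mean allocation weights,
and type rows are split across the spot's nuclei.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from spotdecon.geometry import SpotAssignment
from spotdecon.io import NucleusSet, ValidationError
from spotdecon.reference import SignatureMatrix

logger = logging.getLogger("spotdecon")


@dataclass
class SpotComposition:
    """Per-spot nucleus totals, integer type counts and updated proportions."""

    spot_ids: list[str]
    type_ids: list[str]
    N: np.ndarray  # (S,) nuclei per spot
    n: np.ndarray  # (S, T) integer type counts
    p_tilde: np.ndarray  # (S, T) updated proportions

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(self.n < 0):
            raise ValidationError("negative type counts")
        if not np.array_equal(self.n.sum(axis=1), self.N):
            raise ValidationError("type counts do not sum to N_s")
        row_sums = self.p_tilde.sum(axis=1)
        ok = np.isclose(row_sums, 1.0, atol=1e-9) | (row_sums == 0)
        if not ok.all():
            raise ValidationError("p_tilde rows must sum to 1 (or be all-zero)")


@dataclass
class DecomposedSpot:
    """Type x gene expression split of one spot plus allocation weights."""

    spot_id: str
    U: np.ndarray  # (T, G), sums over types reproduce x_s
    omega: np.ndarray  # (T, G) allocation weights; columns sum to 1 where defined


@dataclass
class CellProfileSet:
    """Per-nucleus expression records (inferred single-cell profiles)."""

    cell_ids: list[str]
    spots: list[Optional[str]]  # None = out-spot
    types: list[str]
    coords: np.ndarray  # (N, 2)
    expression: np.ndarray  # (N, G)
    gene_ids: list[str]
    provenance: list[str]  # "decomposed" | "imputed"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": self.cell_ids,
                "spot": ["" if s is None else s for s in self.spots],
                "type": self.types,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "provenance": self.provenance,
            }
        )


def apportion_cells(p: np.ndarray, N: int) -> np.ndarray:
    """Integer type counts minimizing sum_t |n_t/N - p_t| with sum n_t = N.

    Largest-remainder method: floor the exact quotas, then hand remaining
    units to types by descending fractional remainder (ties: larger
    proportion, then lower type index).
    """
    p = np.asarray(p, dtype=float)
    if N < 0:
        raise ValidationError("N must be nonnegative")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValidationError("p must be a simplex")
    if N == 0:
        return np.zeros(len(p), dtype=int)
    quota = p * N
    n = np.floor(quota).astype(int)
    remainder = quota - n
    short = N - int(n.sum())
    if short > 0:
        order = np.lexsort((np.arange(len(p)), -p, -remainder))
        n[order[:short]] += 1
    return n


def threshold_proportions(p: np.ndarray, l_p: float) -> np.ndarray:
    """Zero types below ``l_p`` and renormalize the survivors.

    If no type survives, the argmax type is kept with proportion 1.
    """
    p = np.asarray(p, dtype=float)
    if not 0 <= l_p < 1:
        raise ValidationError("l_p must be in [0, 1)")
    keep = p >= l_p
    if l_p == 0:
        return p.copy()
    if not keep.any():
        logger.warning("threshold_proportions: no type above %.3g; keeping argmax", l_p)
        out = np.zeros_like(p)
        out[int(np.argmax(p))] = 1.0
        return out
    out = np.where(keep, p, 0.0)
    return out / out.sum()


def composition_from_counts(
    assignment: SpotAssignment,
    P: np.ndarray,
    spot_ids: list[str],
    type_ids: list[str],
) -> SpotComposition:
    """Apportion every spot's nuclei into integer type counts."""
    S, T = P.shape
    N = np.array([assignment.counts.get(s, 0) for s in spot_ids], dtype=int)
    n = np.zeros((S, T), dtype=int)
    p_tilde = np.zeros((S, T))
    for i in range(S):
        n[i] = apportion_cells(P[i], int(N[i]))
        if N[i] > 0:
            p_tilde[i] = n[i] / N[i]
    return SpotComposition(
        spot_ids=list(spot_ids), type_ids=list(type_ids), N=N, n=n, p_tilde=p_tilde
    )


def composition_from_threshold(
    P: np.ndarray,
    spot_ids: list[str],
    type_ids: list[str],
    l_p: float,
) -> SpotComposition:
    """Image-free branch: threshold proportions instead of apportioning.

    Integer counts are nominal — one cell per surviving type — so the
    downstream per-cell machinery stays usable without nucleus counts.
    """
    S, T = P.shape
    p_tilde = np.vstack([threshold_proportions(P[i], l_p) for i in range(S)])
    n = (p_tilde > 0).astype(int)
    N = n.sum(axis=1)
    return SpotComposition(
        spot_ids=list(spot_ids), type_ids=list(type_ids), N=N, n=n, p_tilde=p_tilde
    )


def decompose_spot(
    x: np.ndarray, p_tilde: np.ndarray, signature: SignatureMatrix, spot_id: str = ""
) -> DecomposedSpot:
    """Split a spot's gene counts across types by posterior-mean weights.

    omega[t, g] = p_tilde[t] * phi[t, g] / sum_t' p_tilde[t'] * phi[t', g];
    U[t, g] = x[g] * omega[t, g]. Genes with zero denominator but nonzero
    counts are allocated proportionally to ``p_tilde`` (logged fallback).
    """
    x = np.asarray(x, dtype=float)
    p_tilde = np.asarray(p_tilde, dtype=float)
    phi = signature.phi
    if x.shape[0] != phi.shape[1] or p_tilde.shape[0] != phi.shape[0]:
        raise ValidationError("shape mismatch between x, p_tilde and signature")
    weighted = p_tilde[:, None] * phi  # (T, G)
    denom = weighted.sum(axis=0)
    omega = np.zeros_like(weighted)
    ok = denom > 0
    omega[:, ok] = weighted[:, ok] / denom[ok]
    fallback = (~ok) & (x > 0)
    if fallback.any():
        logger.info(
            "decompose_spot %s: %d genes allocated by proportions (zero signature)",
            spot_id,
            int(fallback.sum()),
        )
        total = p_tilde.sum()
        share = p_tilde / total if total > 0 else np.full_like(p_tilde, 1 / len(p_tilde))
        omega[:, fallback] = share[:, None]
    U = x[None, :] * omega
    # Make conservation sum_t U[t,g] == x_g bit-exact: snap every allocation
    # to the ulp grid of x_g (all summands and partial sums are then exactly
    # representable, so float addition is exact in any order) and hand the
    # leftover grid units to the dominant type.
    _, expo = np.frexp(np.maximum(x, 1.0))
    q = np.ldexp(1.0, expo - 53)  # grid unit per gene
    U = np.round(U / q[None, :]) * q[None, :]
    residual = x - U.sum(axis=0)
    top = np.argmax(omega, axis=0)
    U[top, np.arange(len(x))] += residual
    return DecomposedSpot(spot_id=spot_id, U=U, omega=omega)


def integer_apportion_matrix(U: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Round type rows to integers while conserving per-gene totals.

    Largest-remainder per gene column: floor each allocation, then hand
    the per-gene shortfall to types by descending fractional remainder.
    Requires the columns of ``U`` to sum to the integer counts ``x``.
    """
    U = np.asarray(U, dtype=float)
    x = np.round(np.asarray(x, dtype=float)).astype(np.int64)
    floor = np.floor(U).astype(np.int64)
    remainder = U - floor
    short = x - floor.sum(axis=0)  # (G,)
    order = np.argsort(-remainder, axis=0, kind="stable")  # (T, G)
    take = np.arange(U.shape[0])[:, None] < short[None, :]
    bonus = np.zeros_like(floor)
    np.put_along_axis(bonus, order, take.astype(np.int64), axis=0)
    return floor + bonus


def partition_to_cells(
    U: np.ndarray,
    n: np.ndarray,
    mode: str = "expected",
    seed: int = 0,
) -> list[tuple[int, np.ndarray]]:
    """Split each type row of ``U`` among its ``n[t]`` cells.

    Returns ``(type_index, profile)`` pairs, one per cell. ``expected``
    gives every cell of a type the same real-valued share; ``sampled``
    multinomially splits integer counts (requires integer ``U`` rows after
    rounding). Both modes sum back to the type rows.
    """
    U = np.asarray(U, dtype=float)
    n = np.asarray(n, dtype=int)
    if mode not in ("expected", "sampled"):
        raise ValidationError("mode must be 'expected' or 'sampled'")
    rng = np.random.default_rng(seed)
    cells: list[tuple[int, np.ndarray]] = []
    for t in range(U.shape[0]):
        row = U[t]
        if n[t] == 0:
            if row.any():
                raise ValidationError(
                    f"type {t} has expression but zero cells in composition"
                )
            continue
        if mode == "expected":
            share = row / n[t]
            for _ in range(n[t]):
                cells.append((t, share.copy()))
        else:
            counts = np.round(row).astype(np.int64)
            split = rng.multinomial(counts, np.full(n[t], 1.0 / n[t]), size=None)
            # np.random.Generator.multinomial broadcasts over counts vector:
            # result (G, n_t); cells are columns
            for j in range(n[t]):
                cells.append((t, split[:, j].astype(float)))
    return cells


def annotate_in_spot_nuclei(
    assignment: SpotAssignment, composition: SpotComposition, seed: int = 0
) -> NucleusSet:
    """Randomly label each spot's nuclei so type counts match composition."""
    nuclei = assignment.nuclei
    spot_index = {s: i for i, s in enumerate(composition.spot_ids)}
    for s, i in spot_index.items():
        if assignment.counts.get(s, 0) != int(composition.N[i]):
            raise ValidationError(
                f"spot {s!r}: assignment has {assignment.counts.get(s, 0)} nuclei "
                f"but composition expects {composition.N[i]}"
            )
    rng = np.random.default_rng(seed)
    types = [None] * nuclei.n_nuclei
    by_spot: dict[str, list[int]] = {}
    for idx, s in enumerate(nuclei.assigned_spot or []):
        if s is not None:
            by_spot.setdefault(s, []).append(idx)
    for s, members in sorted(by_spot.items()):
        i = spot_index[s]
        order = rng.permutation(len(members))
        labels: list[str] = []
        for t, count in enumerate(composition.n[i]):
            labels.extend([composition.type_ids[t]] * int(count))
        for pos, member_pos in enumerate(order):
            types[members[member_pos]] = labels[pos]
    return NucleusSet(
        nucleus_ids=list(nuclei.nucleus_ids),
        coords=nuclei.coords.copy(),
        assigned_spot=list(nuclei.assigned_spot) if nuclei.assigned_spot else None,
        assigned_type=types,
    )


def decompose_all(
    X: np.ndarray,
    composition: SpotComposition,
    signature: SignatureMatrix,
    nuclei: Optional[NucleusSet] = None,
    mode: str = "expected",
    seed: int = 0,
) -> tuple[list[DecomposedSpot], CellProfileSet]:
    """Decompose every spot and emit per-cell profiles.

    When ``nuclei`` (typed, spot-assigned) is given, cells are matched to
    actual nuclei; otherwise synthetic cell records at spot centers are
    emitted with zero coordinates.
    """
    S = len(composition.spot_ids)
    if X.shape[0] != S:
        raise ValidationError("X rows do not match composition spots")
    decomposed: list[DecomposedSpot] = []
    cell_ids: list[str] = []
    spots: list[Optional[str]] = []
    cell_types: list[str] = []
    coords: list[tuple[float, float]] = []
    profiles: list[np.ndarray] = []

    nuclei_by_spot: dict[str, list[int]] = {}
    if nuclei is not None and nuclei.assigned_spot is not None:
        for idx, s in enumerate(nuclei.assigned_spot):
            if s is not None:
                nuclei_by_spot.setdefault(s, []).append(idx)

    for i, spot_id in enumerate(composition.spot_ids):
        d = decompose_spot(X[i], composition.p_tilde[i], signature, spot_id=spot_id)
        decomposed.append(d)
        if composition.n[i].sum() == 0:
            continue  # no nuclei in this spot: no per-cell records
        U = d.U
        if mode == "sampled":
            U = integer_apportion_matrix(d.U, X[i]).astype(float)
        cells = partition_to_cells(U, composition.n[i], mode=mode, seed=seed + i)
        members = nuclei_by_spot.get(spot_id, [])
        if nuclei is not None and members:
            # pair cells with nuclei of the matching type
            remaining = {t: [] for t in range(len(composition.type_ids))}
            for m_idx in members:
                t_label = nuclei.assigned_type[m_idx]
                remaining[composition.type_ids.index(t_label)].append(m_idx)
            for t, profile in cells:
                m_idx = remaining[t].pop()
                cell_ids.append(nuclei.nucleus_ids[m_idx])
                coords.append(tuple(nuclei.coords[m_idx]))
                spots.append(spot_id)
                cell_types.append(composition.type_ids[t])
                profiles.append(profile)
        else:
            for j, (t, profile) in enumerate(cells):
                cell_ids.append(f"{spot_id}:cell{j}")
                coords.append((np.nan, np.nan))
                spots.append(spot_id)
                cell_types.append(composition.type_ids[t])
                profiles.append(profile)

    expression = (
        np.vstack(profiles) if profiles else np.empty((0, X.shape[1]))
    )
    coords_arr = np.asarray(coords, dtype=float).reshape(-1, 2)
    cell_set = CellProfileSet(
        cell_ids=cell_ids,
        spots=spots,
        types=cell_types,
        coords=coords_arr,
        expression=expression,
        gene_ids=list(signature.gene_ids),
        provenance=["decomposed"] * len(cell_ids),
    )
    return decomposed, cell_set
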