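"""Domain types and on-disk format readers/writers.

All downstream modules operate on the types defined here. Coordinates are
in full-resolution pixel space, origin top-left, ``x`` = column, ``y`` =
row; physical units enter only through ``microns_per_px``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("spotdecon")

CPM_TOTAL = 1e6


class FormatError(ValueError):
    """Malformed or inconsistent on-disk input."""


class ValidationError(ValueError):
    """Input violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedCounts:
    """A nonnegative observations x genes matrix with identifiers.

    Rows are cells or spots, columns are genes. ``labels`` optionally
    carries a per-row categorical (cell-type annotation for scRNA input).
    ``normalized`` is ``"raw"`` or ``"CPM"``.
    """

    matrix: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]
    labels: Optional[list[str]] = None
    normalized: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.matrix.ndim != 2:
            raise ValidationError("counts matrix must be 2-D")
        if self.matrix.shape != (len(self.row_ids), len(self.gene_ids)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.gene_ids)} gene ids"
            )
        if np.any(self.matrix < 0):
            raise ValidationError("counts matrix contains negative entries")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("counts matrix contains non-finite entries")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != len(self.row_ids):
                raise ValidationError("labels length does not match row count")
        if self.normalized not in ("raw", "CPM"):
            raise ValidationError(f"unknown normalization flag {self.normalized!r}")
        if self.normalized == "CPM":
            totals = self.matrix.sum(axis=1)
            nz = totals > 0
            if nz.any() and not np.allclose(totals[nz], CPM_TOTAL, rtol=1e-6):
                raise ValidationError("CPM-flagged matrix rows do not sum to 1e6")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "AnnotatedCounts":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in genes]
        return replace(self, matrix=self.matrix[:, cols], gene_ids=list(genes))


@dataclass
class SpotGeometry:
    """Capture-area geometry: spot centers, radius and scale."""

    spot_ids: list[str]
    centers: np.ndarray  # (S, 2) as (x, y) full-res pixels
    spot_diameter_px: float
    microns_per_px: float
    in_tissue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValidationError("centers must be (S, 2)")
        if self.centers.shape[0] != len(self.spot_ids):
            raise ValidationError("centers do not match spot_ids")
        if not np.all(np.isfinite(self.centers)):
            raise ValidationError("non-finite spot centers")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("duplicate spot ids")
        if not self.spot_diameter_px > 0:
            raise ValidationError("spot_diameter_px must be positive")
        if not self.microns_per_px > 0:
            raise ValidationError("microns_per_px must be positive")
        if self.in_tissue is None:
            self.in_tissue = np.ones(len(self.spot_ids), dtype=bool)
        else:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if self.in_tissue.shape != (len(self.spot_ids),):
                raise ValidationError("in_tissue does not match spot_ids")

    @property
    def radius_px(self) -> float:
        return self.spot_diameter_px / 2.0

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class NucleusSet:
    """Nucleus centroids with optional spot assignment and type labels."""

    nucleus_ids: list[str]
    coords: np.ndarray  # (N, 2) as (x, y)
    assigned_spot: Optional[list[Optional[str]]] = None
    assigned_type: Optional[list[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.nucleus_ids = [str(n) for n in self.nucleus_ids]
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.coords.shape[0] != len(self.nucleus_ids):
            raise ValidationError("coords do not match nucleus_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite nucleus coordinates")
        if len(set(self.nucleus_ids)) != len(self.nucleus_ids):
            raise ValidationError("duplicate nucleus ids")
        for attr in ("assigned_spot", "assigned_type"):
            val = getattr(self, attr)
            if val is not None and len(val) != len(self.nucleus_ids):
                raise ValidationError(f"{attr} does not match nucleus count")

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_ids)

    def validate_against(self, geometry: SpotGeometry) -> None:
        if self.assigned_spot is None:
            return
        known = set(geometry.spot_ids)
        for spot in self.assigned_spot:
            if spot is not None and spot not in known:
                raise ValidationError(f"assigned spot {spot!r} not in geometry")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with documented defaults."""

    # marker selection
    l_fold: float = 1.5
    l_lambda: float = 0.1
    l_cover: float = 0.60
    v: float = 0.15
    n_select: int = 50
    # presence threshold (image-free decomposition branch)
    l_p: float = 0.05
    # inference
    n_iterations: int = 8000
    learning_rate: float = 0.01
    seed: int = 0
    inference_mode: str = "map"  # "map" or "vi"
    qp_mode: str = "mrna"  # "mrna" or "identity"
    # imputation
    gp_length_scale: Optional[float] = None  # pixels; default 2x spot pitch
    gp_noise: float = 0.01  # proportion targets carry counting noise
    k_neighbors: int = 10
    optimize_gp: bool = False
    # simulation
    noise_level: str = "none"
    # per-cell split of decomposed counts
    cell_mode: str = "expected"  # "expected" or "sampled"

    def __post_init__(self) -> None:
        if not 0 < self.v < 1:
            raise ValidationError("v must be in (0, 1)")
        if not 0 <= self.l_cover <= 1:
            raise ValidationError("l_cover must be in [0, 1]")
        if not self.l_fold > 0:
            raise ValidationError("l_fold must be positive")
        if not 0 <= self.l_p < 1:
            raise ValidationError("l_p must be in [0, 1)")
        if self.n_select < 1:
            raise ValidationError("n_select must be >= 1")
        if not 0 <= self.l_lambda <= 1:
            raise ValidationError("l_lambda must be in [0, 1]")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.noise_level not in ("none", "small", "medium", "large"):
            raise ValidationError(f"unknown noise level {self.noise_level!r}")
        if self.inference_mode not in ("map", "vi"):
            raise ValidationError("inference_mode must be 'map' or 'vi'")
        if self.qp_mode not in ("mrna", "identity"):
            raise ValidationError("qp_mode must be 'mrna' or 'identity'")
        if self.cell_mode not in ("expected", "sampled"):
            raise ValidationError("cell_mode must be 'expected' or 'sampled'")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        # first TSV column only, so feature files with extra columns work
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_counts(
    mtx_path: str | Path,
    row_ids_path: str | Path,
    gene_ids_path: str | Path,
    labels_path: Optional[str | Path] = None,
) -> AnnotatedCounts:
    """Read a Matrix Market counts file with row/gene id lists.

    The matrix on disk is observations x genes. ``labels_path``, when
    given, is a two-column CSV ``row_id,label`` attached as per-row labels.
    """
    for p in (mtx_path, row_ids_path, gene_ids_path):
        if not Path(p).exists():
            raise FormatError(f"input file does not exist: {p}")
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"invalid Matrix Market file {mtx_path}: {exc}") from exc
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    row_ids = _read_id_list(row_ids_path)
    gene_ids = _read_id_list(gene_ids_path)
    if mat.shape[0] != len(row_ids):
        raise FormatError(
            f"{row_ids_path}: {len(row_ids)} ids but matrix has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(gene_ids):
        raise FormatError(
            f"{gene_ids_path}: {len(gene_ids)} ids but matrix has {mat.shape[1]} columns"
        )
    labels = None
    if labels_path is not None:
        table = pd.read_csv(labels_path, dtype=str)
        if table.shape[1] < 2:
            raise FormatError(f"{labels_path}: expected columns row_id,label")
        mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
        missing = [r for r in row_ids if r not in mapping]
        if missing:
            raise FormatError(
                f"{labels_path}: no label for {len(missing)} rows (e.g. {missing[0]!r})"
            )
        labels = [mapping[r] for r in row_ids]
    return AnnotatedCounts(mat, row_ids, gene_ids, labels=labels)


def write_counts(counts: AnnotatedCounts, out_dir: str | Path, prefix: str = "matrix") -> dict:
    """Write counts as ``<prefix>.mtx`` plus id lists; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mtx_path = out / f"{prefix}.mtx"
    rows_path = out / f"{prefix}.rows.txt"
    genes_path = out / f"{prefix}.genes.txt"
    mat = counts.matrix
    if np.allclose(mat, np.round(mat)):
        mat = sparse.coo_matrix(mat.astype(np.int64))
        spio.mmwrite(str(mtx_path), mat, field="integer")
    else:
        spio.mmwrite(str(mtx_path), sparse.coo_matrix(mat))
    rows_path.write_text("".join(f"{r}\n" for r in counts.row_ids))
    genes_path.write_text("".join(f"{g}\n" for g in counts.gene_ids))
    paths = {"mtx": mtx_path, "rows": rows_path, "genes": genes_path}
    if counts.labels is not None:
        labels_path = out / f"{prefix}.labels.csv"
        pd.DataFrame({"row_id": counts.row_ids, "label": counts.labels}).to_csv(
            labels_path, index=False
        )
        paths["labels"] = labels_path
    return paths


_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_spot_geometry(
    positions_csv: str | Path, scalefactors_json: str | Path
) -> SpotGeometry:
    """Read Visium-style ``tissue_positions`` CSV + scalefactors JSON.

    The CSV may or may not carry a header line; centers are taken as
    ``(pxl_col_in_fullres, pxl_row_in_fullres)``.
    """
    first = open(positions_csv).readline()
    has_header = "barcode" in first
    table = pd.read_csv(
        positions_csv,
        header=0 if has_header else None,
        names=None if has_header else _POSITION_COLUMNS,
    )
    missing = [c for c in _POSITION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{positions_csv}: missing columns {missing}")
    try:
        with open(scalefactors_json) as fh:
            factors = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{scalefactors_json}: malformed JSON: {exc}") from exc
    if "spot_diameter_fullres" not in factors:
        raise FormatError(f"{scalefactors_json}: missing key spot_diameter_fullres")
    mpp = None
    for key in ("microns_per_pixel", "microns_per_px", "pixel_size_um"):
        if key in factors:
            mpp = float(factors[key])
            break
    if mpp is None:
        raise FormatError(
            f"{scalefactors_json}: missing a microns-per-pixel entry "
            "(microns_per_pixel/microns_per_px/pixel_size_um)"
        )
    centers = np.column_stack(
        [
            table["pxl_col_in_fullres"].to_numpy(dtype=float),
            table["pxl_row_in_fullres"].to_numpy(dtype=float),
        ]
    )
    return SpotGeometry(
        spot_ids=table["barcode"].astype(str).tolist(),
        centers=centers,
        spot_diameter_px=float(factors["spot_diameter_fullres"]),
        microns_per_px=mpp,
        in_tissue=table["in_tissue"].to_numpy(dtype=int) == 1,
    )


def write_spot_geometry(
    geometry: SpotGeometry, positions_csv: str | Path, scalefactors_json: str | Path
) -> None:
    table = pd.DataFrame(
        {
            "barcode": geometry.spot_ids,
            "in_tissue": geometry.in_tissue.astype(int),
            "array_row": 0,
            "array_col": 0,
            "pxl_row_in_fullres": geometry.centers[:, 1],
            "pxl_col_in_fullres": geometry.centers[:, 0],
        }
    )
    table.to_csv(positions_csv, index=False)
    with open(scalefactors_json, "w") as fh:
        json.dump(
            {
                "spot_diameter_fullres": geometry.spot_diameter_px,
                "microns_per_pixel": geometry.microns_per_px,
            },
            fh,
        )


def read_nuclei(path: str | Path) -> NucleusSet:
    """Read nuclei CSV: ``nucleus_id,x,y[,assigned_spot,assigned_type]``."""
    table = pd.read_csv(path, dtype={"nucleus_id": str})
    for col in ("nucleus_id", "x", "y"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    coords = table[["x", "y"]].to_numpy(dtype=float)

    def _opt(col: str) -> Optional[list[Optional[str]]]:
        if col not in table.columns:
            return None
        return [None if pd.isna(v) or v == "" else str(v) for v in table[col]]

    return NucleusSet(
        nucleus_ids=table["nucleus_id"].astype(str).tolist(),
        coords=coords,
        assigned_spot=_opt("assigned_spot"),
        assigned_type=_opt("assigned_type"),
    )


def write_nuclei(nuclei: NucleusSet, path: str | Path, provenance: Optional[list[str]] = None) -> None:
    data = {
        "nucleus_id": nuclei.nucleus_ids,
        "x": nuclei.coords[:, 0],
        "y": nuclei.coords[:, 1],
    }
    if nuclei.assigned_spot is not None:
        data["assigned_spot"] = ["" if s is None else s for s in nuclei.assigned_spot]
    if nuclei.assigned_type is not None:
        data["assigned_type"] = ["" if t is None else t for t in nuclei.assigned_type]
    if provenance is not None:
        data["provenance"] = provenance
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def cpm_normalize(counts: AnnotatedCounts) -> AnnotatedCounts:
    """Counts-per-million row normalization.

    Each row is rescaled so it sums to 1e6. All-zero rows are left as-is
    and reported in the log. Re-normalizing CPM data is an error.
    """
    if counts.normalized == "CPM":
        raise ValidationError("input is already CPM-normalized")
    totals = counts.matrix.sum(axis=1)
    zero_rows = int((totals == 0).sum())
    if zero_rows:
        logger.warning("cpm_normalize: %d all-zero rows left unscaled", zero_rows)
    scale = np.divide(CPM_TOTAL, totals, out=np.zeros_like(totals), where=totals > 0)
    return replace(counts, matrix=counts.matrix * scale[:, None], normalized="CPM")


def intersect_genes(
    st: AnnotatedCounts, sc: AnnotatedCounts
) -> tuple[AnnotatedCounts, AnnotatedCounts]:
    """Restrict both matrices to their shared gene universe (exact match).

    Gene order follows the spatial matrix. Dropped counts are logged.
    """
    shared = [g for g in st.gene_ids if g in set(sc.gene_ids)]
    if not shared:
        raise ValidationError("spatial and scRNA data share no genes")
    dropped = (len(st.gene_ids) - len(shared)) + (len(sc.gene_ids) - len(shared))
    if dropped:
        logger.info("intersect_genes: dropped %d non-shared gene columns", dropped)
    return st.subset_genes(shared), sc.subset_genes(shared)
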