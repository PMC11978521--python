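"""Nucleus-to-spot assignment and a toy segmenter for synthetic fixtures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from spotdecon.io import NucleusSet, SpotGeometry, ValidationError


@dataclass
class SpotAssignment:
    """Per-nucleus spot membership and per-spot nucleus counts."""

    nuclei: NucleusSet  # with assigned_spot filled in ("" -> out-spot is None)
    counts: dict[str, int]  # N_s per spot id (zeros included)

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())


def assign_nuclei_to_spots(nuclei: NucleusSet, geometry: SpotGeometry) -> SpotAssignment:
    """Assign each nucleus to the spot whose center covers it.

    A nucleus belongs to a spot iff its distance to the spot center is at
    most the spot radius (boundary inclusive). If several spots cover a
    nucleus the nearest center wins; exact ties go to the earlier spot id.
    Nuclei covered by no spot are marked out-spot (``None``).
    """
    if geometry.n_spots == 0:
        raise ValidationError("empty spot geometry")
    radius = geometry.radius_px
    tree = cKDTree(geometry.centers)
    # k=8 covers any realistic overlap; tie-break below needs candidates
    k = min(8, geometry.n_spots)
    dists, idx = tree.query(nuclei.coords, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]
    assigned: list[str | None] = []
    counts = {s: 0 for s in geometry.spot_ids}
    for i in range(nuclei.n_nuclei):
        within = dists[i] <= radius
        if not within.any():
            assigned.append(None)
            continue
        cand = idx[i][within]
        d = dists[i][within]
        best = d.min()
        ties = cand[np.isclose(d, best, rtol=0, atol=1e-12)]
        spot = geometry.spot_ids[int(ties.min())]
        assigned.append(spot)
        counts[spot] += 1
    out = NucleusSet(
        nucleus_ids=list(nuclei.nucleus_ids),
        coords=nuclei.coords.copy(),
        assigned_spot=assigned,
        assigned_type=list(nuclei.assigned_type) if nuclei.assigned_type else None,
    )
    return SpotAssignment(nuclei=out, counts=counts)


def toy_segment(image: np.ndarray, threshold: float, min_area: int = 1) -> NucleusSet:
    """Threshold + connected components (8-connectivity) -> centroids.

    Fixture plumbing for synthetic grayscale images; real pipelines consume
    externally produced centroid CSVs.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("toy_segment expects a 2-D intensity array")
    labeled = measure.label(image > threshold, connectivity=2)
    ids: list[str] = []
    coords: list[tuple[float, float]] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        r, c = region.centroid  # (row, col) -> (x=col, y=row)
        ids.append(f"nuc_{len(ids)}")
        coords.append((c, r))
    return NucleusSet(
        nucleus_ids=ids,
        coords=np.asarray(coords, dtype=float).reshape(-1, 2),
    )
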