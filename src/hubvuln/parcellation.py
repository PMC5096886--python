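"""Random-centroid Voronoi parcellation of a voxel mask.

K centroid voxels are drawn uniformly without replacement from the mask and
every masked voxel is assigned to its nearest centroid by Euclidean distance
in mm (voxel indices scaled by voxel size). Exact distance ties are broken by
a seeded uniform choice among the tied centroids. Optional Lloyd iterations
(centroid update + reassignment) are available behind a flag.

Region contiguity is *not* guaranteed on non-convex masks; use
:func:`contiguity_fractions` to quantify it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Parcellation",
    "tessellate",
    "apply_coverage_exclusion",
    "region_size_stats",
    "contiguity_fractions",
]


@dataclass
class VolumeGrid:
    """A boolean voxel mask with its spatial metadata."""

    mask: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be 3 positive values")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]


@dataclass
class Parcellation:
    """Voxel labels 1..K (0 = background/excluded) with centroids and metadata."""

    labels: np.ndarray
    centroids: np.ndarray  # voxel coordinates, one row per region
    K: int
    voxel_size: np.ndarray
    affine: np.ndarray
    seed: int | None = None
    excluded_ids: frozenset[int] = frozenset()
    relabel_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.centroids = np.asarray(self.centroids)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and (present.max() > self.K):
            raise ValueError("labels exceed K")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def region_sizes(self) -> dict[int, int]:
        counts = np.bincount(self.labels.reshape(-1), minlength=self.K + 1)
        return {int(i): int(counts[i]) for i in self.region_ids}

    def centroids_mm(self) -> np.ndarray:
        """Mean voxel position of each region, mapped through the affine (mm).

        Rows follow ``region_ids`` order.
        """
        out = []
        flat = self.labels
        for rid in self.region_ids:
            ijk = np.argwhere(flat == rid).mean(axis=0)
            homog = np.append(ijk, 1.0)
            out.append((self.affine @ homog)[:3])
        return np.asarray(out)


def _assign_nearest(
    coords_mm: np.ndarray, centroids_mm: np.ndarray, rng: np.random.Generator,
    chunk: int = 20000,
) -> np.ndarray:
    """Nearest-centroid index per voxel; exact ties broken uniformly by rng."""
    n = len(coords_mm)
    out = np.empty(n, dtype=np.int64)
    for start in range(0, n, chunk):
        block = coords_mm[start : start + chunk]
        d2 = (
            (block**2).sum(1)[:, None]
            - 2.0 * block @ centroids_mm.T
            + (centroids_mm**2).sum(1)[None, :]
        )
        dmin = d2.min(axis=1, keepdims=True)
        ties = d2 <= dmin  # exact float equality of the minimum
        # argmax of ties*U picks uniformly among tied entries
        u = rng.random(d2.shape)
        out[start : start + chunk] = np.argmax(ties * u, axis=1)
    return out


def tessellate(
    grid: VolumeGrid, K: int, seed: int, lloyd_iters: int = 0
) -> Parcellation:
    """Seeded random-centroid Voronoi tessellation of the mask.

    Parameters
    ----------
    grid
        Mask and spatial metadata.
    K
        Number of regions; must not exceed the masked voxel count.
    seed
        Seed for centroid selection and tie-breaking.
    lloyd_iters
        Optional number of centroid-update/reassign iterations (0 = the
        single-shot assignment).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if K > grid.n_masked:
        raise ValueError(f"K={K} exceeds masked voxel count {grid.n_masked}")
    rng = np.random.default_rng(seed)
    vox = np.argwhere(grid.mask)
    pick = rng.choice(len(vox), size=K, replace=False)
    centroids = vox[pick].astype(float)
    coords_mm = vox * grid.voxel_size
    cent_mm = centroids * grid.voxel_size
    assign = _assign_nearest(coords_mm, cent_mm, rng)
    for _ in range(lloyd_iters):
        for k in range(K):
            members = coords_mm[assign == k]
            if len(members):
                cent_mm[k] = members.mean(axis=0)
        assign = _assign_nearest(coords_mm, cent_mm, rng)
    labels = np.zeros(grid.dims, dtype=np.int32)
    labels[tuple(vox.T)] = assign + 1
    return Parcellation(
        labels=labels,
        centroids=cent_mm / grid.voxel_size,
        K=K,
        voxel_size=grid.voxel_size,
        affine=grid.affine,
        seed=seed,
    )


def apply_coverage_exclusion(
    parcellation: Parcellation,
    coverage: list[np.ndarray],
    min_fraction: float = 0.5,
) -> Parcellation:
    """Exclude regions insufficiently covered in any subject and re-index.

    A region is excluded if in ANY subject the fraction of its voxels present
    in that subject's boolean coverage map is below ``min_fraction``.
    Surviving regions are renumbered 1..K' and the old-to-new map persisted in
    ``relabel_map``.
    """
    if not coverage:
        raise ValueError("empty coverage list")
    labels = parcellation.labels
    flat = labels.reshape(-1)
    sizes = np.bincount(flat, minlength=parcellation.K + 1).astype(float)
    excluded: set[int] = set()
    for cov in coverage:
        cov = np.asarray(cov, dtype=bool)
        if cov.shape != labels.shape:
            raise ValueError("coverage map does not align with the label grid")
        covered = np.bincount(flat, weights=cov.reshape(-1), minlength=parcellation.K + 1)
        with np.errstate(invalid="ignore"):
            frac = np.where(sizes > 0, covered / np.maximum(sizes, 1), 1.0)
        for rid in parcellation.region_ids:
            if frac[rid] < min_fraction:
                excluded.add(int(rid))
    survivors = [int(r) for r in parcellation.region_ids if r not in excluded]
    relabel = {old: new + 1 for new, old in enumerate(survivors)}
    lut = np.zeros(parcellation.K + 1, dtype=np.int32)
    for old, new in relabel.items():
        lut[old] = new
    new_labels = lut[flat].reshape(labels.shape)
    new_centroids = parcellation.centroids[[old - 1 for old in survivors]]
    return Parcellation(
        labels=new_labels,
        centroids=new_centroids,
        K=len(survivors),
        voxel_size=parcellation.voxel_size,
        affine=parcellation.affine,
        seed=parcellation.seed,
        excluded_ids=frozenset(excluded),
        relabel_map=relabel,
    )


def region_size_stats(parcellation: Parcellation) -> tuple[float, float]:
    """Mean and sd (n-1 denominator) of non-excluded region voxel counts."""
    sizes = np.array(list(parcellation.region_sizes().values()), dtype=float)
    if len(sizes) == 0:
        raise ValueError("parcellation has no regions")
    mean = float(sizes.mean())
    sd = float(sizes.std(ddof=1)) if len(sizes) > 1 else float("nan")
    return mean, sd


def contiguity_fractions(parcellation: Parcellation) -> dict[int, float]:
    """Per region, fraction of voxels in its largest connected component."""
    out: dict[int, float] = {}
    structure = ndimage.generate_binary_structure(3, 1)
    for rid in parcellation.region_ids:
        region = parcellation.labels == rid
        lab, n = ndimage.label(region, structure=structure)
        if n == 0:
            continue
        largest = np.bincount(lab.reshape(-1))[1:].max()
        out[int(rid)] = float(largest / region.sum())
    return out
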