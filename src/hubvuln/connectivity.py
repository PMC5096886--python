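"""Region time-series extraction and wavelet-correlation association matrices.

The association matrix holds Fisher z-transformed Pearson correlations of
MODWT detail coefficients at a chosen level, unthresholded, with negative
weights retained and a zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .wavelet import modwt, n_boundary_coeffs

__all__ = [
    "RegionTimeSeries",
    "AssociationMatrix",
    "extract_timeseries",
    "wavelet_correlation",
    "fisher_z",
    "build_association_matrix",
    "group_mean_matrix",
]

CLIP_R = 1.0 - 1e-6


@dataclass
class RegionTimeSeries:
    """Mean signal per region: ``values`` is timepoints x regions."""

    values: np.ndarray
    repetition_time: float
    region_ids: np.ndarray
    n_discarded: int = 0
    empty_region_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (timepoints x regions)")
        if self.values.shape[1] != len(self.region_ids):
            raise ValueError("region_ids length must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("region time series contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationMatrix:
    """Symmetric matrix of Fisher-z wavelet correlations, diagonal 0."""

    z_values: np.ndarray
    scale: int
    filter_name: str
    region_ids: np.ndarray
    clipped: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        z = self.z_values
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z_values must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.z_values.shape[0]


def extract_timeseries(
    volume4d, parcellation, n_discard: int = 5, repetition_time: float = 2.0
) -> RegionTimeSeries:
    """Average voxel signals within each non-excluded region.

    Parameters
    ----------
    volume4d
        4-D array (x, y, z, t).
    parcellation
        :class:`~hubvuln.parcellation.Parcellation` whose label grid matches
        the volume's spatial dimensions.
    n_discard
        Leading volumes dropped before averaging.

    Regions with no voxels are flagged in ``empty_region_ids`` (their column
    is NaN-free: they are omitted from the output, not silently dropped
    without record).
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4:
        raise ValueError("volume4d must be 4-D (x, y, z, t)")
    labels = parcellation.labels
    if vol.shape[:3] != labels.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape[:3]} vs parcellation {labels.shape}"
        )
    if n_discard < 0 or n_discard >= vol.shape[3]:
        raise ValueError("n_discard out of range")
    data = vol[..., n_discard:].reshape(-1, vol.shape[3] - n_discard)
    flat = labels.reshape(-1)
    ids = parcellation.region_ids
    counts = np.bincount(flat, minlength=labels.max() + 1)
    sums = np.zeros((labels.max() + 1, data.shape[1]))
    np.add.at(sums, flat, data)
    empty = tuple(int(i) for i in ids if counts[i] == 0)
    if empty:
        warnings.warn(f"regions with zero voxels: {empty}", stacklevel=2)
    keep = [int(i) for i in ids if counts[i] > 0]
    values = sums[keep] / counts[keep, None]
    return RegionTimeSeries(
        values=values.T,
        repetition_time=repetition_time,
        region_ids=np.array(keep),
        n_discarded=n_discard,
        empty_region_ids=empty,
    )


def fisher_z(r, clip: bool = False):
    """Fisher z-transform ``atanh(r)``.

    With ``clip=True``, ``|r|`` is clipped at ``1 - 1e-6`` first; otherwise
    ``|r| >= 1`` raises.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -CLIP_R, CLIP_R)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1: Fisher z undefined (set clip=True to clip)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _detail_interior(values: np.ndarray, level: int, filter_name: str) -> np.ndarray:
    res = modwt(values, filter_name=filter_name, n_levels=level)
    return res.interior(level)


def wavelet_correlation(
    tsA: np.ndarray,
    tsB: np.ndarray,
    level: int = 2,
    filter_name: str = "d4",
) -> float:
    """Pearson correlation of two series' level-``level`` MODWT details.

    Boundary-affected coefficients are excluded. Returns NaN (with a warning)
    if either coefficient series has zero variance.
    """
    a = np.asarray(tsA, dtype=float)
    b = np.asarray(tsB, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("tsA and tsB must be 1-D of equal length")
    wa = _detail_interior(a, level, filter_name)
    wb = _detail_interior(b, level, filter_name)
    sa, sb = wa.std(), wb.std()
    if sa == 0.0 or sb == 0.0:
        warnings.warn("zero-variance wavelet coefficients: correlation undefined",
                      stacklevel=2)
        return float("nan")
    r = float(np.corrcoef(wa, wb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def build_association_matrix(
    rts: RegionTimeSeries,
    level: int = 2,
    filter_name: str = "d4",
    clip: bool = True,
    source: str = "",
) -> AssociationMatrix:
    """All pairwise wavelet correlations, Fisher-z transformed.

    Nothing is thresholded or rectified; the diagonal is set to 0.
    """
    if rts.n_regions < 2:
        raise ValueError("need at least 2 regions")
    W = _detail_interior(rts.values, level, filter_name)
    sd = W.std(axis=0)
    if np.any(sd == 0.0):
        bad = rts.region_ids[sd == 0.0]
        warnings.warn(f"zero-variance coefficients for regions {bad.tolist()}",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(W.T)
    r = np.clip(r, -1.0, 1.0)
    z = fisher_z(r, clip=clip)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return AssociationMatrix(
        z_values=z,
        scale=level,
        filter_name=filter_name,
        region_ids=rts.region_ids.copy(),
        clipped=clip,
        source=source,
    )


def group_mean_matrix(matrices: list[AssociationMatrix], source: str = "") -> AssociationMatrix:
    """Edgewise arithmetic mean of per-subject z-matrices.

    By linearity, region strengths of the result equal the mean of the
    per-subject region strengths.
    """
    if not matrices:
        raise ValueError("empty matrix list")
    ref = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.region_ids, ref.region_ids):
            raise ValueError("region-id mismatch across subjects")
        if m.scale != ref.scale or m.filter_name != ref.filter_name:
            raise ValueError("mixed wavelet settings across subjects")
    z = np.mean([m.z_values for m in matrices], axis=0)
    return AssociationMatrix(
        z_values=z,
        scale=ref.scale,
        filter_name=ref.filter_name,
        region_ids=ref.region_ids.copy(),
        clipped=any(m.clipped for m in matrices),
        source=source,
    )
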