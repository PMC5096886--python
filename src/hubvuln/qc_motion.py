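"""Motion quality control: framewise displacement, scrubbing, delta-BOLD.

The subject-exclusion rules are (1) any framewise displacement above a hard
limit, and (2) a significant association between head motion and the signal
change introduced by scrubbing (delta-BOLD). The delta-BOLD statistic used
here is this package's own concrete definition (the source protocol is
under-specified): per frame, the mean absolute difference between the raw
region signals and the scrubbed-and-reinterpolated signals, correlated with
the framewise displacement series and tested by permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import RegionTimeSeries, build_association_matrix

__all__ = [
    "MotionTrace",
    "DeltaBoldResult",
    "framewise_displacement",
    "exclude_by_fd",
    "scrub",
    "delta_bold_check",
]

HEAD_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters over time."""

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3) radians
    repetition_time: float

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.shape != self.rotations.shape or self.translations.ndim != 2:
            raise ValueError("translations and rotations must both be (T, 3)")
        if self.translations.shape[1] != 3:
            raise ValueError("expected 3 translation and 3 rotation parameters")
        if not (np.all(np.isfinite(self.translations)) and np.all(np.isfinite(self.rotations))):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.translations.shape[0]


def framewise_displacement(trace: MotionTrace, head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """FD_t = sum |d translations| + head_radius * sum |d rotations|, FD_1 = 0."""
    if trace.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    fd = np.zeros(trace.n_timepoints)
    fd[1:] = dt + head_radius * dr
    return fd


def exclude_by_fd(fd: np.ndarray, limit: float = 5.0) -> tuple[bool, float]:
    """Exclude iff max(FD) strictly exceeds ``limit`` mm. Returns (excluded, max FD)."""
    fd = np.asarray(fd, dtype=float)
    max_fd = float(fd.max())
    return max_fd > limit, max_fd


def scrub(
    rts: RegionTimeSeries,
    fd: np.ndarray,
    fd_threshold: float = 0.5,
    min_frames: int = 64,
) -> tuple[RegionTimeSeries, np.ndarray]:
    """Censor frames with FD above threshold plus the following frame.

    Returns the censored series and the sorted array of removed frame
    indices. Raises if fewer than ``min_frames`` frames survive.
    """
    fd = np.asarray(fd, dtype=float)
    if len(fd) != rts.n_timepoints:
        raise ValueError("FD series and time series lengths differ")
    bad = fd > fd_threshold
    censored = bad.copy()
    censored[1:] |= bad[:-1]
    keep = ~censored
    if keep.sum() < min_frames:
        raise ValueError(
            f"only {int(keep.sum())} frames survive scrubbing (< {min_frames})"
        )
    out = RegionTimeSeries(
        values=rts.values[keep],
        repetition_time=rts.repetition_time,
        region_ids=rts.region_ids.copy(),
        n_discarded=rts.n_discarded,
        empty_region_ids=rts.empty_region_ids,
    )
    return out, np.flatnonzero(censored)


@dataclass
class DeltaBoldResult:
    excluded: bool
    statistic: float
    p_value: float
    mean_edge_delta_z: float
    n_censored: int
    alpha: float


def delta_bold_check(
    rts_raw: RegionTimeSeries,
    rts_scrubbed: RegionTimeSeries,
    fd: np.ndarray,
    censored_frames: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    level: int = 2,
    filter_name: str = "d4",
) -> DeltaBoldResult:
    """Motion-correlation check on the change in signal due to scrubbing.

    Per censored frame, delta-BOLD is the mean over regions of
    ``|raw - reconstructed|``, where the reconstruction linearly
    interpolates from the surviving frames — the signal content that
    scrubbing removes. The subject statistic is the Pearson correlation
    between delta-BOLD and FD across the censored frames. Because both the
    censoring pattern and the interpolation-error geometry are themselves
    driven by FD, the null distribution is built by circularly shifting the
    signal against the *fixed* censoring geometry (``n_perm`` random
    shifts), which preserves that geometry while breaking any signal-motion
    locking; ``p = (b + 1) / (n_perm + 1)``, one-sided (positive
    association). The edgewise mean ``|z_raw - z_scrubbed|`` of the wavelet
    association matrices is reported alongside.

    Degenerate cases (fewer than 5 censored frames, zero variance) retain
    the subject with a warning.
    """
    fd = np.asarray(fd, dtype=float)
    censored_frames = np.asarray(censored_frames, dtype=int)
    if len(fd) != rts_raw.n_timepoints:
        raise ValueError("FD series does not align with the raw series")
    if not np.array_equal(rts_raw.region_ids, rts_scrubbed.region_ids):
        raise ValueError("raw and scrubbed series are defined on different regions")

    try:
        z_raw = build_association_matrix(rts_raw, level=level, filter_name=filter_name).z_values
        z_scr = build_association_matrix(rts_scrubbed, level=level, filter_name=filter_name).z_values
        iu = np.triu_indices_from(z_raw, k=1)
        mean_edge_delta = float(np.abs(z_raw[iu] - z_scr[iu]).mean())
    except ValueError:
        mean_edge_delta = float("nan")

    T = rts_raw.n_timepoints
    X = rts_raw.values
    keep = np.setdiff1d(np.arange(T), censored_frames)
    fd_c = fd[censored_frames]
    if len(censored_frames) < 5 or len(keep) < 2 or fd_c.std() == 0.0:
        warnings.warn(
            "degenerate delta-BOLD statistic: subject retained without test",
            stacklevel=2,
        )
        return DeltaBoldResult(
            excluded=False,
            statistic=float("nan"),
            p_value=float("nan"),
            mean_edge_delta_z=mean_edge_delta,
            n_censored=len(censored_frames),
            alpha=alpha,
        )

    # linear-interpolation geometry: left/right surviving frame and weight
    right_pos = np.searchsorted(keep, censored_frames)
    left = keep[np.clip(right_pos - 1, 0, len(keep) - 1)]
    right = keep[np.clip(right_pos, 0, len(keep) - 1)]
    gap = np.where(right > left, right - left, 1)
    w = np.where(right > left, (censored_frames - left) / gap, 0.0)
    w = np.clip(w, 0.0, 1.0)

    def _delta(shift: np.ndarray) -> np.ndarray:
        # shift: (n_shifts,) circular offsets applied to the signal
        c = (censored_frames[None, :] + shift[:, None]) % T
        lo = (left[None, :] + shift[:, None]) % T
        hi = (right[None, :] + shift[:, None]) % T
        recon = (1.0 - w)[None, :, None] * X[lo] + w[None, :, None] * X[hi]
        return np.abs(X[c] - recon).mean(axis=2)

    delta_obs = _delta(np.array([0]))[0]
    if delta_obs.std() == 0.0:
        warnings.warn(
            "degenerate delta-BOLD statistic: subject retained without test",
            stacklevel=2,
        )
        return DeltaBoldResult(
            excluded=False,
            statistic=float("nan"),
            p_value=float("nan"),
            mean_edge_delta_z=mean_edge_delta,
            n_censored=len(censored_frames),
            alpha=alpha,
        )
    fz = (fd_c - fd_c.mean()) / fd_c.std()

    def _corr(deltas: np.ndarray) -> np.ndarray:
        d = deltas - deltas.mean(axis=1, keepdims=True)
        sd = d.std(axis=1)
        sd[sd == 0] = np.inf
        return (d @ fz) / (len(fz) * sd)

    r_obs = float(_corr(delta_obs[None, :])[0])
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, T, size=n_perm)
    r_null = _corr(_delta(shifts))
    b = int(np.sum(r_null >= r_obs))
    p = (b + 1) / (n_perm + 1)
    return DeltaBoldResult(
        excluded=p <= alpha,
        statistic=r_obs,
        p_value=p,
        mean_edge_delta_z=mean_edge_delta,
        n_censored=len(censored_frames),
        alpha=alpha,
    )
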