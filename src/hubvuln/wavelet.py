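"""Maximal overlap discrete wavelet transform (MODWT).

Non-decimated pyramid transform with circular (periodic) boundary handling.
Coefficient series have the same length as the input and the transform is
energy preserving: ``||x||^2 = sum_j ||W_j||^2 + ||V_J||^2``.

Filters follow the Percival & Walden convention: the MODWT scaling / wavelet
filters are the orthonormal DWT filters divided by sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCALING_FILTERS",
    "ModwtResult",
    "modwt",
    "min_series_length",
    "n_boundary_coeffs",
    "scale_band",
]

_S3 = np.sqrt(3.0)

#: Orthonormal scaling (low-pass) filters, indexed by name.
SCALING_FILTERS: dict[str, np.ndarray] = {
    # Daubechies extremal-phase, 4 taps.
    "d4": np.array([1.0 + _S3, 3.0 + _S3, 3.0 - _S3, 1.0 - _S3]) / (4.0 * np.sqrt(2.0)),
    # Daubechies least-asymmetric, 8 taps.
    "la8": np.array(
        [
            -0.0757657147893407,
            -0.0296355276459541,
            0.4976186676324578,
            0.8037387518052163,
            0.2978577956055422,
            -0.0992195435769354,
            -0.0126039672622612,
            0.0322231006040713,
        ]
    ),
}


def _wavelet_filter(g: np.ndarray) -> np.ndarray:
    """Quadrature-mirror high-pass filter: h_l = (-1)^l g_{L-1-l}."""
    L = len(g)
    return np.array([(-1.0) ** l * g[L - 1 - l] for l in range(L)])


def n_boundary_coeffs(filter_name: str, level: int) -> int:
    """Number of circular-boundary-affected MODWT coefficients at ``level``.

    Equals ``L_j - 1`` where ``L_j = (2^j - 1)(L - 1) + 1`` is the width of
    the equivalent filter at level j.
    """
    L = len(SCALING_FILTERS[filter_name])
    return (2**level - 1) * (L - 1)


def min_series_length(filter_name: str, n_levels: int) -> int:
    """Shortest series for which level ``n_levels`` has non-boundary coefficients."""
    return n_boundary_coeffs(filter_name, n_levels) + 1


@dataclass
class ModwtResult:
    """MODWT coefficients: one detail series per level plus the final smooth.

    ``details[j-1]`` and ``smooth`` have the same shape as the input
    (timepoints first).
    """

    details: list[np.ndarray]
    smooth: np.ndarray
    filter_name: str
    n_levels: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_levels = len(self.details)

    def boundary_count(self, level: int) -> int:
        return n_boundary_coeffs(self.filter_name, level)

    def interior(self, level: int) -> np.ndarray:
        """Detail coefficients at ``level`` with boundary-affected ones removed."""
        w = self.details[level - 1]
        nb = self.boundary_count(level)
        if nb >= w.shape[0]:
            raise ValueError(
                f"no interior coefficients at level {level}: series of length "
                f"{w.shape[0]} has {nb} boundary coefficients"
            )
        return w[nb:]


def modwt(x: np.ndarray, filter_name: str = "d4", n_levels: int = 4) -> ModwtResult:
    """Compute the MODWT of ``x`` down to ``n_levels``.

    Parameters
    ----------
    x
        1-D series or 2-D array of series stacked as columns (time on axis 0).
    filter_name
        Key into :data:`SCALING_FILTERS` (``"d4"`` or ``"la8"``).
    n_levels
        Number of decomposition levels.

    Notes
    -----
    Filtering is circular; implemented as one FFT per level over all columns,
    using the filters upsampled by ``2^(j-1)``.
    """
    if filter_name not in SCALING_FILTERS:
        raise KeyError(f"unknown wavelet filter {filter_name!r}")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = x[:, None] if one_d else x
    T = X.shape[0]
    need = min_series_length(filter_name, n_levels)
    if T < need:
        raise ValueError(
            f"series of length {T} too short for a {n_levels}-level MODWT with "
            f"filter {filter_name!r}: minimum length is {need}"
        )

    g = SCALING_FILTERS[filter_name]
    h = _wavelet_filter(g)
    gt = g / np.sqrt(2.0)
    ht = h / np.sqrt(2.0)
    L = len(g)

    V = X
    details: list[np.ndarray] = []
    for j in range(1, n_levels + 1):
        stride = 2 ** (j - 1)
        idx = (np.arange(L) * stride) % T
        h_up = np.zeros(T)
        g_up = np.zeros(T)
        np.add.at(h_up, idx, ht)
        np.add.at(g_up, idx, gt)
        Vf = np.fft.rfft(V, axis=0)
        W = np.fft.irfft(np.fft.rfft(h_up)[:, None] * Vf, n=T, axis=0)
        V = np.fft.irfft(np.fft.rfft(g_up)[:, None] * Vf, n=T, axis=0)
        details.append(W[:, 0] if one_d else W)
    smooth = V[:, 0] if one_d else V
    return ModwtResult(details=details, smooth=smooth, filter_name=filter_name)


def scale_band(repetition_time: float, level: int) -> tuple[float, float]:
    """Frequency band (Hz) isolated by MODWT detail level ``level``.

    Returns ``(1 / (2^(j+1) * TR), 1 / (2^j * TR))`` for level j.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if repetition_time <= 0:
        raise ValueError("repetition_time must be positive")
    return (
        1.0 / (2 ** (level + 1) * repetition_time),
        1.0 / (2**level * repetition_time),
    )
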