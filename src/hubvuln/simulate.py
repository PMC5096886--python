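"""Synthetic data generation for the full analysis pipeline.

Generates every pipeline input — masks, parcellation-ready grids, BOLD-like
volumes, motion traces, donor expression tables, behavioural scores — with
the statistical structure the analysis assumes, plus a ground-truth record
for recovery testing.

Signal model
------------
Region signals are mixtures of band-limited latent factors (a low-rank
factor model, which guarantees a positive semidefinite covariance): hub
regions load on all factors, other regions on one factor each, so hubs have
the largest expected connectivity row sums. In disease groups every region's
factor loadings are scaled by ``(1 - severity * attenuation)``. All latent
components are filtered into the analyzed wavelet band so that the chosen
MODWT level carries the planted correlation structure.

Expression model
----------------
Regions are grouped into mirror-pair classes (left/right homologues share a
structure label and a latent expression value), so the hemispheric-symmetry
assumption of the mapping stage holds by construction. The latent profile of
the first gene is built to correlate with the expected control connection
strength at exactly the requested value; remaining genes are orthogonal to
strength. Donor and probe offsets are additive constants, removed by
within-donor normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import Parcellation, VolumeGrid
from .qc_motion import MotionTrace

__all__ = [
    "Scenario",
    "GroundTruth",
    "make_mask",
    "make_ground_truth",
    "band_limited_noise",
    "simulate_region_signals",
    "simulate_bold",
    "simulate_motion",
    "simulate_expression",
    "simulate_behaviour",
    "simulate_symmetry_donor",
    "correlated_band_pair",
]

GROUPS = ("control", "PD", "PSP")


@dataclass
class Scenario:
    """Size and noise parameters of one synthetic study."""

    n_regions: int = 100
    n_subjects_per_group: int = 20
    n_timepoints: int = 256
    repetition_time: float = 2.0
    n_donors: int = 6
    n_probes_per_gene: int = 3
    single_hemisphere_donors: int = 4
    expression_noise_sd: float = 0.05
    signal_noise_sd: float = 1.0
    voxel_noise_sd: float = 0.5
    add_qc_fail_probe: bool = True
    spike_rate: float = 0.0
    spike_mm: float = 0.3
    analysis_level: int = 2
    genes: tuple[str, ...] = ("MAPT", "SNCA")

    def __post_init__(self) -> None:
        if self.n_timepoints < 64:
            raise ValueError("n_timepoints must be >= 64")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        if self.single_hemisphere_donors > self.n_donors:
            raise ValueError("single_hemisphere_donors cannot exceed n_donors")
        if self.n_probes_per_gene < 2:
            raise ValueError("need at least 2 probes per gene")


@dataclass
class GroundTruth:
    """Planted effects and the parameters needed to regenerate a study."""

    hub_region_ids: set[int]
    expression_strength_corr: float
    attenuation_map: dict[str, np.ndarray]
    fluency_slope: float
    seeds: dict[str, int]
    loadings: np.ndarray  # regions x factors
    noise_sd: float
    expected_strength: np.ndarray
    expression_profiles: dict[str, np.ndarray]
    class_of_region: np.ndarray
    class_labels: list[str]
    fluency_intercepts: dict[str, float] = field(
        default_factory=lambda: {"control": 40.3, "PD": 34.3, "PSP": 14.1}
    )
    fluency_noise_sd: float = 5.0
    updrs_means: dict[str, float] = field(
        default_factory=lambda: {"control": 2.0, "PD": 25.0, "PSP": 40.0}
    )
    updrs_noise_sd: float = 8.0
    analysis_level: int = 2

    def __post_init__(self) -> None:
        if not self.hub_region_ids:
            raise ValueError("hub_region_ids must be nonempty")
        if not self.seeds:
            raise ValueError("seeds must be recorded")
        for g, a in self.attenuation_map.items():
            a = np.asarray(a, dtype=float)
            if np.any((a < 0) | (a > 1)):
                raise ValueError(f"attenuation for group {g!r} outside [0, 1]")
            self.attenuation_map[g] = a

    def to_dict(self) -> dict:
        return {
            "hub_region_ids": sorted(self.hub_region_ids),
            "expression_strength_corr": self.expression_strength_corr,
            "attenuation_map": {g: a.tolist() for g, a in self.attenuation_map.items()},
            "fluency_slope": self.fluency_slope,
            "seeds": dict(self.seeds),
            "loadings": self.loadings.tolist(),
            "noise_sd": self.noise_sd,
            "expected_strength": self.expected_strength.tolist(),
            "expression_profiles": {g: v.tolist() for g, v in self.expression_profiles.items()},
            "class_of_region": self.class_of_region.tolist(),
            "class_labels": list(self.class_labels),
            "fluency_intercepts": dict(self.fluency_intercepts),
            "fluency_noise_sd": self.fluency_noise_sd,
            "updrs_means": dict(self.updrs_means),
            "updrs_noise_sd": self.updrs_noise_sd,
            "analysis_level": self.analysis_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            hub_region_ids=set(d["hub_region_ids"]),
            expression_strength_corr=d["expression_strength_corr"],
            attenuation_map={g: np.asarray(a) for g, a in d["attenuation_map"].items()},
            fluency_slope=d["fluency_slope"],
            seeds={k: int(v) for k, v in d["seeds"].items()},
            loadings=np.asarray(d["loadings"]),
            noise_sd=d["noise_sd"],
            expected_strength=np.asarray(d["expected_strength"]),
            expression_profiles={g: np.asarray(v) for g, v in d["expression_profiles"].items()},
            class_of_region=np.asarray(d["class_of_region"], dtype=int),
            class_labels=list(d["class_labels"]),
            fluency_intercepts=dict(d["fluency_intercepts"]),
            fluency_noise_sd=d["fluency_noise_sd"],
            updrs_means=dict(d["updrs_means"]),
            updrs_noise_sd=d["updrs_noise_sd"],
            analysis_level=d["analysis_level"],
        )


def make_mask(
    shape: tuple[int, int, int],
    kind: str = "ellipsoid",
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> VolumeGrid:
    """Bilaterally symmetric boolean mask with an RAS mm affine.

    ``kind`` is ``"ellipsoid"`` or ``"two_lobes"``. The affine centers the
    grid so the midsagittal plane sits at x = 0 mm; symmetry under the voxel
    x-mirror holds by construction.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("each mask dimension must be >= 8 voxels")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    jitter = 0.9 + 0.1 * rng.random(3)  # same both sides -> symmetry preserved
    if kind == "ellipsoid":
        rx, ry, rz = 0.45 * nx * jitter[0], 0.45 * ny * jitter[1], 0.45 * nz * jitter[2]
        mask = ((i - cx) / rx) ** 2 + ((j - cy) / ry) ** 2 + ((k - cz) / rz) ** 2 <= 1.0
    elif kind == "two_lobes":
        rx, ry, rz = 0.28 * nx * jitter[0], 0.42 * ny * jitter[1], 0.42 * nz * jitter[2]
        off = 0.22 * nx
        left = ((i - (cx - off)) / rx) ** 2 + ((j - cy) / ry) ** 2 + ((k - cz) / rz) ** 2 <= 1.0
        right = ((i - (cx + off)) / rx) ** 2 + ((j - cy) / ry) ** 2 + ((k - cz) / rz) ** 2 <= 1.0
        mask = left | right
    else:
        raise ValueError(f"unknown mask kind {kind!r}")
    if not mask.any():
        raise ValueError("degenerate shape produced an empty mask")
    vs = np.asarray(voxel_size, dtype=float)
    affine = np.diag([vs[0], vs[1], vs[2], 1.0])
    affine[:3, 3] = -np.array([cx, cy, cz]) * vs
    return VolumeGrid(mask=mask, voxel_size=vs, affine=affine)


def _mirror_pair_classes(
    centroids_mm: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Group regions into mirror-pair classes by greedy nearest matching.

    Returns (class index per region, structure label per class). Left/right
    homologues share a class; unpaired and midline regions form singletons.
    """
    x = centroids_mm[:, 0]
    left = np.flatnonzero(x < -1e-9)
    right = np.flatnonzero(x > 1e-9)
    mid = np.flatnonzero(np.abs(x) <= 1e-9)
    n = len(centroids_mm)
    class_of = np.full(n, -1, dtype=int)
    next_class = 0
    unpaired_right = list(right)
    for li in left:
        target = centroids_mm[li] * np.array([-1.0, 1.0, 1.0])
        if unpaired_right:
            d = np.linalg.norm(centroids_mm[unpaired_right] - target, axis=1)
            ri = unpaired_right.pop(int(np.argmin(d)))
            class_of[li] = class_of[ri] = next_class
        else:
            class_of[li] = next_class
        next_class += 1
    for ri in unpaired_right:
        class_of[ri] = next_class
        next_class += 1
    for mi in mid:
        class_of[mi] = next_class
        next_class += 1
    labels = [f"struct_{c:04d}" for c in range(next_class)]
    return class_of, labels


def _orthogonal_unit(target: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standardized noise vector with exactly zero sample correlation to target."""
    t = (target - target.mean()) / target.std()
    for _ in range(100):
        e = rng.standard_normal(len(t))
        e = e - e.mean()
        e = e - (e @ t) / (t @ t) * t
        if e.std() > 0:
            return e / e.std()
    raise RuntimeError("could not draw an orthogonal noise vector")


def make_ground_truth(
    parcellation: Parcellation,
    scenario: Scenario,
    seed: int,
    expression_strength_corr: float = 0.3,
    attenuation_max: dict[str, float] | None = None,
    fluency_slope: float = 2.0,
    hub_fraction: float = 0.1,
) -> GroundTruth:
    """Plant hubs, expression profiles, and disease attenuation for a study.

    Attenuation scales with the rank of expected control strength, so the
    best-connected regions lose the most (the selective-vulnerability
    pattern). ``attenuation_max`` defaults are documented modelling choices,
    not literature values.
    """
    if attenuation_max is None:
        attenuation_max = {"PD": 0.35, "PSP": 0.5}
    rng = np.random.default_rng(seed)
    K = len(parcellation.region_ids)
    centroids = parcellation.centroids_mm()
    class_of, class_labels = _mirror_pair_classes(centroids)
    n_classes = len(class_labels)

    m = max(4, n_classes // 5)
    n_hub_classes = max(1, round(hub_fraction * n_classes))
    # prefer full mirror pairs as hub classes so hubs come in homologous pairs
    class_sizes = np.bincount(class_of, minlength=n_classes)
    order = np.argsort(-class_sizes, kind="stable")
    hub_classes = set(int(c) for c in rng.permutation(order[: 2 * n_hub_classes])[:n_hub_classes])

    c_hub, d_spoke = 1.0, 0.5
    loadings = np.zeros((K, m))
    spoke_factor = {c: c % m for c in range(n_classes)}
    for i in range(K):
        c = class_of[i]
        if c in hub_classes:
            loadings[i, :] = c_hub / np.sqrt(m)
        else:
            loadings[i, spoke_factor[c]] = d_spoke

    sigma = scenario.signal_noise_sd
    cov = loadings @ loadings.T + (sigma**2) * np.eye(K)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    z = np.arctanh(np.clip(corr, -1 + 1e-9, 1 - 1e-9))
    np.fill_diagonal(z, 0.0)
    expected_strength = z.sum(axis=1)

    # class-level expression profiles (shared by mirror partners)
    class_strength = np.array(
        [expected_strength[class_of == c].mean() for c in range(n_classes)]
    )
    s_std = (class_strength - class_strength.mean()) / class_strength.std()
    profiles: dict[str, np.ndarray] = {}
    r = expression_strength_corr
    for gi, gene in enumerate(scenario.genes):
        eta = _orthogonal_unit(s_std, rng)
        if gi == 0:
            g_class = r * s_std + np.sqrt(max(0.0, 1 - r**2)) * eta
        else:
            g_class = eta
        profiles[gene] = g_class[class_of]

    ranks = np.argsort(np.argsort(expected_strength))
    rank_frac = ranks / max(K - 1, 1)
    attenuation = {"control": np.zeros(K)}
    for grp, amax in attenuation_max.items():
        attenuation[grp] = amax * rank_frac

    hub_regions = {
        int(rid)
        for rid, c in zip(parcellation.region_ids, class_of)
        if c in hub_classes
    }
    return GroundTruth(
        hub_region_ids=hub_regions,
        expression_strength_corr=expression_strength_corr,
        attenuation_map=attenuation,
        fluency_slope=fluency_slope,
        seeds={"ground_truth": int(seed)},
        loadings=loadings,
        noise_sd=sigma,
        expected_strength=expected_strength,
        expression_profiles=profiles,
        class_of_region=class_of,
        class_labels=class_labels,
        analysis_level=scenario.analysis_level,
    )


def _band_for_level(level: int) -> tuple[float, float]:
    """Normalized frequency band (cycles/sample) of MODWT detail ``level``."""
    return 1.0 / 2 ** (level + 1), 1.0 / 2**level


def band_limited_noise(
    T: int,
    n: int,
    rng: np.random.Generator,
    band: tuple[float, float] | None = None,
    level: int = 2,
    invert: bool = False,
) -> np.ndarray:
    """Unit-variance white noise brick-wall filtered into a frequency band.

    ``band`` is in cycles/sample; by default the dyadic band of the given
    MODWT level. With ``invert=True`` the complement band is kept instead.
    Columns are independent and standardized.
    """
    if band is None:
        band = _band_for_level(level)
    x = rng.standard_normal((T, n))
    F = np.fft.rfft(x, axis=0)
    f = np.fft.rfftfreq(T)
    keep = (f > band[0]) & (f <= band[1])
    if invert:
        keep = ~keep
        keep[0] = False  # never keep DC
    F[~keep] = 0.0
    y = np.fft.irfft(F, n=T, axis=0)
    y = y - y.mean(axis=0)
    sd = y.std(axis=0)
    sd[sd == 0] = 1.0
    return y / sd


def simulate_region_signals(
    ground_truth: GroundTruth,
    scenario: Scenario,
    group: str,
    seed: int,
    severity: float = 1.0,
) -> np.ndarray:
    """Band-limited region signals (T x K) for one subject of ``group``.

    Disease groups have factor loadings scaled by ``1 - severity *
    attenuation``; region noise is band-limited so the analyzed wavelet level
    carries the planted covariance.
    """
    if group not in ground_truth.attenuation_map:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(seed)
    T = scenario.n_timepoints
    lam = ground_truth.loadings
    K, m = lam.shape
    atten = np.clip(severity * ground_truth.attenuation_map[group], 0.0, 1.0)
    lam_eff = lam * (1.0 - atten)[:, None]
    level = ground_truth.analysis_level
    S = band_limited_noise(T, m, rng, level=level)
    E = band_limited_noise(T, K, rng, level=level)
    return S @ lam_eff.T + ground_truth.noise_sd * E


def simulate_motion(
    T: int,
    repetition_time: float,
    seed: int,
    spike_rate: float = 0.0,
    spike_mm: float = 0.3,
    base_sd: float = 0.01,
) -> MotionTrace:
    """Slow drift plus Poisson-placed translation spikes of given magnitude."""
    rng = np.random.default_rng(seed)
    trans = np.cumsum(rng.normal(0.0, base_sd, size=(T, 3)), axis=0)
    rots = np.cumsum(rng.normal(0.0, base_sd / 50.0, size=(T, 3)), axis=0)
    if spike_rate > 0:
        spikes = rng.random(T) < spike_rate
        spikes[0] = False
        axes = rng.integers(0, 3, size=T)
        for t in np.flatnonzero(spikes):
            trans[t, axes[t]] += spike_mm
    return MotionTrace(translations=trans, rotations=rots, repetition_time=repetition_time)


def simulate_bold(
    parcellation: Parcellation,
    scenario: Scenario,
    group: str,
    ground_truth: GroundTruth,
    seed: int,
    severity: float = 1.0,
) -> tuple[np.ndarray, MotionTrace]:
    """4-D BOLD-like volume (x, y, z, t) plus a motion trace.

    Voxel signal = its region's signal + white voxel noise; voxels outside
    all regions stay zero.
    """
    signals = simulate_region_signals(ground_truth, scenario, group, seed, severity)
    rng = np.random.default_rng([seed, 7])
    labels = parcellation.labels
    T = scenario.n_timepoints
    vol = np.zeros(labels.shape + (T,), dtype=np.float32)
    ids = parcellation.region_ids
    col = {int(rid): c for c, rid in enumerate(ids)}
    vox = np.argwhere(labels > 0)
    lab = labels[tuple(vox.T)]
    cols = np.array([col[int(v)] for v in lab])
    vol[tuple(vox.T)] = (
        signals[:, cols].T + rng.normal(0.0, scenario.voxel_noise_sd, size=(len(vox), T))
    ).astype(np.float32)
    trace = simulate_motion(
        T,
        scenario.repetition_time,
        seed=seed + 101,
        spike_rate=scenario.spike_rate,
        spike_mm=scenario.spike_mm,
    )
    return vol, trace


def region_structure_table(
    parcellation: Parcellation, ground_truth: GroundTruth
) -> pd.DataFrame:
    """Region id, mirror-class structure label, hemisphere, and centroid (mm)."""
    centroids = parcellation.centroids_mm()
    hemi = np.where(centroids[:, 0] < 0, "L", "R")
    labels = [ground_truth.class_labels[c] for c in ground_truth.class_of_region]
    return pd.DataFrame(
        {
            "region_id": parcellation.region_ids,
            "structure_label": labels,
            "hemisphere": hemi,
            "x_mm": centroids[:, 0],
            "y_mm": centroids[:, 1],
            "z_mm": centroids[:, 2],
        }
    )


def simulate_expression(
    parcellation: Parcellation,
    scenario: Scenario,
    ground_truth: GroundTruth,
    seed: int,
    donor_offset_sd: float = 0.5,
    probe_offset_sd: float = 0.3,
    jitter_mm: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Donor expression sample table and probe annotation table.

    Exactly ``scenario.single_hemisphere_donors`` donors sample the left
    hemisphere only; the rest sample both. Per-probe sample values are
    latent class profile + donor offset + probe offset + Gaussian noise.
    With ``add_qc_fail_probe`` one extra probe per gene carries scrambled
    values and ``qc_pass = False``.
    """
    rng = np.random.default_rng(seed)
    regions = region_structure_table(parcellation, ground_truth)
    donor_ids = [f"donor{d:02d}" for d in range(scenario.n_donors)]

    probe_rows = []
    for gene in scenario.genes:
        for k in range(scenario.n_probes_per_gene):
            probe_rows.append({"probe_id": f"{gene}_p{k}", "gene": gene, "qc_pass": True})
        if scenario.add_qc_fail_probe:
            probe_rows.append(
                {"probe_id": f"{gene}_pX", "gene": gene, "qc_pass": False}
            )
    probes = pd.DataFrame(probe_rows)

    probe_off = {p: rng.normal(0.0, probe_offset_sd) for p in probes["probe_id"]}
    donor_off = {d: rng.normal(0.0, donor_offset_sd) for d in donor_ids}

    sample_rows = []
    for di, donor in enumerate(donor_ids):
        hemis = ("L",) if di < scenario.single_hemisphere_donors else ("L", "R")
        block = regions[regions["hemisphere"].isin(hemis)]
        if len(block) == 0:
            raise ValueError(f"no regions on hemisphere(s) {hemis} for donor {donor}")
        for _, reg in block.iterrows():
            pos = (
                np.array([reg["x_mm"], reg["y_mm"], reg["z_mm"]])
                + rng.normal(0.0, jitter_mm, size=3)
            )
            row = {
                "donor_id": donor,
                "structure_label": reg["structure_label"],
                "hemisphere": reg["hemisphere"],
                "x_mm": pos[0],
                "y_mm": pos[1],
                "z_mm": pos[2],
            }
            ridx = int(np.flatnonzero(parcellation.region_ids == reg["region_id"])[0])
            for _, pr in probes.iterrows():
                pid = pr["probe_id"]
                if pr["qc_pass"]:
                    latent = ground_truth.expression_profiles[pr["gene"]][ridx]
                    row[pid] = (
                        latent
                        + donor_off[donor]
                        + probe_off[pid]
                        + rng.normal(0.0, scenario.expression_noise_sd)
                    )
                else:
                    row[pid] = rng.normal(0.0, 1.0)  # failed probe: unrelated values
            sample_rows.append(row)
    return pd.DataFrame(sample_rows), probes


def simulate_behaviour(
    subject_hub_strength: np.ndarray,
    groups: np.ndarray,
    ground_truth: GroundTruth,
    seed: int,
) -> pd.DataFrame:
    """Fluency (slope-coupled to hub strength) and UPDRS (independent) scores."""
    s = np.asarray(subject_hub_strength, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("hub strengths must be finite")
    groups = np.asarray(groups, dtype=object)
    rng = np.random.default_rng(seed)
    fluency = np.empty(len(s))
    updrs = np.empty(len(s))
    for i, g in enumerate(groups):
        fluency[i] = (
            ground_truth.fluency_intercepts[str(g)]
            + ground_truth.fluency_slope * s[i]
            + rng.normal(0.0, ground_truth.fluency_noise_sd)
        )
        updrs[i] = ground_truth.updrs_means[str(g)] + rng.normal(
            0.0, ground_truth.updrs_noise_sd
        )
    mmse = np.clip(rng.normal(28.0, 1.5, size=len(s)), 0, 30)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:03d}" for i in range(len(s))],
            "group": groups,
            "fluency": fluency,
            "updrs": updrs,
            "mmse": mmse,
        }
    )


def simulate_symmetry_donor(
    n_pairs: int,
    n_probes: int,
    symmetric: bool,
    noise_sd: float = 0.3,
    seed: int = 0,
    donor_id: str = "donor00",
) -> pd.DataFrame:
    """One two-hemisphere donor for symmetry-test calibration.

    With ``symmetric=True`` the right-hemisphere values equal the left latent
    profile plus independent noise; otherwise the right hemisphere is
    regenerated independently.
    """
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_pairs, n_probes))
    left = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    if symmetric:
        right = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    else:
        right = rng.standard_normal((n_pairs, n_probes)) + rng.normal(
            0.0, noise_sd, size=latent.shape
        )
    rows = []
    probe_cols = [f"sym_p{j}" for j in range(n_probes)]
    for i in range(n_pairs):
        for hemi, mat, xsign in (("L", left, -1.0), ("R", right, 1.0)):
            row = {
                "donor_id": donor_id,
                "structure_label": f"pair_{i:04d}",
                "hemisphere": hemi,
                "x_mm": xsign * (10.0 + i),
                "y_mm": 0.0,
                "z_mm": 0.0,
            }
            row.update(dict(zip(probe_cols, mat[i])))
            rows.append(row)
    return pd.DataFrame(rows)


def correlated_band_pair(
    T: int,
    rho: float,
    seed: int,
    level: int = 2,
    out_band_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two series whose in-band components correlate at exactly ``rho``.

    The shared and private components are brick-wall filtered into the
    dyadic band of ``level``. Independent noise of sd ``out_band_sd`` is
    added outside a one-octave guard band around that band, so correlations
    estimated at other levels are strongly attenuated while the in-band
    estimate stays close to ``rho`` (MODWT filters are not brick-wall; the
    guard band limits their leakage into the analysis level).
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    comps = band_limited_noise(T, 3, rng, level=level)
    s, ea, eb = comps[:, 0], comps[:, 1], comps[:, 2]
    a_in = np.sqrt(rho) * s + np.sqrt(1 - rho) * ea
    b_in = np.sqrt(rho) * s + np.sqrt(1 - rho) * eb
    lo, hi = _band_for_level(level)
    out = band_limited_noise(T, 2, rng, band=(lo / 2.0, hi * 1.5), invert=True)
    return a_in + out_band_sd * out[:, 0], b_in + out_band_sd * out[:, 1]
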