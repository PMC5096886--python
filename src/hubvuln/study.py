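"""Whole-study simulation: in-memory bundles and on-disk datasets.

:func:`simulate_study` produces everything the analysis needs in memory
(fast path, region-level signals); :func:`simulate_dataset` additionally
expands to voxel space and writes the file layout consumed by
:func:`hubvuln.pipeline.run_pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio
from .parcellation import Parcellation, VolumeGrid, tessellate
from .simulate import (
    GROUPS,
    GroundTruth,
    Scenario,
    make_ground_truth,
    make_mask,
    simulate_behaviour,
    simulate_bold,
    simulate_expression,
    simulate_region_signals,
)

__all__ = ["StudyBundle", "simulate_study", "simulate_dataset", "expected_strengths"]


def expected_strengths(
    ground_truth: GroundTruth, group: str, severity: float = 1.0
) -> np.ndarray:
    """Model-implied Fisher-z strength per region under a group's attenuation."""
    if group not in ground_truth.attenuation_map:
        raise ValueError(f"unknown group label {group!r}")
    atten = np.clip(severity * ground_truth.attenuation_map[group], 0.0, 1.0)
    lam = ground_truth.loadings * (1.0 - atten)[:, None]
    K = lam.shape[0]
    cov = lam @ lam.T + ground_truth.noise_sd**2 * np.eye(K)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    z = np.arctanh(np.clip(corr, -1 + 1e-9, 1 - 1e-9))
    np.fill_diagonal(z, 0.0)
    return z.sum(axis=1)


@dataclass
class StudyBundle:
    """Everything one synthetic study generates, plus its ground truth."""

    scenario: Scenario
    grid: VolumeGrid
    parcellation: Parcellation
    ground_truth: GroundTruth
    subjects: pd.DataFrame
    signals: dict[str, np.ndarray]
    severities: dict[str, float]
    subject_seeds: dict[str, int]
    samples: pd.DataFrame
    probes: pd.DataFrame
    seed: int = 0
    extras: dict = field(default_factory=dict)


def simulate_study(
    scenario: Scenario,
    seed: int,
    mask_shape: tuple[int, int, int] = (22, 22, 22),
    expression_strength_corr: float = 0.3,
    fluency_slope: float = 2.0,
    attenuation_max: dict[str, float] | None = None,
) -> StudyBundle:
    """Simulate a full study at region level (no voxel expansion).

    Deterministic given ``seed``; all derived seeds are recorded in the
    bundle and ground truth.
    """
    grid = make_mask(mask_shape, kind="ellipsoid", seed=seed)
    parc = tessellate(grid, scenario.n_regions, seed=seed)
    gt = make_ground_truth(
        parc,
        scenario,
        seed=seed,
        expression_strength_corr=expression_strength_corr,
        fluency_slope=fluency_slope,
        attenuation_max=attenuation_max,
    )
    rng = np.random.default_rng(seed)
    n = scenario.n_subjects_per_group
    subject_ids, groups = [], []
    for g in GROUPS:
        for i in range(n):
            subject_ids.append(f"{g}{i:03d}")
            groups.append(g)
    seeds = rng.integers(0, 2**31 - 1, size=len(subject_ids))
    sev = rng.uniform(0.4, 1.6, size=len(subject_ids))

    signals: dict[str, np.ndarray] = {}
    severities: dict[str, float] = {}
    subject_seeds: dict[str, int] = {}
    hub_idx = np.flatnonzero(
        np.isin(parc.region_ids, sorted(gt.hub_region_ids))
    )
    true_hub_strength = np.empty(len(subject_ids))
    for i, (sid, g) in enumerate(zip(subject_ids, groups)):
        severity = 1.0 if g == "control" else float(sev[i])
        signals[sid] = simulate_region_signals(
            gt, scenario, g, seed=int(seeds[i]), severity=severity
        )
        severities[sid] = severity
        subject_seeds[sid] = int(seeds[i])
        true_hub_strength[i] = expected_strengths(gt, g, severity)[hub_idx].mean()

    behaviour = simulate_behaviour(
        true_hub_strength, np.array(groups, dtype=object), gt, seed=seed + 1
    )
    behaviour["subject_id"] = subject_ids
    samples, probes = simulate_expression(parc, scenario, gt, seed=seed + 2)
    gt.seeds.update({"study": int(seed), "behaviour": int(seed + 1), "expression": int(seed + 2)})
    return StudyBundle(
        scenario=scenario,
        grid=grid,
        parcellation=parc,
        ground_truth=gt,
        subjects=behaviour,
        signals=signals,
        severities=severities,
        subject_seeds=subject_seeds,
        samples=samples,
        probes=probes,
        seed=seed,
    )


def simulate_dataset(
    scenario: Scenario,
    seed: int,
    data_dir,
    mask_shape: tuple[int, int, int] = (22, 22, 22),
    **study_kwargs,
) -> StudyBundle:
    """Write a complete pipeline input directory (NIfTI + TSV + JSON)."""
    bundle = simulate_study(scenario, seed, mask_shape=mask_shape, **study_kwargs)
    data = Path(data_dir)
    data.mkdir(parents=True, exist_ok=True)
    fileio.write_mask(data / "mask.nii", bundle.grid)
    for sid in bundle.subjects["subject_id"]:
        group = bundle.subjects.set_index("subject_id").loc[sid, "group"]
        vol, trace = simulate_bold(
            bundle.parcellation,
            scenario,
            str(group),
            bundle.ground_truth,
            seed=bundle.subject_seeds[sid],
            severity=bundle.severities[sid],
        )
        fileio.write_nifti(data / f"bold_{sid}.nii", vol, bundle.grid.affine)
        fileio.write_motion(data / f"motion_{sid}.tsv", trace)
    fileio.write_table(data / "subjects.tsv", bundle.subjects)
    fileio.write_table(data / "samples.tsv", bundle.samples)
    fileio.write_table(data / "probes.tsv", bundle.probes)
    fileio.write_ground_truth(data / "ground_truth.json", bundle.ground_truth)
    fileio.write_json(
        data / "scenario.json",
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(bundle.scenario).items()},
    )
    return bundle
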