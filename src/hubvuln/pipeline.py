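"""End-to-end orchestration: QC -> parcellation -> connectivity -> expression
mapping -> network statistics, with provenance.

All stage settings live in :class:`PipelineConfig`; the merged effective
configuration (plus a hash of it) is written next to the results so every
number in the report is reproducible from config + seeds alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio
from .connectivity import build_association_matrix, extract_timeseries, group_mean_matrix
from .expression_map import (
    aggregate_expression,
    interhemispheric_symmetry_test,
    match_regions,
    mirror_samples,
    normalize_within_donor,
)
from .network_stats import (
    bonferroni,
    connection_strength,
    define_hubs,
    fluency_covariance,
    mean_hub_strength,
    pearson_permutation,
    proportional_loss,
)
from .parcellation import apply_coverage_exclusion, region_size_stats, tessellate
from .qc_motion import delta_bold_check, exclude_by_fd, framewise_displacement, scrub

log = logging.getLogger("hubvuln")

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Paths and analysis settings for one pipeline run."""

    data_dir: str
    out_dir: str
    K: int = 100
    seed: int = 0
    wavelet_filter: str = "d4"
    wavelet_level: int = 2
    n_discard: int = 5
    repetition_time: float = 2.0
    fd_limit_mm: float = 5.0
    scrub_threshold_mm: float = 0.5
    min_coverage: float = 0.5
    hub_k: float = 1.5
    n_perm: int = 5000
    delta_bold_alpha: float = 0.05
    control_group: str = "control"
    genes: tuple[str, ...] = ("MAPT", "SNCA")

    def validate(self) -> None:
        data = Path(self.data_dir)
        required = ["mask.nii", "subjects.tsv", "samples.tsv", "probes.tsv"]
        missing = [f for f in required if not (data / f).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs in {data}: {missing}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class _Stage:
    name: str
    started: float = field(default_factory=time.time)

    def done(self) -> None:
        log.info("stage %s finished in %.2fs", self.name, time.time() - self.started)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write results + provenance under ``out_dir``.

    Expects a data directory as written by the ``simulate`` CLI command:
    ``mask.nii``, ``subjects.tsv``, per-subject ``bold_<id>.nii`` and
    ``motion_<id>.tsv``, ``samples.tsv``, ``probes.tsv``.
    """
    config.validate()
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = fileio.read_table(data / "subjects.tsv")
    grid = fileio.read_mask(data / "mask.nii")

    # ---- stage: motion QC (FD limit) -------------------------------------
    stage = _Stage("qc_fd")
    qc: dict[str, dict] = {}
    retained: list[str] = []
    fd_by_subject: dict[str, np.ndarray] = {}
    for sid in subjects["subject_id"]:
        trace = fileio.read_motion(data / f"motion_{sid}.tsv", config.repetition_time)
        fd = framewise_displacement(trace)
        excluded, max_fd = exclude_by_fd(fd, limit=config.fd_limit_mm)
        qc[sid] = {"max_fd_mm": max_fd, "fd_excluded": bool(excluded)}
        fd_by_subject[sid] = fd
        if excluded:
            log.info("subject %s excluded: max FD %.2f mm", sid, max_fd)
        else:
            retained.append(sid)
    if not retained:
        raise RuntimeError("stage qc_fd: all subjects excluded")
    stage.done()

    # ---- stage: parcellation + coverage exclusion ------------------------
    stage = _Stage("parcellate")
    parc = tessellate(grid, config.K, seed=config.seed)
    coverage = []
    bold: dict[str, np.ndarray] = {}
    for sid in retained:
        vol, affine = fileio.read_nifti(data / f"bold_{sid}.nii")
        fileio.check_affines_match(affine, grid.affine)
        bold[sid] = np.asarray(vol, dtype=float)
        coverage.append(bold[sid].std(axis=3) > 0)
    parc = apply_coverage_exclusion(parc, coverage, min_fraction=config.min_coverage)
    size_mean, size_sd = region_size_stats(parc)
    fileio.write_parcellation(out / "parcellation.nii", parc)
    stage.done()

    # ---- stage: time series + delta-BOLD QC ------------------------------
    stage = _Stage("qc_delta_bold")
    series = {}
    for sid in list(retained):
        try:
            rts = extract_timeseries(
                bold[sid], parc, n_discard=config.n_discard,
                repetition_time=config.repetition_time,
            )
        except ValueError as err:
            raise RuntimeError(f"stage extract: subject {sid}: {err}") from err
        fd = fd_by_subject[sid][config.n_discard :]
        try:
            scrubbed, censored = scrub(rts, fd, fd_threshold=config.scrub_threshold_mm)
        except ValueError:
            qc[sid]["delta_bold_excluded"] = True
            retained.remove(sid)
            continue
        res = delta_bold_check(
            rts, scrubbed, fd, censored,
            alpha=config.delta_bold_alpha, seed=config.seed,
            level=config.wavelet_level, filter_name=config.wavelet_filter,
        )
        qc[sid]["delta_bold_excluded"] = bool(res.excluded)
        qc[sid]["delta_bold_statistic"] = res.statistic
        qc[sid]["delta_bold_p"] = res.p_value
        if res.excluded:
            retained.remove(sid)
        else:
            series[sid] = rts
    fileio.write_json(out / "qc.json", qc)
    stage.done()

    # ---- stage: connectivity ---------------------------------------------
    stage = _Stage("connect")
    matrices = {}
    for sid, rts in series.items():
        matrices[sid] = build_association_matrix(
            rts, level=config.wavelet_level, filter_name=config.wavelet_filter,
            source=sid,
        )
        fileio.write_matrix(
            out / f"matrix_{sid}.tsv", matrices[sid].z_values, matrices[sid].region_ids,
            meta={
                "filter": config.wavelet_filter, "level": config.wavelet_level,
                "repetition_time": config.repetition_time, "n_discard": config.n_discard,
            },
        )
    group_of = dict(zip(subjects["subject_id"], subjects["group"]))
    groups = sorted({group_of[sid] for sid in series})
    group_matrices = {
        g: group_mean_matrix([m for s, m in matrices.items() if group_of[s] == g], source=g)
        for g in groups
    }
    stage.done()

    # ---- stage: strengths, hubs, loss ------------------------------------
    stage = _Stage("network")
    strengths = {g: connection_strength(m) for g, m in group_matrices.items()}
    ctrl = config.control_group
    if ctrl not in strengths:
        raise RuntimeError(f"stage network: no retained subjects in group {ctrl!r}")
    hubs = define_hubs(strengths[ctrl], k=config.hub_k, reference_group=ctrl)
    losses = {
        g: proportional_loss(strengths[ctrl], strengths[g], disease_group=g)
        for g in groups
        if g != ctrl
    }
    strength_table = pd.DataFrame(
        {
            "region_id": strengths[ctrl].region_ids,
            **{f"strength_{g}": strengths[g].values for g in groups},
            "hub": [
                int(r) in hubs.region_ids for r in strengths[ctrl].region_ids
            ],
        }
    )
    fileio.write_table(out / "strengths.tsv", strength_table)
    stage.done()

    # ---- stage: expression mapping ---------------------------------------
    stage = _Stage("expression")
    samples = fileio.read_table(data / "samples.tsv")
    probes = fileio.read_table(data / "probes.tsv")
    normalized = normalize_within_donor(samples, probes)
    try:
        symmetry = interhemispheric_symmetry_test(
            normalized, probes, seed=config.seed
        )
        symmetry_out = {
            d: {"mean_z": r.observed_mean_z, "p": r.p_value} for d, r in symmetry.items()
        }
    except ValueError as err:
        symmetry_out = {"error": str(err)}
    mirrored = mirror_samples(normalized)
    region_map = match_regions(parc.centroids_mm(), parc.region_ids, mirrored)
    expression = {}
    for gene in config.genes:
        expression[gene] = aggregate_expression(region_map, mirrored, probes, gene)
        fileio.write_table(out / f"expression_{gene}.tsv", expression[gene])
    stage.done()

    # ---- stage: statistics ------------------------------------------------
    stage = _Stage("stats")
    results: dict = {
        "n_subjects_retained": len(series),
        "groups": {g: sum(1 for s in series if group_of[s] == g) for g in groups},
        "region_sizes": {"mean": size_mean, "sd": size_sd},
        "n_regions": int(len(parc.region_ids)),
        "excluded_regions": sorted(parc.excluded_ids),
        "hubs": {"ids": sorted(hubs.region_ids), "threshold": hubs.threshold, "k": hubs.k},
        "symmetry": symmetry_out,
        "expression_strength": {},
        "expression_loss": {},
        "strength_loss": {},
        "fluency": None,
    }
    m_genes = len(config.genes)
    for gi, gene in enumerate(config.genes):
        expr = expression[gene]
        ok = ~expr["value"].isna()
        x = expr.loc[ok, "value"].to_numpy()
        s = strengths[ctrl].values[ok.to_numpy()]
        t = pearson_permutation(x, s, n_perm=config.n_perm, seed=config.seed + gi)
        per_probe = {}
        for col in [c for c in expr.columns if c.startswith("probe:")]:
            pv = expr.loc[ok, col].to_numpy()
            if np.std(pv) > 0:
                tp = pearson_permutation(pv, s, n_perm=config.n_perm, seed=config.seed + gi)
                per_probe[col.removeprefix("probe:")] = {"r": tp.statistic, "p": tp.p_value}
        results["expression_strength"][gene] = {
            "r": t.statistic,
            "p": t.p_value,
            "p_bonferroni": bonferroni(t.p_value, m_genes),
            "n": int(ok.sum()),
            "per_probe": per_probe,
        }
        for g, loss in losses.items():
            idx = np.isin(expr["region_id"].to_numpy(), loss.region_ids) & ok.to_numpy()
            lmask = np.isin(loss.region_ids, expr.loc[idx, "region_id"].to_numpy())
            t2 = pearson_permutation(
                expr.loc[idx, "value"].to_numpy(),
                loss.values[lmask],
                n_perm=config.n_perm,
                seed=config.seed + 10 + gi,
            )
            results["expression_loss"].setdefault(gene, {})[g] = {
                "r": t2.statistic,
                "p": t2.p_value,
                "p_bonferroni": bonferroni(t2.p_value, m_genes),
            }
    for g, loss in losses.items():
        keep = np.isin(strengths[ctrl].region_ids, loss.region_ids)
        t3 = pearson_permutation(
            strengths[ctrl].values[keep], loss.values,
            n_perm=config.n_perm, seed=config.seed + 20,
        )
        results["strength_loss"][g] = {"r": t3.statistic, "p": t3.p_value}

    patients = [sid for sid in series if group_of[sid] != ctrl]
    patient_groups = sorted({group_of[s] for s in patients})
    if hubs.region_ids and len(patient_groups) >= 2:
        hub_s = np.array(
            [mean_hub_strength(connection_strength(matrices[s]), hubs) for s in patients]
        )
        flu = subjects.set_index("subject_id").loc[patients, "fluency"].to_numpy(dtype=float)
        grp = np.array([group_of[s] for s in patients], dtype=object)
        counts = pd.Series(grp).value_counts()
        if (counts >= 5).all():
            fc = fluency_covariance(hub_s, flu, grp, n_perm=config.n_perm, seed=config.seed)
            results["fluency"] = {
                "main_F": fc.main_F, "main_df": fc.main_df, "main_p": fc.main_p,
                "slope": fc.main_slope,
                "interaction_F": fc.interaction_F, "interaction_p": fc.interaction_p,
                "per_group": {
                    g: {"r": r.statistic, "p": r.p_value} for g, r in fc.per_group.items()
                },
            }
    elif not hubs.region_ids:
        log.warning("empty hub set: fluency analysis skipped")
    stage.done()

    provenance = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
    }
    results["provenance"] = provenance
    fileio.write_json(out / "results.json", results)
    return results


def report(results: dict) -> str:
    """Human-readable summary of a results bundle."""
    lines = ["hubvuln pipeline report", "=" * 40]
    lines.append(f"subjects retained: {results['n_subjects_retained']} {results['groups']}")
    lines.append(
        f"regions: {results['n_regions']} "
        f"(excluded: {len(results['excluded_regions'])}); "
        f"mean size {results['region_sizes']['mean']:.1f} voxels "
        f"(sd {results['region_sizes']['sd']:.1f})"
    )
    hubs = results["hubs"]
    if hubs["ids"]:
        lines.append(f"hubs (k={hubs['k']}): {len(hubs['ids'])} regions, "
                     f"threshold {hubs['threshold']:.3f}")
    else:
        lines.append("WARNING: empty hub set")
    n_genes = len(results["expression_strength"])
    lines.append(f"gene-level correlations (Bonferroni m={n_genes}):")
    for gene, st in results["expression_strength"].items():
        lines.append(
            f"  {gene} expression vs control strength: r={st['r']:.3f} "
            f"p={st['p']:.4g} p_corr={st['p_bonferroni']:.4g} (n={st['n']})"
        )
        for probe, ps in st.get("per_probe", {}).items():
            lines.append(f"    probe {probe}: r={ps['r']:.3f} p={ps['p']:.4g}")
    for gene, by_group in results.get("expression_loss", {}).items():
        for g, st in by_group.items():
            lines.append(
                f"  {gene} expression vs proportional loss [{g}]: "
                f"r={st['r']:.3f} p={st['p']:.4g} p_corr={st['p_bonferroni']:.4g}"
            )
    for g, st in results.get("strength_loss", {}).items():
        lines.append(
            f"  control strength vs proportional loss [{g}]: r={st['r']:.3f} p={st['p']:.4g}"
        )
    flu = results.get("fluency")
    if flu:
        lines.append(
            f"fluency ~ hub strength: F={flu['main_F']:.2f} p={flu['main_p']:.4g} "
            f"slope={flu['slope']:.3f}; interaction F={flu['interaction_F']:.2f} "
            f"p={flu['interaction_p']:.4g}"
        )
        for g, st in flu["per_group"].items():
            lines.append(f"  post hoc [{g}]: r={st['r']:.3f} p={st['p']:.4g}")
    return "\n".join(lines)
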