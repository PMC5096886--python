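"""Donor expression normalization, symmetry testing, and region mapping.

Sample tables are pandas DataFrames with metadata columns
``donor_id, structure_label, hemisphere, x_mm, y_mm, z_mm`` (plus an optional
``mirrored`` flag) and one numeric column per probe. Probe tables have
columns ``probe_id, gene, qc_pass``.

Order of operations for the full mapping: normalize within donor -> mirror ->
match regions -> aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .connectivity import fisher_z

__all__ = [
    "SAMPLE_META_COLS",
    "SymmetryTestResult",
    "probe_columns",
    "normalize_within_donor",
    "interhemispheric_symmetry_test",
    "mirror_samples",
    "match_regions",
    "aggregate_expression",
    "interdonor_variability",
]

SAMPLE_META_COLS = ["donor_id", "structure_label", "hemisphere", "x_mm", "y_mm", "z_mm"]


def probe_columns(samples: pd.DataFrame, probes: pd.DataFrame | None = None) -> list[str]:
    """Probe-value columns of a sample table, optionally limited to a probe table."""
    cols = [c for c in samples.columns if c not in SAMPLE_META_COLS and c != "mirrored"]
    if probes is not None:
        wanted = set(probes["probe_id"].astype(str))
        cols = [c for c in cols if c in wanted]
    if not cols:
        raise ValueError("no probe columns found")
    return cols


def normalize_within_donor(
    samples: pd.DataFrame, probes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Z-score each probe within each donor (n-1 sd) across that donor's samples.

    Probes with zero within-donor sd get missing values with a warning.
    """
    cols = probe_columns(samples, probes)
    out = samples.copy()
    degenerate: list[tuple[str, str]] = []
    for donor, idx in samples.groupby("donor_id").groups.items():
        if len(idx) < 2:
            raise ValueError(f"donor {donor!r} has fewer than 2 samples")
        block = samples.loc[idx, cols].astype(float)
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            degenerate.extend((str(donor), c) for c in sd.index[zero])
        sd = sd.replace(0.0, np.nan)
        out.loc[idx, cols] = (block - mu) / sd
    if degenerate:
        warnings.warn(f"zero-sd probes set missing: {degenerate}", stacklevel=2)
    return out


@dataclass
class SymmetryTestResult:
    """Permutation test of left/right expression correspondence for one donor."""

    donor_id: str
    per_pair_z: np.ndarray
    observed_mean_z: float
    null_mean_zs: np.ndarray
    p_value: float
    n_pairs_permuted: int


def _hemisphere_means(block: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return block.groupby("structure_label")[cols].mean()


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows of A and B (across columns)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def interhemispheric_symmetry_test(
    samples: pd.DataFrame,
    probes: pd.DataFrame | None = None,
    n_random_pairs: int = 10000,
    seed: int = 0,
) -> dict[str, SymmetryTestResult]:
    """Test expression correspondence of homologous left/right regions.

    For every donor with samples in both hemispheres: per structure label
    present on both sides, the Pearson correlation across probes between the
    left and right mean expression vectors is Fisher-z transformed (clipped
    at |r| = 1 - 1e-6). The observed statistic is the mean z. The null is
    built from randomly mismatched left/right label pairings (fixed-point-free
    permutations of the right labels), grouped so that roughly
    ``n_random_pairs`` pair correlations are drawn in total;
    ``p = (#{null >= observed} + 1) / (n_null + 1)``.
    """
    rng = np.random.default_rng(seed)
    cols = probe_columns(samples, probes)
    if len(cols) < 3:
        raise ValueError("need at least 3 probes for a correlation across probes")
    if len(cols) < 100:
        warnings.warn(
            f"only {len(cols)} probes available; the symmetry test is noisy",
            stacklevel=2,
        )
    results: dict[str, SymmetryTestResult] = {}
    for donor, block in samples.groupby("donor_id"):
        hemis = set(block["hemisphere"])
        if not {"L", "R"}.issubset(hemis):
            continue
        left = _hemisphere_means(block[block["hemisphere"] == "L"], cols)
        right = _hemisphere_means(block[block["hemisphere"] == "R"], cols)
        common = sorted(set(left.index) & set(right.index))
        if not common:
            raise ValueError(f"donor {donor!r} has no homologous region pairs")
        Lm = left.loc[common].to_numpy(dtype=float)
        Rm = right.loc[common].to_numpy(dtype=float)
        n_pairs = len(common)
        per_pair_z = fisher_z(_row_correlations(Lm, Rm), clip=True)
        observed = float(np.nanmean(per_pair_z))
        n_null = max(199, n_random_pairs // max(n_pairs, 1))
        null_means = np.empty(n_null)
        for b in range(n_null):
            perm = _derangement(n_pairs, rng)
            null_means[b] = float(
                np.nanmean(fisher_z(_row_correlations(Lm, Rm[perm]), clip=True))
            )
        p = (int(np.sum(null_means >= observed)) + 1) / (n_null + 1)
        results[str(donor)] = SymmetryTestResult(
            donor_id=str(donor),
            per_pair_z=per_pair_z,
            observed_mean_z=observed,
            null_mean_zs=null_means,
            p_value=p,
            n_pairs_permuted=n_null * n_pairs,
        )
    if not results:
        raise ValueError("no donor has samples in both hemispheres")
    return results


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 1:
        return np.array([0])
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def mirror_samples(samples: pd.DataFrame, donors: list | None = None) -> pd.DataFrame:
    """Reflect samples across the midsagittal plane under a symmetry assumption.

    Each (non-mirrored) sample of the selected donors is duplicated with the
    x coordinate sign flipped and the hemisphere label swapped; a ``mirrored``
    column marks provenance. Already-mirrored rows are never re-mirrored, so
    the operation is idempotent up to deduplication.
    """
    out = samples.copy()
    if "mirrored" not in out.columns:
        out["mirrored"] = False
    originals = out[~out["mirrored"]]
    if donors is not None:
        originals = originals[originals["donor_id"].isin(donors)]
    mirrored = originals.copy()
    mirrored["x_mm"] = -mirrored["x_mm"]
    mirrored["hemisphere"] = mirrored["hemisphere"].map({"L": "R", "R": "L"})
    mirrored["mirrored"] = True
    combined = pd.concat([out, mirrored], ignore_index=True)
    return combined.drop_duplicates(
        subset=["donor_id", "structure_label", "hemisphere", "x_mm", "y_mm", "z_mm"]
    ).reset_index(drop=True)


def match_regions(
    centroids_mm: np.ndarray,
    region_ids: np.ndarray,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each imaging region the structure label of its nearest sample.

    Distances are Euclidean in mm, samples pooled across donors (mirrored
    samples included). Exact ties go to the lowest sample row index and are
    flagged. Returns a DataFrame with ``region_id, structure_label,
    sample_index, distance, tie``.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    xyz = samples[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    centroids_mm = np.asarray(centroids_mm, dtype=float)
    d = cdist(centroids_mm, xyz)
    nearest = d.argmin(axis=1)  # argmin returns the lowest index on ties
    dmin = d[np.arange(len(centroids_mm)), nearest]
    ties = (d <= dmin[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "region_id": np.asarray(region_ids, dtype=int),
            "structure_label": samples["structure_label"].to_numpy()[nearest],
            "sample_index": samples.index.to_numpy()[nearest],
            "distance": dmin,
            "tie": ties,
        }
    )


def aggregate_expression(
    region_map: pd.DataFrame,
    samples: pd.DataFrame,
    probes: pd.DataFrame,
    gene: str,
) -> pd.DataFrame:
    """Per-region expression for ``gene``: mean of normalized values over all
    qc-passing probes and all samples whose structure label matches.

    Mirrored duplicates are dropped first (they repeat donor values).
    Regions with no matching samples get a missing value and are flagged.
    Returns columns ``region_id, gene, value, n_samples, missing`` plus one
    ``probe:<id>`` column per contributing probe.
    """
    sel = probes[(probes["gene"] == gene) & probes["qc_pass"].astype(bool)]
    if len(sel) == 0:
        raise ValueError(f"no qc-passing probes for gene {gene!r}")
    cols = [str(p) for p in sel["probe_id"]]
    missing_cols = [c for c in cols if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"sample table lacks probe columns {missing_cols}")
    data = samples
    if "mirrored" in data.columns:
        data = data[~data["mirrored"]]
    by_label = data.groupby("structure_label")
    rows = []
    for _, reg in region_map.iterrows():
        label = reg["structure_label"]
        row: dict = {"region_id": int(reg["region_id"]), "gene": gene}
        if label in by_label.groups:
            block = by_label.get_group(label)[cols].astype(float)
            per_probe = block.mean(axis=0)
            row["value"] = float(np.nanmean(per_probe.to_numpy()))
            row["n_samples"] = int(len(block))
            row["missing"] = False
            for c in cols:
                row[f"probe:{c}"] = float(per_probe[c])
        else:
            row["value"] = np.nan
            row["n_samples"] = 0
            row["missing"] = True
            for c in cols:
                row[f"probe:{c}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def donor_breakdown(
    region_map: pd.DataFrame, samples: pd.DataFrame
) -> dict[int, dict[str, int]]:
    """Contributing sample count per donor for each mapped region."""
    data = samples
    if "mirrored" in data.columns:
        data = data[~data["mirrored"]]
    out: dict[int, dict[str, int]] = {}
    for _, reg in region_map.iterrows():
        block = data[data["structure_label"] == reg["structure_label"]]
        out[int(reg["region_id"])] = (
            block.groupby("donor_id").size().astype(int).to_dict()
        )
    return out


def interdonor_variability(
    region_map: pd.DataFrame,
    samples: pd.DataFrame,
    probes: pd.DataFrame,
    gene: str,
) -> pd.DataFrame:
    """Per-region sd (n-1) across donors of the donor-mean normalized expression.

    Regions with fewer than 2 contributing donors are flagged and get a
    missing sd.
    """
    sel = probes[(probes["gene"] == gene) & probes["qc_pass"].astype(bool)]
    cols = [str(p) for p in sel["probe_id"]]
    data = samples
    if "mirrored" in data.columns:
        data = data[~data["mirrored"]]
    rows = []
    for _, reg in region_map.iterrows():
        block = data[data["structure_label"] == reg["structure_label"]]
        donor_means = (
            block.groupby("donor_id")[cols].mean().mean(axis=1).dropna()
        )
        n = len(donor_means)
        rows.append(
            {
                "region_id": int(reg["region_id"]),
                "gene": gene,
                "sd_across_donors": float(donor_means.std(ddof=1)) if n >= 2 else np.nan,
                "n_donors": n,
                "flagged_single_donor": n < 2,
            }
        )
    return pd.DataFrame(rows)
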