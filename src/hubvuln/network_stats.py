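"""Connection strength, hubs, proportional loss, and inferential statistics.

Connection strength is the signed sum of Fisher-z edge weights to all other
regions (weighted degree, negatives retained). Hubs are regions whose
strength exceeds the reference-group mean by more than k standard deviations
(k = 1.5 by default, n-1 sd). Proportional loss is
``(s_ctrl - s_dis) / s_ctrl``, defined only where ``s_ctrl > 0``.

Permutation p-values use the add-one form ``(b + 1) / (n + 1)`` throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .connectivity import AssociationMatrix

__all__ = [
    "StrengthVector",
    "HubSet",
    "ProportionalLoss",
    "PermutationTestResult",
    "connection_strength",
    "define_hubs",
    "proportional_loss",
    "mean_hub_strength",
    "pearson_permutation",
    "fdr_bh",
    "bonferroni",
    "groupwise_strength_test",
    "fluency_covariance",
    "FluencyCovarianceResult",
]


@dataclass
class StrengthVector:
    """Weighted degree per region."""

    values: np.ndarray
    region_ids: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.shape != self.region_ids.shape:
            raise ValueError("values and region_ids must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("strengths must be finite")


@dataclass
class HubSet:
    region_ids: frozenset[int]
    threshold: float
    k: float
    reference_group: str = ""


@dataclass
class ProportionalLoss:
    """Per-region proportional strength loss relative to controls."""

    region_ids: np.ndarray
    values: np.ndarray
    disease_group: str
    excluded_regions: tuple[int, ...]


@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int
    corrected_p: float | None = None
    correction_method: str | None = None
    statistic_name: str = "r"


def connection_strength(matrix: AssociationMatrix, source: str | None = None) -> StrengthVector:
    """s_i = sum over j != i of z_ij (signed; diagonal excluded)."""
    z = matrix.z_values.copy()
    np.fill_diagonal(z, 0.0)
    return StrengthVector(
        values=z.sum(axis=1),
        region_ids=matrix.region_ids.copy(),
        source=source if source is not None else matrix.source,
    )


def define_hubs(strengths: StrengthVector, k: float = 1.5, reference_group: str = "") -> HubSet:
    """Regions with strength strictly above mean + k * sd (n-1 sd)."""
    s = strengths.values
    if len(s) < 3:
        raise ValueError("need at least 3 regions to define hubs")
    sd = s.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero strength variance: empty hub set", stacklevel=2)
        return HubSet(frozenset(), float(s.mean()), k, reference_group)
    theta = float(s.mean() + k * sd)
    hubs = frozenset(int(i) for i in strengths.region_ids[s > theta])
    return HubSet(hubs, theta, k, reference_group)


def proportional_loss(
    ctrl: StrengthVector, dis: StrengthVector, disease_group: str = ""
) -> ProportionalLoss:
    """L_i = (s_ctrl - s_dis) / s_ctrl where s_ctrl > 0; others excluded."""
    if not np.array_equal(ctrl.region_ids, dis.region_ids):
        raise ValueError("control and disease strength vectors differ in regions")
    ok = ctrl.values > 0
    excluded = tuple(int(i) for i in ctrl.region_ids[~ok])
    loss = (ctrl.values[ok] - dis.values[ok]) / ctrl.values[ok]
    return ProportionalLoss(
        region_ids=ctrl.region_ids[ok].copy(),
        values=loss,
        disease_group=disease_group,
        excluded_regions=excluded,
    )


def mean_hub_strength(strengths: StrengthVector, hubs: HubSet) -> float:
    """Mean of a subject's region strengths over the hub set."""
    if not hubs.region_ids:
        raise ValueError("empty hub set")
    mask = np.isin(strengths.region_ids, list(hubs.region_ids))
    if mask.sum() != len(hubs.region_ids):
        raise ValueError("hub ids missing from the strength vector")
    return float(strengths.values[mask].mean())


def pearson_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationTestResult:
    """Pearson correlation with a permutation p-value.

    The null is built by permuting ``y``; ``p = (b + 1) / (n_perm + 1)`` with
    b the number of permuted statistics at least as extreme as the observed
    one (|r| comparison when two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance input")
    n = len(x)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r_obs = float(xs @ ys / n)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
    r_null = perm @ xs / n
    if alternative == "two-sided":
        b = int(np.sum(np.abs(r_null) >= abs(r_obs)))
    elif alternative == "greater":
        b = int(np.sum(r_null >= r_obs))
    elif alternative == "less":
        b = int(np.sum(r_null <= r_obs))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationTestResult(
        statistic=r_obs,
        n_permutations=n_perm,
        p_value=(b + 1) / (n_perm + 1),
        seed=seed,
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-D array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bonferroni(p_values, m: int):
    """min(1, p * m); ``m`` must cover the number of tests."""
    p = np.asarray(p_values, dtype=float)
    n_tests = 1 if p.ndim == 0 else len(p)
    if m < n_tests:
        raise ValueError(f"m={m} smaller than the number of tests ({n_tests})")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t statistic per column (a, b: subjects x regions)."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(va + vb)


@dataclass
class GroupStrengthTestResult:
    region_ids: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    p_fdr: np.ndarray
    skipped_regions: tuple[int, ...]
    n_permutations: int
    seed: int


def groupwise_strength_test(
    strengths_a: np.ndarray,
    strengths_b: np.ndarray,
    region_ids: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> GroupStrengthTestResult:
    """Per-region Welch t test of group strength, permutation p, BH-FDR.

    ``strengths_a`` / ``strengths_b`` are subjects x regions arrays of
    per-subject strengths. The null permutes group labels; p-values are
    two-sided ``(b + 1) / (n_perm + 1)``, then BH-adjusted across regions.
    Regions with degenerate variance in both groups are skipped and logged.
    """
    a = np.asarray(strengths_a, dtype=float)
    b = np.asarray(strengths_b, dtype=float)
    region_ids = np.asarray(region_ids, dtype=int)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("strength arrays must be subjects x regions with equal regions")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    na = a.shape[0]
    stacked = np.vstack([a, b])
    t_obs = _welch_t(a, b)
    degenerate = ~np.isfinite(t_obs)
    skipped = tuple(int(i) for i in region_ids[degenerate])
    if skipped:
        warnings.warn(f"degenerate variance, regions skipped: {skipped}", stacklevel=2)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(stacked.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(stacked.shape[0])
        t_p = _welch_t(stacked[perm[:na]], stacked[perm[na:]])
        exceed += np.abs(t_p) >= np.abs(t_obs)
    p = (exceed + 1) / (n_perm + 1)
    keep = ~degenerate
    p_fdr = np.full_like(p, np.nan)
    if keep.any():
        p_fdr[keep] = fdr_bh(p[keep])
    return GroupStrengthTestResult(
        region_ids=region_ids,
        t_values=t_obs,
        p_values=p,
        p_fdr=p_fdr,
        skipped_regions=skipped,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class FluencyCovarianceResult:
    main_F: float
    main_df: tuple[float, float]
    main_p: float
    main_slope: float
    interaction_F: float
    interaction_df: tuple[float, float]
    interaction_p: float
    per_group: dict[str, PermutationTestResult] = field(default_factory=dict)


def fluency_covariance(
    hub_strengths: np.ndarray,
    fluency: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> FluencyCovarianceResult:
    """Covariance analysis of verbal fluency on hub connection strength.

    Fits ``fluency ~ group + strength`` and reports the type-II F test for
    the strength main effect, plus the group x strength interaction F from
    the full-factorial model, plus per-group Pearson correlations with
    permutation p-values as post hoc tests.
    """
    df = pd.DataFrame(
        {
            "fluency": np.asarray(fluency, dtype=float),
            "strength": np.asarray(hub_strengths, dtype=float),
            "group": np.asarray(groups, dtype=object),
        }
    )
    labels = df["group"].unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = df.groupby("group").size()
    if (counts < 5).any():
        raise ValueError("need at least 5 subjects per group")
    if df["strength"].std(ddof=0) == 0.0:
        raise ValueError("rank deficiency: 'strength' is constant")
    for g in labels:
        if df.loc[df["group"] == g, "strength"].std(ddof=0) == 0.0:
            raise ValueError(f"rank deficiency: 'strength' constant within group {g!r}")

    main = smf.ols("fluency ~ C(group) + strength", data=df).fit()
    main_aov = sm.stats.anova_lm(main, typ=2)
    inter = smf.ols("fluency ~ C(group) * strength", data=df).fit()
    inter_aov = sm.stats.anova_lm(inter, typ=2)
    s_row = main_aov.loc["strength"]
    i_row = inter_aov.loc["C(group):strength"]
    resid_df_main = float(main_aov.loc["Residual", "df"])
    resid_df_inter = float(inter_aov.loc["Residual", "df"])

    def _f_and_p(row) -> tuple[float, float]:
        # a term explaining exactly nothing yields 0/0 when the model is
        # otherwise saturated; report F = 0, p = 1 in that case
        if row["sum_sq"] <= 1e-12:
            return 0.0, 1.0
        return float(row["F"]), float(row["PR(>F)"])

    main_F, main_p = _f_and_p(s_row)
    inter_F, inter_p = _f_and_p(i_row)

    per_group: dict[str, PermutationTestResult] = {}
    for gi, g in enumerate(sorted(map(str, labels))):
        block = df[df["group"].astype(str) == g]
        try:
            per_group[g] = pearson_permutation(
                block["strength"].to_numpy(),
                block["fluency"].to_numpy(),
                n_perm=n_perm,
                seed=seed + gi,
            )
        except ValueError:
            warnings.warn(
                f"degenerate variance in group {g!r}: post hoc skipped", stacklevel=2
            )
    return FluencyCovarianceResult(
        main_F=main_F,
        main_df=(float(s_row["df"]), resid_df_main),
        main_p=main_p,
        main_slope=float(main.params["strength"]),
        interaction_F=inter_F,
        interaction_df=(float(i_row["df"]), resid_df_inter),
        interaction_p=inter_p,
        per_group=per_group,
    )
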