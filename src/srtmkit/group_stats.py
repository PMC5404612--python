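"""Condition contrasts at ROI and voxel level, correlation screens, and the
summary report table.

ROI-level ΔBP is compared between conditions with a two-tailed paired
t-test, reported uncorrected with the Bonferroni threshold printed
alongside.  Voxel-level contrasts produce a (1 - p) significance image,
displayed above 0.90, with the sign of the mean paired difference recorded
separately so that the two directions remain distinguishable.  No
voxel-level multiple-comparison correction is applied (the maps are
descriptive, as in the ROI analysis they accompany).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionContrast",
    "SignificanceMap",
    "paired_ttest",
    "bonferroni_threshold",
    "pearson_screen",
    "voxelwise_contrast",
    "percent_significant_voxels",
    "build_table1",
]

DISPLAY_ONE_MINUS_P = 0.90


@dataclass(frozen=True)
class RegionContrast:
    region: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class SignificanceMap:
    """Voxel image of (1 - p) with display mask and paired-difference sign."""

    one_minus_p: np.ndarray   # float in [0, 1]; 0 outside valid mask
    displayed: np.ndarray     # bool: valid and (1 - p) > threshold
    direction: np.ndarray     # int8 sign of mean(a - b); 0 outside valid
    valid: np.ndarray         # bool: voxels where the test was performed
    threshold: float = DISPLAY_ONE_MINUS_P


def paired_ttest(
    delta_a: np.ndarray, delta_b: np.ndarray
) -> tuple[float, float, float]:
    """Two-tailed paired Student t-test.

    Returns ``(t, p, mean_difference)`` with t on n-1 degrees of freedom
    computed from the paired differences.  Zero-variance differences yield
    ``(nan, nan, mean_diff)`` — flagged degenerate by the caller.
    """
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
        return float("nan"), float("nan"), float(d.mean())
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), float(d.mean())


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance threshold, ``alpha / m``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def pearson_screen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its t-based two-sided p-value.

    Returns ``(nan, nan)`` when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def voxelwise_contrast(
    dbp_maps_a: np.ndarray,
    dbp_maps_b: np.ndarray,
    valid_mask: np.ndarray,
    threshold: float = DISPLAY_ONE_MINUS_P,
) -> SignificanceMap:
    """Per-voxel paired t-test of ΔBP between two conditions.

    Parameters
    ----------
    dbp_maps_a, dbp_maps_b
        ``(n_subjects, x, y, z)`` subject-aligned ΔBP images per condition.
    valid_mask
        Boolean 3-D mask of voxels with valid fits in all subjects and both
        conditions.

    The (1 - p) image is computed in every valid voxel; voxels whose paired
    differences have zero variance are excluded from the valid set.
    """
    a = np.asarray(dbp_maps_a, dtype=float)
    b = np.asarray(dbp_maps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 4:
        raise ValueError("condition image stacks must share (n_subjects, x, y, z) shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects for a paired test")
    mask = np.asarray(valid_mask, dtype=bool)
    if mask.shape != a.shape[1:]:
        raise ValueError("valid mask must match the image grid")

    d = (a - b)[:, mask]                 # (n, n_valid_vox)
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    nonzero = sd_d > 0
    t = np.zeros(d.shape[1])
    p = np.ones(d.shape[1])
    t[nonzero] = mean_d[nonzero] / (sd_d[nonzero] / np.sqrt(n))
    p[nonzero] = 2.0 * stats.t.sf(np.abs(t[nonzero]), df=n - 1)

    shape = mask.shape
    omp = np.zeros(shape)
    direction = np.zeros(shape, dtype=np.int8)
    valid = np.zeros(shape, dtype=bool)
    vox_idx = np.where(mask)
    omp[vox_idx] = np.where(nonzero, 1.0 - p, 0.0)
    direction[vox_idx] = np.sign(mean_d).astype(np.int8)
    valid[vox_idx] = nonzero
    displayed = valid & (omp > threshold)
    return SignificanceMap(
        one_minus_p=omp, displayed=displayed, direction=direction,
        valid=valid, threshold=threshold,
    )


def percent_significant_voxels(
    sig_map: SignificanceMap,
    region_mask: np.ndarray,
) -> float:
    """Percent of valid in-region voxels that pass the display threshold.

    Voxels flagged invalid by the kinetic fit (or degenerate in the test)
    are excluded from numerator and denominator alike.
    """
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    denom = int((region & sig_map.valid).sum())
    if denom == 0:
        raise ValueError("region contains no valid voxels")
    num = int((region & sig_map.displayed).sum())
    return 100.0 * num / denom


# ---------------------------------------------------------------------------
# report table

#: (report row, member regions to pool, volume column in ml)
_TABLE_ROWS: list[tuple[str, tuple[str, ...], float]] = [
    ("Striatum", ("caudate_left", "caudate_right", "putamen_left", "putamen_right",
                  "ventral_striatum_left", "ventral_striatum_right"), 42.6),
    ("Putamen", ("putamen_left", "putamen_right"), 21.9),
    ("Putamen L", ("putamen_left",), 10.7),
    ("Putamen R", ("putamen_right",), 11.3),
    ("Caudate", ("caudate_left", "caudate_right"), 20.7),
    ("Caudate L", ("caudate_left",), 10.2),
    ("Caudate R", ("caudate_right",), 10.5),
    ("Ventral striatum", ("ventral_striatum_left", "ventral_striatum_right"), 2.9),
    ("Ventral striatum L", ("ventral_striatum_left",), 1.4),
    ("Ventral striatum R", ("ventral_striatum_right",), 1.5),
]


def build_table1(
    dbp_table: pd.DataFrame,
    condition_a: str = "MP+LPS",
    condition_b: str = "MP+PBO",
    lps_condition: str = "LPS",
    region_volumes_ml: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Region-by-condition summary: mean (SD) ΔBP per condition and the
    paired two-tailed p for condition_a vs condition_b.

    Expects a long-format table with columns ``subject, condition, region,
    delta_bp``.  Regions present in the input are matched against the
    standard row layout (pooled rows use the ``region`` value directly if a
    pooled entry exists, e.g. ``putamen``); rows whose regions are absent
    are skipped; rows with incomplete condition pairs are flagged.  The
    LPS-alone column is descriptive only (its small arm supports no test).
    Output row order is fixed, independent of input ordering.
    """
    df = dbp_table.copy()
    required = {"subject", "condition", "region", "delta_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"dbp table needs columns {sorted(required)}")

    regions_present = set(df["region"])
    rows = []
    for title, members, volume in _TABLE_ROWS:
        explicit = title.lower().replace(" ", "_")
        if explicit in regions_present:
            sub = df[df["region"] == explicit]
        elif len(members) == 1 and members[0] in regions_present:
            sub = df[df["region"] == members[0]]
        elif set(members) <= regions_present:
            # pool by averaging member-region ΔBP per subject, volume-free
            # fallback when no explicit pooled ROI was computed
            vols = region_volumes_ml or {}
            w = np.array([vols.get(m, 1.0) for m in members])
            sub = (
                df[df["region"].isin(members)]
                .pivot_table(index=["subject", "condition"], columns="region",
                             values="delta_bp")
                .reindex(columns=list(members))
            )
            pooled = (sub * w).sum(axis=1) / w.sum()
            sub = pooled.rename("delta_bp").reset_index()
        else:
            continue
        row: dict = {"region": title, "volume_ml": volume}
        piv = sub.pivot_table(index="subject", columns="condition", values="delta_bp")
        for cond, key in ((condition_a, "a"), (condition_b, "b")):
            if cond in piv.columns:
                vals = piv[cond].dropna()
                row[f"mean_{key}"] = float(vals.mean())
                row[f"sd_{key}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                row[f"n_{key}"] = int(len(vals))
        if lps_condition in piv.columns:
            vals = piv[lps_condition].dropna()
            row["mean_lps"] = float(vals.mean())
            row["sd_lps"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row["n_lps"] = int(len(vals))
        if condition_a in piv.columns and condition_b in piv.columns:
            paired = piv[[condition_a, condition_b]].dropna()
            if len(paired) >= 2:
                t, p, _ = paired_ttest(
                    paired[condition_a].to_numpy(), paired[condition_b].to_numpy()
                )
                row["t_stat"], row["p_value"] = t, p
                row["incomplete"] = False
            else:
                row["incomplete"] = True
        else:
            row["incomplete"] = condition_a in piv.columns or condition_b in piv.columns
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.reset_index(drop=True)
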