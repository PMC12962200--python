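"""Segmentation-comparison metrics for paired acquisitions.

Compares tissue segmentations of the same brain acquired under two RF shim
conditions: global tissue fractions inside a unified brain mask, a
voxelwise Multiclass Jaccard Similarity (MJS) map of the two fraction
estimates, hemispheric asymmetry indices of regional volumes, and paired
two-tailed t-tests across subjects.

For a voxel with per-class fraction estimates A_n and B_n (n over the N=3
classes GM, WM, CSF),

    MJS = sum_n w_n * min(A_n, B_n) / max(A_n, B_n)

where the class weight w_n is the mean fraction (A_n + B_n)/2, renormalised
to sum to 1 over classes.  MJS is 1 for identical composition and 0 for
fully disjoint one-hot compositions.  The asymmetry index of a paired
region with hemispheric volumes V_left, V_right is

    AsI = (V_left - V_right) / (V_left + V_right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import VoxelGrid

logger = logging.getLogger(__name__)

CLASS_NAMES = ("GM", "WM", "CSF")


@dataclass
class TissueFractionMap:
    """Per-voxel tissue-class fractions on a voxel grid.

    ``fractions`` has shape (n_classes, nx, ny, nz) with values in [0, 1];
    inside an analysis mask the per-voxel class sum should not exceed 1
    (up to rounding).
    """

    grid: VoxelGrid
    fractions: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 4:
            raise ValueError("fractions must be 4-D (class, x, y, z)")
        if self.fractions.shape[1:] != self.grid.shape:
            raise ValueError("fraction map spatial shape does not match grid")
        if self.fractions.shape[0] != len(self.class_names):
            raise ValueError("class axis length does not match class_names")
        if np.any(self.fractions < -1e-9) or np.any(self.fractions > 1 + 1e-6):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.fractions.shape[0]


@dataclass
class PairedTestResult:
    """Classical paired two-tailed t-test on per-subject differences."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int
    degenerate: bool = False


def union_masks(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise union of two brain masks defined on the same grid."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return mask_a | mask_b


def tissue_fractions(frac_map: TissueFractionMap, mask: np.ndarray) -> dict[str, float]:
    """Percentage of total tissue per class inside the mask; sums to 100."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frac_map.grid.shape:
        raise ValueError("mask shape does not match the fraction map grid")
    if not mask.any():
        raise ValueError("mask is empty")
    sums = frac_map.fractions[:, mask].sum(axis=1)
    total = sums.sum()
    if total <= 0:
        raise ValueError("all tissue fractions are zero inside the mask")
    return {
        name: 100.0 * s / total for name, s in zip(frac_map.class_names, sums)
    }


def mjs_map(
    map_a: TissueFractionMap,
    map_b: TissueFractionMap,
    mask: np.ndarray,
) -> np.ndarray:
    """Voxelwise Multiclass Jaccard Similarity between two fraction maps.

    Class weights are the per-voxel mean fractions (A_n + B_n)/2,
    renormalised to sum to 1 over classes; class terms with A_n = B_n = 0
    contribute zero (their weight is zero anyway).  Voxels inside the mask
    where either map carries no tissue at all are excluded (NaN) and their
    count logged.  Outside the mask the output is NaN.  Use ``1 - mjs`` for
    a difference-highlighting view.
    """
    if map_a.grid != map_b.grid:
        raise ValueError("fraction maps live on different grids")
    if map_a.n_classes != map_b.n_classes:
        raise ValueError(
            f"class-count mismatch: {map_a.n_classes} vs {map_b.n_classes}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != map_a.grid.shape:
        raise ValueError("mask shape does not match the fraction map grid")
    if not mask.any():
        raise ValueError("mask is empty")

    a = map_a.fractions[:, mask]  # (n_classes, M)
    b = map_b.fractions[:, mask]
    sum_a, sum_b = a.sum(axis=0), b.sum(axis=0)
    valid = (sum_a > 0) & (sum_b > 0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("mjs_map: excluded %d masked voxels with an all-zero map", n_excluded)

    w = 0.5 * (a + b)
    w_sum = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(w_sum > 0, w / w_sum, 0.0)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        ratio = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 0.0)
    vals = (w * ratio).sum(axis=0)
    vals[~valid] = np.nan

    out = np.full(map_a.grid.shape, np.nan)
    out[mask] = vals
    return out


def asymmetry_index(v_left: float, v_right: float) -> float:
    """Hemispheric asymmetry index (V_left - V_right) / (V_left + V_right)."""
    v_left, v_right = float(v_left), float(v_right)
    if v_left < 0 or v_right < 0:
        raise ValueError("volumes must be nonnegative")
    total = v_left + v_right
    if total <= 0:
        raise ValueError("both volumes are zero; AsI undefined")
    return (v_left - v_right) / total


def paired_t_test(values_a, values_b) -> PairedTestResult:
    """Paired two-tailed t-test on matched samples.

    Degenerate cases follow explicit conventions: identical samples give
    p = 1 with a degenerate flag; zero-variance differences with nonzero
    mean give p = 0 (the difference is deterministic).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, df, 1.0, n, degenerate=True)
        return PairedTestResult(np.inf * np.sign(mean), df, 0.0, n, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(float(t), df, float(p), n)


def read_volume_table(path) -> pd.DataFrame:
    """Read a region-volume CSV into the canonical long layout.

    Accepts either the long layout (columns region, hemisphere, volume_mm3)
    or the common wide layout (region, left_volume, right_volume), which is
    melted into the long one.  Hemisphere values are left/right/none.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if {"region", "hemisphere", "volume_mm3"} <= set(cols):
        out = df.rename(columns={cols["region"]: "region",
                                 cols["hemisphere"]: "hemisphere",
                                 cols["volume_mm3"]: "volume_mm3"})
        out = out[["region", "hemisphere", "volume_mm3"]]
    elif {"region", "left_volume", "right_volume"} <= set(cols):
        out = df.melt(
            id_vars=[cols["region"]],
            value_vars=[cols["left_volume"], cols["right_volume"]],
            var_name="hemisphere",
            value_name="volume_mm3",
        )
        out["hemisphere"] = out["hemisphere"].map(
            {cols["left_volume"]: "left", cols["right_volume"]: "right"}
        )
        out = out.rename(columns={cols["region"]: "region"})
    else:
        raise ValueError(
            "expected columns (region, hemisphere, volume_mm3) or "
            "(region, left_volume, right_volume)"
        )
    if (out["volume_mm3"] < 0).any():
        raise ValueError("volumes must be nonnegative")
    return out.reset_index(drop=True)


def compare_solutions(
    tables_a: list[pd.DataFrame],
    tables_b: list[pd.DataFrame],
    adjust: bool = True,
) -> pd.DataFrame:
    """Region-by-region comparison of two shim conditions across subjects.

    ``tables_a``/``tables_b`` hold one long-layout volume table per subject
    (same subject order in both conditions).  Per region and hemisphere a
    paired t-test compares volumes across subjects; per bilaterally paired
    region a paired t-test compares the asymmetry indices.  P-values are
    reported unadjusted (flagged as such); a Benjamini-Hochberg column is
    appended when ``adjust`` is true.  Regions present in only one
    condition are excluded and logged.
    """
    if len(tables_a) != len(tables_b):
        raise ValueError("need one table per subject in each condition")
    if len(tables_a) < 2:
        raise ValueError("need at least two subjects for a paired test")

    def _pivot(tables):
        frames = []
        for i, t in enumerate(tables):
            t = t.copy()
            t["subject"] = i
            frames.append(t)
        df = pd.concat(frames, ignore_index=True)
        return df.set_index(["region", "hemisphere", "subject"])["volume_mm3"]

    va, vb = _pivot(tables_a), _pivot(tables_b)
    keys_a = set(va.index.droplevel("subject"))
    keys_b = set(vb.index.droplevel("subject"))
    shared = sorted(keys_a & keys_b)
    dropped = (keys_a | keys_b) - set(shared)
    if dropped:
        logger.info("compare_solutions: excluded %d one-condition regions: %s",
                    len(dropped), sorted(dropped))

    n_subj = len(tables_a)
    rows = []
    for region, hemi in shared:
        a_vals = np.array([va[region, hemi, s] for s in range(n_subj)])
        b_vals = np.array([vb[region, hemi, s] for s in range(n_subj)])
        res = paired_t_test(a_vals, b_vals)
        rows.append({
            "region": region, "hemisphere": hemi, "metric": "volume_mm3",
            "mean_a": a_vals.mean(), "mean_b": b_vals.mean(),
            "t": res.t_statistic, "df": res.degrees_of_freedom,
            "p_unadjusted": res.p_value, "degenerate": res.degenerate,
        })

    paired_regions = sorted(
        {r for r, h in shared if h == "left"} & {r for r, h in shared if h == "right"}
    )
    for region in paired_regions:
        asi_a = np.array([
            asymmetry_index(va[region, "left", s], va[region, "right", s])
            for s in range(n_subj)
        ])
        asi_b = np.array([
            asymmetry_index(vb[region, "left", s], vb[region, "right", s])
            for s in range(n_subj)
        ])
        res = paired_t_test(asi_a, asi_b)
        rows.append({
            "region": region, "hemisphere": "both", "metric": "asymmetry_index",
            "mean_a": asi_a.mean(), "mean_b": asi_b.mean(),
            "t": res.t_statistic, "df": res.degrees_of_freedom,
            "p_unadjusted": res.p_value, "degenerate": res.degenerate,
        })

    out = pd.DataFrame(rows)
    out["note"] = "not adjusted for multiple comparisons"
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_unadjusted"].to_numpy(), method="fdr_bh")[1]
    return out
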