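"""ROI-level intensity statistics for coaggregation analysis.

Three readouts quantify how two channels relate within a membrane-sheet ROI:

* the background-corrected mean intensity (membrane ROI mean minus the mean
  of a background ROI placed next to the sheet),
* the Pearson correlation coefficient (PCC) between the two channels' pixel
  intensities, computed over the membrane ROI only, with no intensity
  thresholding,
* the rSDM ("relative standard deviation of the mean"): the SD of the pixel
  intensities in the ROI divided by their mean — a clustering index that
  rises when signal concentrates into fewer, brighter puncta.

Condition summaries are expressed as percent of a reference condition
(typically "fixed" = 100%), with the replicate hierarchy sheets -> mean per
experiment -> mean +/- SD across experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sheetquant.core_io import Micrograph, Roi, require_same_grid


@dataclass(frozen=True)
class RoiStats:
    """Per-ROI statistics for one condition."""

    mean_intensity_au: float | None = None
    pcc: float | None = None
    rsdm: float | None = None
    condition: str = ""
    missing_reason: str | None = None


def corrected_mean(img: Micrograph, membrane_roi: Roi, background_roi: Roi) -> float:
    """Membrane-ROI mean intensity minus background-ROI mean intensity.

    The result may be negative (e.g. with a bright background region); it is
    reported as-is so that downstream averaging remains unbiased.
    """
    m_mask = membrane_roi.mask(img.shape)
    b_mask = background_roi.mask(img.shape)
    if np.any(m_mask & b_mask):
        raise ValueError("membrane and background ROIs must be disjoint")
    return float(img.pixels[m_mask].mean() - img.pixels[b_mask].mean())


def pearson(img_a: Micrograph, img_b: Micrograph, roi: Roi) -> float:
    """Pearson correlation of the two channels' pixel intensities in the ROI.

    Raises ``ValueError`` when either channel has zero variance in the ROI
    (the correlation is undefined there).
    """
    require_same_grid(img_a, img_b)
    mask = roi.mask(img_a.shape)
    if mask.sum() < 2:
        raise ValueError("PCC needs an ROI of at least 2 pixels")
    a = img_a.pixels[mask].astype(float)
    b = img_b.pixels[mask].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("PCC undefined: zero variance in at least one channel")
    r = np.corrcoef(a, b)[0, 1]
    return float(r)


def rsdm(img: Micrograph, roi: Roi) -> float:
    """SD of the ROI pixel intensities divided by their mean (clustering index).

    Undefined for non-positive mean intensity (raises ``ValueError``).
    The population SD (ddof=0) is used, so a balanced binary ROI (half 0,
    half 1) gives exactly 1.0 and a uniform ROI gives 0.
    """
    vals = img.pixels[roi.mask(img.shape)].astype(float)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(f"rSDM undefined for ROI mean {mean} <= 0")
    return float(vals.std(ddof=0) / mean)


def roi_stats(
    img_a: Micrograph,
    img_b: Micrograph | None,
    membrane_roi: Roi,
    background_roi: Roi | None = None,
    condition: str = "",
) -> RoiStats:
    """Convenience bundle of the three ROI statistics; missing ones carry a reason."""
    mean_val = None
    pcc_val = None
    rsdm_val = None
    reason = None
    if background_roi is not None:
        mean_val = corrected_mean(img_a, membrane_roi, background_roi)
    try:
        rsdm_val = rsdm(img_a, membrane_roi)
    except ValueError as exc:
        reason = str(exc)
    if img_b is not None:
        try:
            pcc_val = pearson(img_a, img_b, membrane_roi)
        except ValueError as exc:
            reason = str(exc) if reason is None else f"{reason}; {exc}"
    return RoiStats(
        mean_intensity_au=mean_val,
        pcc=pcc_val,
        rsdm=rsdm_val,
        condition=condition or img_a.condition,
        missing_reason=reason,
    )


def normalize_to_reference(
    values: pd.DataFrame,
    reference_condition: str,
    value_col: str = "value",
    condition_col: str = "condition",
    experiment_col: str | None = "experiment",
) -> pd.DataFrame:
    """Express per-condition values as percent of the reference condition.

    Each replicate value is divided by the reference-condition mean and
    multiplied by 100, so the reference maps to 100% by construction.  When
    an experiment column is present, sheet-level values are first averaged
    per experiment and the summary SD is taken across experiments.

    Returns a table with columns ``condition, n, mean_percent, sd_percent``.
    """
    df = values.copy()
    if reference_condition not in set(df[condition_col]):
        raise ValueError(f"reference condition {reference_condition!r} not in table")
    if experiment_col is not None and experiment_col in df.columns:
        df = (
            df.groupby([condition_col, experiment_col], as_index=False)[value_col]
            .mean()
        )
    ref_mean = df.loc[df[condition_col] == reference_condition, value_col].mean()
    if ref_mean == 0:
        raise ValueError("reference-condition mean is zero; percent normalization undefined")
    df["percent"] = df[value_col] / ref_mean * 100.0
    out = (
        df.groupby(condition_col)["percent"]
        .agg(n="count", mean_percent="mean", sd_percent=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out
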