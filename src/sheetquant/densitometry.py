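"""Western-blot band densitometry and the sAPPalpha cleavage ratio.

Input is a band-intensity table (gel-image segmentation is out of scope;
band and background regions are drawn manually in practice).  Per band the
integrated background intensity, measured in a region of identical area, is
subtracted from the integrated band intensity.  The cleavage readout for a
construct is

    ratio = (sAPPalpha_lysate + sAPPalpha_supernatant) / (APP_mature + APP_immature)

i.e. released ectodomain over total full-length APP.  Because both the
numerator and the denominator are sums of bands from the same exposure, the
ratio is invariant to a global lane scaling.  Construct ratios are expressed
as percent of the wild-type construct (wild type = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BAND_LABELS = ("sAPPalpha", "APP_mature", "APP_immature", "other")
FRACTION_LABELS = ("lysate", "supernatant")


@dataclass(frozen=True)
class BandMeasurement:
    """One quantified blot band."""

    lane: str
    band: str
    integrated_au: float
    background_au: float

    def __post_init__(self) -> None:
        if self.band not in BAND_LABELS:
            raise ValueError(f"band must be one of {BAND_LABELS}, got {self.band!r}")

    @property
    def corrected_au(self) -> float:
        return self.integrated_au - self.background_au


def corrected_table(bands: pd.DataFrame) -> pd.DataFrame:
    """Add a ``corrected`` column (integrated minus background) to a band table."""
    required = {"band", "integrated", "background"}
    if not required.issubset(bands.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    out = bands.copy()
    out["corrected"] = out["integrated"] - out["background"]
    return out


def cleavage_ratio(bands: pd.DataFrame) -> float:
    """sAPPalpha (lysate + supernatant) over full-length APP (mature + immature).

    ``bands`` holds the measurements of one construct in one replicate,
    with columns ``band``, ``integrated``, ``background`` and, for sAPPalpha
    rows, a ``fraction`` column distinguishing lysate from supernatant (a
    single unlabelled sAPPalpha row is also accepted).  A non-positive
    full-length denominator makes the ratio undefined (``ValueError``).
    """
    df = corrected_table(bands)
    sapp = df.loc[df["band"] == "sAPPalpha", "corrected"].sum()
    app_m = df.loc[df["band"] == "APP_mature", "corrected"].sum()
    app_i = df.loc[df["band"] == "APP_immature", "corrected"].sum()
    if (df["band"] == "APP_mature").sum() == 0 or (df["band"] == "APP_immature").sum() == 0:
        raise ValueError("cleavage ratio needs both mature and immature full-length bands")
    denom = app_m + app_i
    if denom <= 0:
        raise ValueError(f"full-length APP intensity {denom} <= 0: ratio undefined")
    return float(sapp / denom)


def percent_of_wildtype(
    ratios: pd.DataFrame,
    wt_label: str = "APP",
    construct_col: str = "construct",
    ratio_col: str = "ratio",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Express per-replicate cleavage ratios as percent of the wild-type construct.

    Each replicate's ratio is divided by the wild-type ratio of the *same*
    replicate (paired within blots) and multiplied by 100; the summary is
    mean +/- SD across replicates.  Returns columns
    ``construct, n, mean_percent, sd_percent``.
    """
    df = ratios.copy()
    if wt_label not in set(df[construct_col]):
        raise ValueError(f"wild-type label {wt_label!r} not in ratio table")
    wt = df[df[construct_col] == wt_label].set_index(replicate_col)[ratio_col]
    if (wt <= 0).any():
        raise ValueError("wild-type ratio must be positive in every replicate")
    df["percent"] = df.apply(
        lambda row: row[ratio_col] / wt.loc[row[replicate_col]] * 100.0, axis=1
    )
    return (
        df.groupby(construct_col)["percent"]
        .agg(n="count", mean_percent="mean", sd_percent=lambda s: s.std(ddof=1))
        .reset_index()
    )
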