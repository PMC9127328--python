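"""End-to-end analysis recipes composing the per-module operations.

Each recipe mirrors one figure-level analysis: maxima density and
cross-channel association with the flipped null, the cross-linking
coaggregation assay (PCC and rSDM per condition, normalized to "fixed"),
two-channel intensity ratios on membrane sheets, FRAP fitting, and the
Western-blot cleavage ratio.  Recipes run on user-supplied inputs or on the
synthetic generator, are deterministic given their seed, and return a
report dictionary that records every threshold used; ``write_report`` dumps
it to JSON (+ CSV tables) for auditability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from sheetquant import coloc, densitometry, frap, spatial
from sheetquant.core_io import AnalysisConfig, Micrograph, Roi
from sheetquant.maxima import detect_maxima
from sheetquant.synthetic_data import (
    AggregationSpec,
    SheetSimSpec,
    simulate_crosslink,
    simulate_frap,
    simulate_sheet,
)

RECIPES = (
    "maxima_association",
    "crosslink_coaggregation",
    "intensity_ratio",
    "frap",
    "wb_cleavage",
)


def _config_record(cfg: AnalysisConfig) -> dict:
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}


def maxima_association_report(
    img_query: Micrograph,
    img_target: Micrograph,
    roi: Roi | None = None,
    cfg: AnalysisConfig | None = None,
    max_hist_nm: float = 300.0,
) -> dict:
    """Densities, shortest-distance histogram, flipped null and close fractions.

    The query channel is the secretase channel, the target channel APP;
    close association uses the configured cutoff (50 nm default).
    """
    cfg = cfg or AnalysisConfig()
    query_set = detect_maxima(img_query, roi, cfg)
    target_set = detect_maxima(img_target, roi, cfg)
    result = spatial.associate(query_set, target_set, img_target, roi, cfg, max_hist_nm)
    return {
        "recipe": "maxima_association",
        "config": _config_record(cfg),
        "query_density_per_um2": query_set.density_per_um2,
        "target_density_per_um2": target_set.density_per_um2,
        "n_query_maxima": len(query_set),
        "n_target_maxima": len(target_set),
        "close_fraction": result.close_fraction,
        "flipped_close_fraction": result.flipped_close_fraction,
        "excess_close_fraction": result.excess_close_fraction,
        "close_density_per_um2": result.close_density_per_um2,
        "histogram": {
            "bin_edges_nm": result.bin_edges_nm.tolist(),
            "observed": result.observed_counts.tolist(),
            "flipped": result.flipped_counts.tolist(),
        },
    }


def simulated_association_report(spec: SheetSimSpec, cfg: AnalysisConfig | None = None) -> dict:
    img_a, img_b, truth = simulate_sheet(spec)
    report = maxima_association_report(img_b, img_a, spec.interior_roi(), cfg)
    report["true_assoc_fraction"] = spec.assoc_fraction
    report["true_n_B"] = int(len(truth.positions_B_nm))
    return report


def crosslink_coaggregation_report(
    spec: SheetSimSpec,
    cfg: AnalysisConfig | None = None,
    n_sheets: int = 5,
) -> dict:
    """Simulated coaggregation assay: PCC and rSDM for fixed/control/CoP sheets.

    Per sheet, "fixed" and "control" are independent sheets without
    cross-linking; "CoP" is the cross-linked re-imaging of the control
    geometry.  PCC is normalized to the mean of the fixed condition (100%).
    """
    if spec.aggregation is None:
        raise ValueError("spec.aggregation required for the coaggregation recipe")
    cfg = cfg or AnalysisConfig()
    roi = spec.interior_roi()
    rows = []
    for i in range(n_sheets):
        fixed_spec = replace(spec, rng_seed=spec.rng_seed + 1000 + i, aggregation=None)
        ctrl_spec = replace(spec, rng_seed=spec.rng_seed + 2000 + i)
        fa, fb, _ = simulate_sheet(fixed_spec)
        ca, cb, ctrl_truth = simulate_sheet(replace(ctrl_spec, aggregation=None))
        xa, xb, _ = simulate_crosslink(ctrl_spec, ctrl_truth)
        for cond, a, b in (("fixed", fa, fb), ("control", ca, cb), ("CoP", xa, xb)):
            rows.append(
                {
                    "sheet": i,
                    "condition": cond,
                    "pcc": coloc.pearson(a, b, roi),
                    "rsdm_A": coloc.rsdm(a, roi),
                }
            )
    table = pd.DataFrame(rows)
    norm = coloc.normalize_to_reference(
        table.rename(columns={"pcc": "value"}),
        "fixed",
        experiment_col=None,
        condition_col="condition",
    )
    summary = {
        cond: {
            "pcc_mean": float(g["pcc"].mean()),
            "pcc_sd": float(g["pcc"].std(ddof=1)) if len(g) > 1 else 0.0,
            "rsdm_mean": float(g["rsdm_A"].mean()),
        }
        for cond, g in table.groupby("condition")
    }
    return {
        "recipe": "crosslink_coaggregation",
        "config": _config_record(cfg),
        "n_sheets": n_sheets,
        "co_drag_fraction": spec.aggregation.co_drag_fraction,
        "per_sheet": rows,
        "summary": summary,
        "pcc_percent_of_fixed": {
            r["condition"]: float(r["mean_percent"]) for _, r in norm.iterrows()
        },
    }


def intensity_ratio_report(
    img_num: Micrograph,
    img_den: Micrograph,
    membrane_roi: Roi,
    background_roi: Roi,
) -> dict:
    """Background-corrected intensity ratio of two channels over one sheet ROI."""
    num = coloc.corrected_mean(img_num, membrane_roi, background_roi)
    den = coloc.corrected_mean(img_den, membrane_roi, background_roi)
    ratio = num / den if den != 0 else float("nan")
    return {
        "recipe": "intensity_ratio",
        "numerator_mean_au": num,
        "denominator_mean_au": den,
        "ratio": ratio,
    }


def frap_report(traces: list[frap.FrapTrace]) -> dict:
    """QC, normalization, averaging and hyperbolic fitting of FRAP recordings."""
    processed = [frap.qc_exclude(frap.normalize_trace(t)) for t in traces]
    n_excluded = sum(t.excluded for t in processed)
    mean_trace = frap.average_traces(processed)
    fit = frap.fit_recovery(mean_trace)
    return {
        "recipe": "frap",
        "n_traces": len(traces),
        "n_excluded": n_excluded,
        "offset": fit.offset,
        "maximal_recovery": fit.maximal_recovery,
        "t_half_s": fit.t_half_s,
        "fit_r2": fit.fit_r2,
        "flag": fit.flag,
    }


def wb_cleavage_report(bands: pd.DataFrame, wt_label: str = "APP") -> dict:
    """Per-construct cleavage ratios and percent-of-wild-type summary.

    ``bands`` needs columns construct, replicate, band, integrated,
    background (and optionally fraction for sAPPalpha lysate/supernatant).
    """
    rows = []
    for (construct, replicate), grp in bands.groupby(["construct", "replicate"]):
        rows.append(
            {
                "construct": construct,
                "replicate": replicate,
                "ratio": densitometry.cleavage_ratio(grp),
            }
        )
    ratios = pd.DataFrame(rows)
    summary = densitometry.percent_of_wildtype(ratios, wt_label=wt_label)
    return {
        "recipe": "wb_cleavage",
        "ratios": rows,
        "percent_of_wildtype": summary.to_dict(orient="records"),
    }


def write_report(report: dict, out_path: str | Path) -> None:
    """Write a recipe report as JSON (sorted keys, so reruns are byte-identical)."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
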