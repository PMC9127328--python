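"""Synthetic membrane-sheet images, FRAP traces and blot tables with ground truth.

The sheet simulator emulates the statistical structure the analysis assumes:

* channel A carries protein *clusters*: cluster centers follow a homogeneous
  Poisson process at the requested density; each cluster holds 20-30
  molecules (uniform in the configured range) scattered around the center
  with a Gaussian SD of one quarter of the cluster diameter, so ~95% of
  molecules fall within the stated diameter (65-85 nm spots for APP),
* channel B carries point-like maxima at its own density; a configurable
  fraction is planted within a small radius of a random A center (true
  association), the remainder is uniform,
* both channels are convolved with an isotropic Gaussian PSF (FWHM
  configurable in the 60-90 nm resolution range), a constant background is
  added, and Poisson or Gaussian detector noise is applied,
* emitters keep a margin of two PSF FWHM from the field edges, mimicking
  analysis of interior membrane regions; densities refer to the interior
  region, exposed as :meth:`SheetSimSpec.interior_roi`.

An antibody cross-linking step reassigns the A molecules to a small number
of aggregate sites (fewer, brighter maxima, higher rSDM) and optionally
drags a fraction of B points into those aggregates (raising the PCC), which
reproduces the qualitative coaggregation contrast between an interacting
and a non-interacting secretase.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from sheetquant.core_io import Micrograph, Roi
from sheetquant.frap import FrapTrace

SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AggregationSpec:
    """Antibody cross-linking parameters: aggregate count and B co-drag fraction."""

    n_aggregates: int
    co_drag_fraction: float

    def __post_init__(self) -> None:
        if self.n_aggregates < 1:
            raise ValueError("n_aggregates must be >= 1")
        if not 0.0 <= self.co_drag_fraction <= 1.0:
            raise ValueError("co_drag_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SheetSimSpec:
    """Parameters of a two-channel membrane-sheet simulation.

    Densities are per square micrometre of the interior region (the field
    minus an edge margin of two PSF FWHM).  ``molecule_peak_au`` is the PSF
    peak amplitude contributed by a single channel-A molecule;
    ``point_peak_au_B`` the peak amplitude of one channel-B punctum (secretase
    maxima are brighter than single-fluorophore signals).
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 25.0
    psf_fwhm_nm: float = 75.0
    clusters_per_um2_A: float = 3.0
    cluster_diameter_nm_A: float = 75.0
    molecules_per_cluster_A: tuple[int, int] = (20, 30)
    maxima_per_um2_B: float = 3.0
    assoc_fraction: float = 0.0
    assoc_radius_nm: float = 20.0
    background_au: float = 0.5
    noise_model: str | tuple[str, float] = "poisson"
    molecule_peak_au: float = 2.0
    point_peak_au_B: float = 30.0
    aggregation: AggregationSpec | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.clusters_per_um2_A < 0 or self.maxima_per_um2_B < 0:
            raise ValueError("densities must be non-negative")
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValueError("assoc_fraction must be in [0, 1]")
        if self.psf_fwhm_nm < self.pixel_size_nm:
            raise ValueError("psf_fwhm_nm must be >= pixel_size_nm (sampled PSF)")
        if self.assoc_radius_nm < 0:
            raise ValueError("assoc_radius_nm must be >= 0")
        lo, hi = self.molecules_per_cluster_A
        if lo < 1 or hi < lo:
            raise ValueError("molecules_per_cluster_A must be a valid integer range")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm * SIGMA_PER_FWHM / self.pixel_size_nm

    @property
    def margin_px(self) -> int:
        return int(np.ceil(2.0 * self.psf_fwhm_nm / self.pixel_size_nm))

    def interior_roi(self, role: str = "membrane") -> Roi:
        """ROI covering the region where emitters are placed."""
        m = self.margin_px
        h = self.image_size_px[0] - 2 * m
        w = self.image_size_px[1] - 2 * m
        if h < 1 or w < 1:
            raise ValueError("field too small for the edge margin")
        return Roi(rect=(m, m, h, w), role=role, name="interior")

    @property
    def interior_area_um2(self) -> float:
        roi = self.interior_roi()
        return roi.rect[2] * roi.rect[3] * (self.pixel_size_nm / 1000.0) ** 2


@dataclass(frozen=True)
class GroundTruth:
    """True emitter geometry behind a simulated image pair."""

    positions_A_nm: np.ndarray  # (n, 2) cluster centers
    positions_B_nm: np.ndarray  # (m, 2) point positions
    assoc_flags_B: np.ndarray  # bool per B point: planted near an A center
    molecules_per_cluster: np.ndarray  # int per A cluster
    molecule_positions_A_nm: np.ndarray  # (total molecules, 2)
    aggregate_sites_nm: np.ndarray | None = None  # set by the cross-linking step


def _render(
    shape: tuple[int, int],
    positions_px: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Sum of Gaussian PSFs at subpixel positions, rendered on small windows."""
    img = np.zeros(shape, dtype=float)
    if len(positions_px) == 0:
        return img
    half = int(np.ceil(4.0 * sigma_px))
    win = np.arange(-half, half + 1, dtype=float)
    for (r, c), amp in zip(positions_px, amplitudes):
        r0, c0 = int(round(r)), int(round(c))
        rows = win + r0
        cols = win + c0
        rmask = (rows >= 0) & (rows < shape[0])
        cmask = (cols >= 0) & (cols < shape[1])
        if not rmask.any() or not cmask.any():
            continue
        gr = np.exp(-((rows[rmask] - r) ** 2) / (2.0 * sigma_px**2))
        gc = np.exp(-((cols[cmask] - c) ** 2) / (2.0 * sigma_px**2))
        img[np.ix_(rows[rmask].astype(int), cols[cmask].astype(int))] += amp * np.outer(gr, gc)
    return img


def _apply_noise(field: np.ndarray, spec: SheetSimSpec, rng: np.random.Generator) -> np.ndarray:
    noisy_model = spec.noise_model
    if noisy_model == "poisson":
        return rng.poisson(np.clip(field, 0, None)).astype(float)
    if isinstance(noisy_model, tuple) and noisy_model[0] == "gaussian":
        return np.clip(field + rng.normal(0.0, noisy_model[1], field.shape), 0, None)
    if noisy_model in (None, "none"):
        return field
    raise ValueError(f"unknown noise model {noisy_model!r}")


def _uniform_in_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in a disc of given radius (area-uniform)."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.sin(theta), r * np.cos(theta)])


def _sample_geometry(spec: SheetSimSpec, rng: np.random.Generator) -> GroundTruth:
    px = spec.pixel_size_nm
    m = spec.margin_px * px
    lo_r, lo_c = m, m
    hi_r = spec.image_size_px[0] * px - m
    hi_c = spec.image_size_px[1] * px - m
    area_um2 = spec.interior_area_um2

    n_clusters = rng.poisson(spec.clusters_per_um2_A * area_um2)
    centers = np.column_stack(
        [rng.uniform(lo_r, hi_r, n_clusters), rng.uniform(lo_c, hi_c, n_clusters)]
    )
    mol_lo, mol_hi = spec.molecules_per_cluster_A
    n_mols = rng.integers(mol_lo, mol_hi + 1, size=n_clusters)
    mol_sd = spec.cluster_diameter_nm_A / 4.0
    mol_positions = (
        np.repeat(centers, n_mols, axis=0)
        + rng.normal(0.0, mol_sd, size=(int(n_mols.sum()), 2))
        if n_clusters
        else np.empty((0, 2))
    )

    n_b = rng.poisson(spec.maxima_per_um2_B * area_um2)
    flags = np.zeros(n_b, dtype=bool)
    b_positions = np.column_stack(
        [rng.uniform(lo_r, hi_r, n_b), rng.uniform(lo_c, hi_c, n_b)]
    )
    if n_clusters > 0 and spec.assoc_fraction > 0 and n_b > 0:
        n_assoc = int(round(spec.assoc_fraction * n_b))
        idx = rng.choice(n_b, size=n_assoc, replace=False)
        # distinct host clusters where possible: planted points are meant to be
        # distinct associated maxima, and two points on one cluster are not
        # resolvable as two maxima
        host = rng.choice(n_clusters, size=n_assoc, replace=n_assoc > n_clusters)
        b_positions[idx] = centers[host] + _uniform_in_disc(
            rng, n_assoc, spec.assoc_radius_nm
        )
        flags[idx] = True
        # keep planted points inside the interior region
        b_positions[idx, 0] = np.clip(b_positions[idx, 0], lo_r, hi_r)
        b_positions[idx, 1] = np.clip(b_positions[idx, 1], lo_c, hi_c)

    return GroundTruth(
        positions_A_nm=centers,
        positions_B_nm=b_positions,
        assoc_flags_B=flags,
        molecules_per_cluster=n_mols,
        molecule_positions_A_nm=mol_positions,
    )


def _render_pair(
    spec: SheetSimSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    condition: str,
) -> tuple[Micrograph, Micrograph]:
    px = spec.pixel_size_nm
    sigma = spec.psf_sigma_px
    field_a = _render(
        spec.image_size_px,
        truth.molecule_positions_A_nm / px,
        np.full(len(truth.molecule_positions_A_nm), spec.molecule_peak_au),
        sigma,
    )
    amp_b = spec.point_peak_au_B * rng.uniform(0.7, 1.3, size=len(truth.positions_B_nm))
    field_b = _render(spec.image_size_px, truth.positions_B_nm / px, amp_b, sigma)
    img_a = _apply_noise(field_a + spec.background_au, spec, rng)
    img_b = _apply_noise(field_b + spec.background_au, spec, rng)
    mk = lambda pix, ch: Micrograph(pix, pixel_size_nm=px, channel=ch, condition=condition)
    return mk(img_a, "A"), mk(img_b, "B")


def simulate_sheet(spec: SheetSimSpec) -> tuple[Micrograph, Micrograph, GroundTruth]:
    """Simulate one two-channel membrane sheet with known emitter geometry."""
    psf_area_um2 = np.pi * (spec.psf_fwhm_nm / 2.0 / 1000.0) ** 2
    for dens in (spec.clusters_per_um2_A, spec.maxima_per_um2_B):
        if dens * psf_area_um2 > 1.0:
            warnings.warn(
                f"density {dens}/um2 exceeds one maximum per PSF area: "
                "field is unresolvable",
                stacklevel=2,
            )
    rng = np.random.default_rng(spec.rng_seed)
    truth = _sample_geometry(spec, rng)
    img_a, img_b = _render_pair(spec, truth, rng, condition="control")
    return img_a, img_b, truth


def simulate_crosslink(
    spec: SheetSimSpec, base_truth: GroundTruth
) -> tuple[Micrograph, Micrograph, GroundTruth]:
    """Re-image a sheet after antibody cross-linking of channel A.

    All A molecules are reassigned to ``n_aggregates`` sites drawn from the
    original cluster centers (fewer, brighter maxima); ``co_drag_fraction``
    of the B points moves to the nearest aggregate site, scattered within a
    quarter cluster diameter. ``co_drag_fraction = 0`` models a secretase
    that does not coaggregate, positive values one that is dragged along.
    """
    agg = spec.aggregation
    if agg is None:
        raise ValueError("spec.aggregation must be set for simulate_crosslink")
    n_clusters = len(base_truth.positions_A_nm)
    if agg.n_aggregates >= n_clusters:
        raise ValueError(
            f"n_aggregates ({agg.n_aggregates}) must be smaller than the "
            f"number of A clusters ({n_clusters})"
        )
    rng = np.random.default_rng(np.random.default_rng(spec.rng_seed).integers(2**31) + 1)
    site_idx = rng.choice(n_clusters, size=agg.n_aggregates, replace=False)
    sites = base_truth.positions_A_nm[site_idx]

    n_total_mols = len(base_truth.molecule_positions_A_nm)
    mol_sd = spec.cluster_diameter_nm_A / 4.0
    host = rng.integers(0, agg.n_aggregates, size=n_total_mols)
    mols = sites[host] + rng.normal(0.0, mol_sd, size=(n_total_mols, 2))

    b_positions = base_truth.positions_B_nm.copy()
    flags = base_truth.assoc_flags_B.copy()
    n_b = len(b_positions)
    if n_b and agg.co_drag_fraction > 0:
        n_drag = int(round(agg.co_drag_fraction * n_b))
        drag_idx = rng.choice(n_b, size=n_drag, replace=False)
        if len(sites) == 1:
            nearest = np.zeros(n_drag, dtype=int)
        else:
            from scipy.spatial import cKDTree

            _, nearest = cKDTree(sites).query(b_positions[drag_idx])
        b_positions[drag_idx] = sites[nearest] + _uniform_in_disc(
            rng, n_drag, spec.cluster_diameter_nm_A / 4.0
        )
        flags[drag_idx] = True

    counts = np.bincount(host, minlength=agg.n_aggregates)
    truth = GroundTruth(
        positions_A_nm=sites,
        positions_B_nm=b_positions,
        assoc_flags_B=flags,
        molecules_per_cluster=counts,
        molecule_positions_A_nm=mols,
        aggregate_sites_nm=sites,
    )
    img_a, img_b = _render_pair(spec, truth, rng, condition="CoP")
    return img_a, img_b, truth


def simulate_frap(
    t_half_s: float,
    offset: float = 0.2,
    recovery: float = 0.6,
    n_frames: int = 117,
    rate_hz: float = 1.77,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_prebleach: int = 3,
    signal_au: float = 100.0,
    background_au: float = 10.0,
) -> FrapTrace:
    """Sample a FRAP recording from the hyperbolic recovery model.

    The normalized recovery follows ``y(t) = offset + recovery * t /
    (t + t_half)`` with the first postbleach frame at ``t = 1/rate_hz``;
    prebleach frames sit at the normalized level 1.  Gaussian noise of the
    given SD (on the normalized scale) is applied to the bleach-ROI signal.
    """
    if t_half_s <= 0:
        raise ValueError(f"t_half_s must be positive, got {t_half_s}")
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(1, n_frames + 1) / rate_hz
    y = offset + recovery * times / (times + t_half_s)
    y_noisy = y + rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else y
    pre = np.ones(n_prebleach)
    norm_all = np.concatenate([pre, y_noisy])
    bleach = norm_all * signal_au + background_au
    background = np.full(n_prebleach + n_frames, background_au)
    reference = np.full(n_prebleach + n_frames, signal_au)
    return FrapTrace(
        times_s=times,
        bleach=bleach,
        background=background,
        reference=reference,
        n_prebleach=n_prebleach,
    )


def simulate_lanes(
    true_bands: pd.DataFrame,
    background_au: float = 50.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate densitometric measurements from true band intensities.

    ``true_bands`` has columns ``lane``, ``band`` (and optionally
    ``fraction``) plus ``true_au``.  The measured integrated intensity is
    the true intensity (with multiplicative Gaussian noise of relative SD
    ``noise_sd``) plus the local background; the background measurement
    carries the same relative noise.  With zero noise,
    ``integrated - background`` recovers the truth exactly.
    """
    required = {"lane", "band", "true_au"}
    if not required.issubset(true_bands.columns):
        raise ValueError(f"true_bands needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    df = true_bands.copy()
    n = len(df)
    band_noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    bg_noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    bg_true = np.full(n, background_au, dtype=float)
    df["background"] = bg_true * (1.0 + bg_noise)
    df["integrated"] = df["true_au"].to_numpy() * (1.0 + band_noise) + df["background"]
    return df.drop(columns=["true_au"])
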