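"""Cross-channel shortest-distance association with a flipped-image null.

For every query maximum (by convention a secretase maximum) the Euclidean
distance to its nearest target maximum (an APP maximum) is computed from the
subpixel positions, in nanometres.  The randomized reference distribution is
obtained by flipping the target image vertically and horizontally (a
180-degree rotation) and re-detecting maxima, which preserves the count and
intensity statistics of the channel while destroying any true spatial
relation to the query channel.

Query maxima whose nearest target lies within a cutoff (50 nm by default)
count as "closely associated"; the close fraction multiplied by the query
maxima density gives the density of potentially interacting maxima per
square micrometre.  No edge correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from sheetquant.core_io import AnalysisConfig, Micrograph, Roi, require_same_grid
from sheetquant.maxima import MaximaSet, detect_maxima


@dataclass(frozen=True)
class DistanceResult:
    """Shortest cross-channel distances and their summary statistics."""

    distances_nm: np.ndarray
    flipped_distances_nm: np.ndarray | None
    bin_edges_nm: np.ndarray | None
    observed_counts: np.ndarray | None
    flipped_counts: np.ndarray | None
    close_cutoff_nm: float
    close_fraction: float
    close_density_per_um2: float
    flipped_close_fraction: float | None = None

    @property
    def excess_close_fraction(self) -> float | None:
        """Observed minus flipped close fraction: the association above chance."""
        if self.flipped_close_fraction is None:
            return None
        return self.close_fraction - self.flipped_close_fraction


def shortest_cross_distances(query: MaximaSet, target: MaximaSet) -> np.ndarray:
    """One shortest distance (nm) from each query maximum to the target set.

    Distances are computed from subpixel positions with the Pythagorean
    theorem (Euclidean metric); border-excluded maxima carry no subpixel
    position and are skipped.
    """
    if not np.isclose(query.pixel_size_nm, target.pixel_size_nm):
        raise ValueError(
            "query and target maxima come from different pixel grids: "
            f"{query.pixel_size_nm} vs {target.pixel_size_nm} nm/px"
        )
    q = query.positions_nm()
    t = target.positions_nm()
    if len(q) == 0:
        raise ValueError("query maxima set is empty")
    if len(t) == 0:
        raise ValueError("target maxima set is empty: no shortest distance defined")
    tree = cKDTree(t)
    d, _ = tree.query(q, k=1)
    return np.asarray(d, dtype=float)


def self_shortest_distances(points_nm: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance within one set, excluding each point itself."""
    pts = np.asarray(points_nm, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points for self-distances")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def flipped_null(
    target_img: Micrograph,
    roi: Roi | None = None,
    cfg: AnalysisConfig | None = None,
) -> MaximaSet:
    """Maxima of the target image flipped vertically and horizontally.

    The flip is a 180-degree rotation of the pixel grid, so the detected
    maxima count equals that of the original image exactly; only the spatial
    relation to the other channel is randomized.  The ROI is rotated with
    the image so the same membrane region is analyzed.
    """
    flipped = target_img.flipped()
    if roi is not None:
        nrow, ncol = target_img.shape
        if roi.rect is not None:
            r0, c0, h, w = roi.rect
            roi = Roi(rect=(nrow - r0 - h, ncol - c0 - w, h, w), role=roi.role, name=roi.name)
        else:
            roi = Roi(
                vertices=tuple((nrow - 1 - r, ncol - 1 - c) for r, c in roi.vertices),
                role=roi.role,
                name=roi.name,
            )
    return detect_maxima(flipped, roi, cfg)


def distance_histogram(
    distances_nm: np.ndarray,
    flipped_distances_nm: np.ndarray | None = None,
    bin_nm: float = 25.0,
    max_nm: float = 300.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Equal-width histogram of shortest distances on ``[0, max_nm)``.

    Returns ``(bin_edges, observed_counts, flipped_counts)``.  The last bin
    collects the overflow ``>= max_nm`` so that counts are conserved; the
    truncation affects display only, never the close-fraction statistics.
    """
    if bin_nm <= 0 or max_nm <= 0:
        raise ValueError("bin_nm and max_nm must be positive")
    edges = np.arange(0.0, max_nm + bin_nm / 2, bin_nm)
    if edges[-1] < max_nm:
        edges = np.append(edges, max_nm)

    def _counts(d: np.ndarray) -> np.ndarray:
        inside, _ = np.histogram(d, bins=edges)
        overflow = int(np.sum(np.asarray(d) >= edges[-1]))
        return np.append(inside, overflow)

    obs = _counts(np.asarray(distances_nm))
    flip = None if flipped_distances_nm is None else _counts(np.asarray(flipped_distances_nm))
    return edges, obs, flip


def close_association(
    distances_nm: np.ndarray,
    cutoff_nm: float = 50.0,
    query_density_per_um2: float | None = None,
) -> tuple[float, float | None]:
    """Fraction of query maxima within ``cutoff_nm`` of a target maximum.

    When the query maxima density is given, the close fraction is also
    expressed as a density of closely associated maxima per square
    micrometre (fraction times density).
    """
    d = np.asarray(distances_nm, dtype=float)
    if len(d) == 0:
        raise ValueError("no distances given")
    frac = float(np.mean(d <= cutoff_nm))
    dens = None if query_density_per_um2 is None else frac * query_density_per_um2
    return frac, dens


def associate(
    query: MaximaSet,
    target: MaximaSet,
    target_img: Micrograph,
    target_roi: Roi | None = None,
    cfg: AnalysisConfig | None = None,
    max_nm: float = 300.0,
) -> DistanceResult:
    """Full association analysis: distances, flipped null, histogram, close fraction."""
    cfg = cfg or AnalysisConfig()
    d = shortest_cross_distances(query, target)
    null_set = flipped_null(target_img, target_roi, cfg)
    d_null = shortest_cross_distances(query, null_set)
    edges, obs, flip = distance_histogram(d, d_null, cfg.histogram_bin_nm, max_nm)
    frac, dens = close_association(d, cfg.close_cutoff_nm, query.density_per_um2)
    null_frac, _ = close_association(d_null, cfg.close_cutoff_nm)
    return DistanceResult(
        distances_nm=d,
        flipped_distances_nm=d_null,
        bin_edges_nm=edges,
        observed_counts=obs,
        flipped_counts=flip,
        close_cutoff_nm=cfg.close_cutoff_nm,
        close_fraction=frac,
        close_density_per_um2=dens if dens is not None else float("nan"),
        flipped_close_fraction=null_frac,
    )


def poisson_close_fraction(density_per_um2: float, cutoff_nm: float) -> float:
    """Closed-form chance close fraction for a homogeneous Poisson target field.

    The nearest-neighbour distance CDF of a 2D Poisson process with
    intensity ``lambda`` is ``1 - exp(-lambda * pi * r^2)``; this is the
    expected close fraction for spatially unrelated channels.
    """
    lam_per_nm2 = density_per_um2 / 1e6
    return 1.0 - float(np.exp(-lam_per_nm2 * np.pi * cutoff_nm**2))
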