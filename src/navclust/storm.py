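"""Super-resolution localization-microscopy analysis.

Processing chain for single-molecule blinking data: per-frame spot detection
and 2D Gaussian localization (with multi-emitter rejection), drift
correction by cross-correlation of temporally binned reconstructions,
density-reachability cluster detection with per-cluster radius and
occupancy, nearest-neighbor distance distributions via a k-d tree, and the
two-sample Kolmogorov-Smirnov comparison between conditions.

Coordinates are in nm, origin top-left, y increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation
from sklearn.cluster import DBSCAN

__all__ = [
    "ClusterSet",
    "NNResult",
    "localize_frames",
    "drift_correct",
    "detect_clusters",
    "nearest_neighbor_distances",
    "ks_two_sample",
    "summarize_rois",
    "restrict_to_roi",
]

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "intensity", "precision_nm"]


@dataclass
class ClusterSet:
    """Cluster assignments plus per-cluster and summary statistics.

    ``assignments`` holds one cluster id per localization (-1 = background);
    ``clusters`` has one row per cluster (centroid, RMS radius, n_members);
    ``percent_clustered`` is the percentage of localizations assigned to any
    cluster; ``cluster_density_per_um2`` is clusters per um^2 of ROI area.
    """

    assignments: np.ndarray
    clusters: pd.DataFrame
    percent_clustered: float
    cluster_density_per_um2: float


@dataclass
class NNResult:
    """Per-localization first-nearest-neighbor distances and their density."""

    distances: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray

    @property
    def modes_nm(self) -> np.ndarray:
        """Bin centers of local maxima of the histogram density."""
        c = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        d = self.density
        peaks = [i for i in range(1, len(d) - 1) if d[i] >= d[i - 1] and d[i] > d[i + 1]]
        return c[peaks]


# --------------------------------------------------------------------------
# localization
# --------------------------------------------------------------------------

def _fit_gaussian_2d(window: np.ndarray) -> tuple[float, float, float, float]:
    """Fit A*exp(-((x-x0)^2+(y-y0)^2)/2s^2)+b to a square window.

    Returns (x0, y0, amplitude, sigma) in window pixel coordinates; raises
    RuntimeError if the optimizer fails.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    b0 = float(window.min())
    a0 = float(window.max() - b0)
    total = max(float((window - b0).sum()), 1e-12)
    x0 = float(((window - b0) * xx).sum() / total)
    y0 = float(((window - b0) * yy).sum() / total)

    def resid(p):
        a, x, y, s, b = p
        return (a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s**2)) + b
                - window).ravel()

    res = optimize.least_squares(
        resid, [a0, x0, y0, 1.3, b0],
        bounds=([0, -2, -2, 0.3, -np.inf], [np.inf, w + 2, h + 2, w, np.inf]))
    if not res.success:
        raise RuntimeError("Gaussian fit failed")
    a, x, y, s, _ = res.x
    return float(x), float(y), float(a), float(s)


def localize_frames(
    movie: np.ndarray,
    peak_mask: int = 9,
    snr_min: float = 6.0,
    pixel_size_nm: float = 100.0,
) -> pd.DataFrame:
    """Localize single emitters in every frame of a blinking movie.

    Per frame, the background is the median and the noise the MAD-based
    robust SD; candidate peaks are local maxima inside a peak_mask-sized
    window whose amplitude above background is >= snr_min * noise SD.  Any
    window containing more than one candidate is discarded (multi-emitter
    rejection); surviving candidates are fitted with a 2D Gaussian for
    sub-pixel position.  Returns a localization table in nm.
    """
    if peak_mask % 2 == 0:
        raise ValueError(f"peak_mask must be odd, got {peak_mask}")
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.size == 0:
        raise ValueError("movie must be a non-empty (frames, H, W) array")
    half = peak_mask // 2
    rows = []
    for f in range(movie.shape[0]):
        frame = movie[f].astype(float)
        bg = float(np.median(frame))
        noise = 1.4826 * float(np.median(np.abs(frame - bg)))
        if noise == 0:
            continue  # zero-variance frame: nothing to detect
        # candidate peaks are 3x3 local maxima above threshold; the coarser
        # peak_mask window is used for exclusivity and for the fit cut-out,
        # so two emitters sharing one window are both rejected
        is_max = frame == ndimage.maximum_filter(frame, size=3, mode="nearest")
        cand = is_max & (frame - bg >= snr_min * noise)
        ys, xs = np.nonzero(cand)
        # drop candidates too close to the border for a full fit window
        keep = (ys >= half) & (ys < frame.shape[0] - half) & \
               (xs >= half) & (xs < frame.shape[1] - half)
        ys, xs = ys[keep], xs[keep]
        for y, x in zip(ys, xs):
            others = (np.abs(ys - y) <= half) & (np.abs(xs - x) <= half)
            if others.sum() > 1:
                continue  # multiple emitters in one window: discard
            window = frame[y - half:y + half + 1, x - half:x + half + 1]
            try:
                wx, wy, amp, sigma = _fit_gaussian_2d(window)
            except RuntimeError:
                continue
            photons = max(2 * math.pi * amp * sigma**2, 1.0)
            rows.append({
                "frame": f,
                "x_nm": (x - half + wx) * pixel_size_nm,
                "y_nm": (y - half + wy) * pixel_size_nm,
                "intensity": photons,
                "precision_nm": sigma * pixel_size_nm / math.sqrt(photons),
            })
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


def drift_correct(
    table: pd.DataFrame,
    n_bins: int = 5,
    hist_bin_nm: float = 20.0,
    min_per_bin: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct sample drift by cross-correlating temporal reconstructions.

    The table is split into ``n_bins`` temporal bins; each bin's 2D
    localization histogram is registered against the first bin's by
    sub-pixel cross correlation; per-bin shifts are interpolated linearly to
    per-frame drift and subtracted.  Returns the corrected table and the
    per-bin drift trace (frame_center, dx_nm, dy_nm).
    """
    if n_bins < 2:
        raise ValueError(f"need n_bins >= 2 for drift estimation, got {n_bins}")
    frames = table["frame"].to_numpy()
    edges = np.linspace(frames.min(), frames.max() + 1, n_bins + 1)
    which = np.clip(np.searchsorted(edges, frames, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    if counts.min() < min_per_bin:
        raise ValueError(
            f"only {counts.min()} localizations in the sparsest temporal bin "
            f"(need >= {min_per_bin}); try fewer bins")

    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    xe = np.arange(x.min(), x.max() + 2 * hist_bin_nm, hist_bin_nm)
    ye = np.arange(y.min(), y.max() + 2 * hist_bin_nm, hist_bin_nm)

    def hist(sel):
        h, _, _ = np.histogram2d(y[sel], x[sel], bins=(ye, xe))
        return h

    ref = hist(which == 0)
    centers, shifts = [], []
    for b in range(n_bins):
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        if b == 0:
            shifts.append((0.0, 0.0))
            continue
        shift, _, _ = phase_cross_correlation(ref, hist(which == b),
                                              upsample_factor=20, normalization=None)
        # shift = displacement of the moving image relative to the reference
        shifts.append((-shift[1] * hist_bin_nm, -shift[0] * hist_bin_nm))
    drift = pd.DataFrame(shifts, columns=["dx_nm", "dy_nm"])
    drift.insert(0, "frame_center", centers)

    dx = np.interp(frames, drift["frame_center"], drift["dx_nm"])
    dy = np.interp(frames, drift["frame_center"], drift["dy_nm"])
    out = table.copy()
    out["x_nm"] = x - dx
    out["y_nm"] = y - dy
    return out, drift


# --------------------------------------------------------------------------
# clustering and nearest neighbors
# --------------------------------------------------------------------------

def detect_clusters(
    table: pd.DataFrame,
    eps: float = 20.0,
    min_pts: int = 3,
    roi_area_um2: float | None = None,
) -> ClusterSet:
    """Density-reachability clustering of a localization table.

    Points with >= ``min_pts`` neighbors within ``eps`` nm seed clusters
    (DBSCAN); per cluster the centroid, RMS member-to-centroid radius and
    member count are reported.  ``roi_area_um2`` sets the area used for the
    cluster-density summary (defaults to the bounding box of the data).
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if min_pts < 2:
        raise ValueError(f"min_pts must be >= 2, got {min_pts}")
    if len(table) == 0:
        return ClusterSet(np.zeros(0, dtype=int),
                          pd.DataFrame(columns=["cluster", "cx_nm", "cy_nm",
                                                "radius_nm", "n_members"]),
                          0.0, 0.0)
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xy)
    rows = []
    for cid in np.unique(labels[labels >= 0]):
        pts = xy[labels == cid]
        c = pts.mean(axis=0)
        radius = math.sqrt(float(((pts - c) ** 2).sum(axis=1).mean()))
        rows.append({"cluster": int(cid), "cx_nm": c[0], "cy_nm": c[1],
                     "radius_nm": radius, "n_members": len(pts)})
    clusters = pd.DataFrame(rows, columns=["cluster", "cx_nm", "cy_nm",
                                           "radius_nm", "n_members"])
    pct = 100.0 * float((labels >= 0).sum()) / len(labels)
    if roi_area_um2 is None:
        spans = xy.max(axis=0) - xy.min(axis=0)
        roi_area_um2 = max(float(spans[0] * spans[1]) / 1e6, 1e-12)
    density = len(clusters) / roi_area_um2
    return ClusterSet(labels, clusters, pct, density)


def nearest_neighbor_distances(table: pd.DataFrame, bin_width: float = 2.0) -> NNResult:
    """First-nearest-neighbor Euclidean distance per localization (k-d tree).

    The histogram density is normalized to unit area.
    """
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if len(xy) < 2:
        raise ValueError(f"need >= 2 localizations for nearest neighbors, got {len(xy)}")
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=2)
    d = dist[:, 1]
    hi = max(float(d.max()), bin_width)
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    return NNResult(distances=d, bin_edges=edges, density=density)


def restrict_to_roi(table: pd.DataFrame, roi: dict) -> pd.DataFrame:
    """Rows inside a rectangular ROI {x, y, width, height} in nm (half-open)."""
    x0, y0 = roi["x"], roi["y"]
    sel = ((table["x_nm"] >= x0) & (table["x_nm"] < x0 + roi["width"]) &
           (table["y_nm"] >= y0) & (table["y_nm"] < y0 + roi["height"]))
    return table[sel].reset_index(drop=True)


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov
# --------------------------------------------------------------------------

def ks_two_sample(
    a, b, n_permutations: int = 0, seed: int = 0
) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| over the merged sample.

    The p value is asymptotic, from the Kolmogorov distribution at
    sqrt(n_eff)*D with n_eff = n_a*n_b/(n_a+n_b) (with the Stephens
    finite-sample correction).  With ``n_permutations`` > 0 a permutation
    p value is returned instead.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(a, b)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 1
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            dp = _ks_statistic(np.sort(pooled[:a.size]), np.sort(pooled[a.size:]))
            if dp >= d:
                count += 1
        return d, count / (n_permutations + 1)
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))
    return d, min(max(p, 0.0), 1.0)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup-norm ECDF difference for two sorted samples."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


# --------------------------------------------------------------------------
# condition summaries
# --------------------------------------------------------------------------

def summarize_rois(cluster_sets: list[ClusterSet], nn_results: list[NNResult]) -> dict:
    """Pool per-ROI cluster and nearest-neighbor results into one condition.

    Radii and NN distances are concatenated across ROIs; blink counts and
    the percent-clustered summary are pooled with per-ROI weights equal to
    localization counts.
    """
    if not cluster_sets:
        raise ValueError("need at least one ROI")
    radii = np.concatenate([cs.clusters["radius_nm"].to_numpy() for cs in cluster_sets]) \
        if any(len(cs.clusters) for cs in cluster_sets) else np.zeros(0)
    nn = np.concatenate([r.distances for r in nn_results]) if nn_results else np.zeros(0)
    n_locs = np.array([len(cs.assignments) for cs in cluster_sets])
    n_clustered = np.array([(cs.assignments >= 0).sum() for cs in cluster_sets])
    return {
        "n_rois": len(cluster_sets),
        "n_localizations": int(n_locs.sum()),
        "n_clusters": int(sum(len(cs.clusters) for cs in cluster_sets)),
        "percent_clustered": 100.0 * float(n_clustered.sum()) / max(int(n_locs.sum()), 1),
        "radii_nm": radii,
        "nn_distances_nm": nn,
    }
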