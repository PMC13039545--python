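"""Nanoparticle-cluster quantification in confocal Z-stacks.

Segments fluorescent nanoparticle clusters by moment-preserving
auto-thresholding and connected-component labeling, then measures the
distribution metrics used to characterize a subretinal injection: major
cluster diameters binned at 250 nm, nearest-neighbor distances between
cluster centroids, the retinal area covered by the particle cloud
(boundary of a Z-max projection), the fraction of clusters internalized by
a labeled compartment (e.g. the RPE), Manders split colocalization
coefficients, and integrated fluorescence density over ROIs.

Conventions: voxel arrays are indexed (z, y, x); spacing is given per axis
in µm/voxel in the same (z, y, x) order; the physical coordinate of voxel
index i along an axis is (i + 0.5) * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union


class DegenerateHistogramError(ValueError):
    """All intensity mass sits in a single bin; no bilevel split exists."""


class InsufficientPointsError(ValueError):
    """Fewer points than the statistic requires."""


class EmptyClusterSetError(ValueError):
    """An operation on clusters received an empty set."""


@dataclass
class ImageStack:
    """A (possibly multi-channel) voxel grid with physical spacing.

    Parameters
    ----------
    channels : dict of str -> ndarray
        One (z, y, x) intensity array per channel name. A 2D image is
        treated as a single-slice stack.
    spacing : tuple of float
        Voxel pitch in µm as (z, y, x).
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.spacing = spacing
        fixed = {}
        shape = None
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                arr = arr[None]
            if arr.ndim != 3 or arr.size == 0:
                raise ValueError(f"channel {name!r} must be a non-empty 2D/3D array")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all channels must share one shape")
            fixed[name] = arr
        self.channels = fixed

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class ClusterSet:
    """Segmented clusters plus the provenance of the segmentation.

    ``table`` has one row per cluster: id, centroid_z/y/x_um, n_voxels and,
    once measured, major_diameter_um and compartment. ``voxels`` maps the
    cluster id to an (n, 3) integer array of (z, y, x) member indices.
    """

    table: pd.DataFrame
    voxels: dict[int, np.ndarray]
    spacing: tuple[float, float, float]
    threshold: float | None = None
    connectivity: int | None = None
    channel: str | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids_um(self) -> np.ndarray:
        return self.table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()


@dataclass
class DiameterHistogram:
    """Frequency distribution of cluster major diameters in fixed-width bins."""

    bin_edges_um: np.ndarray
    frequency: np.ndarray
    n_total: int

    def fraction_below(self, cutoff_um: float) -> float:
        """Fraction of the tallied diameters strictly below ``cutoff_um``."""
        if self.n_total == 0:
            return float("nan")
        edges = self.bin_edges_um
        full = edges[1:] <= cutoff_um
        frac = float(self.frequency[full].sum())
        # partial bin containing the cutoff
        part = (edges[:-1] < cutoff_um) & (edges[1:] > cutoff_um)
        if part.any():
            i = int(np.flatnonzero(part)[0])
            frac += float(self.frequency[i]) * (cutoff_um - edges[i]) / (edges[i + 1] - edges[i])
        return frac

    @property
    def modal_bin_um(self) -> tuple[float, float]:
        if self.n_total == 0:
            raise EmptyClusterSetError("empty histogram has no mode")
        i = int(np.argmax(self.frequency))
        return (float(self.bin_edges_um[i]), float(self.bin_edges_um[i + 1]))


@dataclass
class ColocResult:
    """Manders split coefficients.

    m1 is the fraction of marker A (area or intensity) overlapping B; m2
    the fraction of B overlapping A. A side with no signal has its
    coefficient reported as NaN and flagged undefined.
    """

    m1: float
    m2: float
    mode: str
    m1_defined: bool = True
    m2_defined: bool = True


def moments_threshold(histogram: np.ndarray) -> int:
    """Moment-preserving (bilevel) auto-threshold of an intensity histogram.

    Finds the two representative gray levels and mixing fraction p0 that
    preserve the first three gray-level moments of the image, then returns
    the gray level at which the cumulative histogram splits the image into
    a below/above partition of size p0. When a run of levels ties (a flat
    stretch of the cumulative distribution), the middle level of the run is
    returned, so the threshold falls strictly between two separated modes.

    Parameters
    ----------
    histogram : array of int
        Counts per gray level (typically 256 bins).

    Returns
    -------
    int
        Threshold level; foreground is intensity strictly greater.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("histogram must be a 1D array with >= 2 bins")
    if (h < 0).any() or h.sum() <= 0:
        raise ValueError("histogram needs non-negative counts with positive total")
    p = h / h.sum()
    levels = np.arange(h.size, dtype=float)
    m1 = float(p @ levels)
    m2 = float(p @ levels**2)
    m3 = float(p @ levels**3)
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("all intensity mass in one gray level")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:  # numerically impossible for a genuine two-level mix
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise DegenerateHistogramError("moment system has a single representative level")
    p0 = (z1 - m1) / (z1 - z0)
    cdf = np.cumsum(p)
    err = np.abs(cdf - p0)
    ties = np.flatnonzero(np.isclose(err, err.min(), rtol=0.0, atol=1e-12))
    return int(ties[len(ties) // 2])


def binarize(stack: np.ndarray | ImageStack, threshold: float, channel: str | None = None) -> np.ndarray:
    """Global binarization: voxel is foreground iff intensity > threshold."""
    if isinstance(stack, ImageStack):
        if channel is None and len(stack.channels) == 1:
            channel = next(iter(stack.channels))
        arr = stack.channel(channel)
    else:
        arr = np.asarray(stack)
    return arr > threshold


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3, 4: 1, 8: 2}


def connected_components(
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    connectivity: int = 26,
    threshold: float | None = None,
    channel: str | None = None,
) -> ClusterSet:
    """Label maximal connected foreground voxel sets of a binary mask.

    ``connectivity`` uses the 3D neighbor-count convention (6, 18 or 26);
    2D masks accept 4 or 8. Default 26: blurred blobs touching diagonally
    are in physical contact.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 2:
        mask = mask[None]
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    spacing = tuple(float(s) for s in spacing)
    rows = []
    voxels: dict[int, np.ndarray] = {}
    if n:
        objs = ndimage.find_objects(labels)
        for cid in range(1, n + 1):
            sl = objs[cid - 1]
            idx = np.argwhere(labels[sl] == cid)
            idx += [s.start for s in sl]
            voxels[cid] = idx
            centers = (idx + 0.5) * spacing
            cz, cy, cx = centers.mean(axis=0)
            rows.append(
                {
                    "id": cid,
                    "centroid_z_um": cz,
                    "centroid_y_um": cy,
                    "centroid_x_um": cx,
                    "n_voxels": len(idx),
                }
            )
    table = pd.DataFrame(
        rows, columns=["id", "centroid_z_um", "centroid_y_um", "centroid_x_um", "n_voxels"]
    )
    return ClusterSet(
        table=table,
        voxels=voxels,
        spacing=spacing,
        threshold=threshold,
        connectivity=connectivity,
        channel=channel,
    )


def major_diameter(voxels: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Major diameter of a cluster in µm: 3D max Feret over voxel centers.

    The Feret term is the maximum Euclidean distance between member voxel
    centers in physical units, plus a quarter of the mean voxel pitch.
    The additive term corrects the quantization shortfall of the discrete
    chord: endpoint voxel centers sit inside the true surface, but because
    the maximum is taken over many near-antipodal voxel pairs the expected
    shortfall is well below the naive one-pitch per-endpoint extent, and
    calibration on voxelized spheres two to four voxels across puts it
    near a quarter pitch (a full-pitch term overshoots by most of a pitch
    and shifts size histograms by a whole bin). A single-voxel cluster
    reports one mean voxel pitch, the size of a voxel, rather than zero.
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise EmptyClusterSetError("empty cluster has no diameter")
    spacing = np.asarray(spacing, dtype=float)
    pts = (voxels + 0.5) * spacing
    extent = float(spacing.mean())
    if len(pts) == 1:
        return extent
    cand = pts
    if len(pts) > 64:
        # max pairwise distance is attained on the convex hull
        try:
            from scipy.spatial import ConvexHull

            cand = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except Exception:
            cand = pts
    d2 = ((cand[:, None, :] - cand[None, :, :]) ** 2).sum(-1)
    return max(float(np.sqrt(d2.max())) + 0.25 * extent, extent)


def measure_clusters(clusters: ClusterSet) -> ClusterSet:
    """Attach major_diameter_um to every cluster in place and return it."""
    diams = [major_diameter(clusters.voxels[i], clusters.spacing) for i in clusters.table["id"]]
    clusters.table["major_diameter_um"] = diams
    return clusters


def diameter_histogram(diameters_um, bin_width_um: float = 0.25) -> DiameterHistogram:
    """Group diameters into fixed-width, left-closed bins starting at 0.

    Frequencies are normalized to the total cluster count (they sum to 1
    when any cluster is present). The default 0.25 µm width is the 250-nm
    binning used for nanoparticle cluster sizes.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        return DiameterHistogram(np.array([0.0]), np.array([]), 0)
    if (d < 0).any():
        raise ValueError("diameters must be non-negative")
    n_bins = int(np.floor(d.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.minimum((d / bin_width_um).astype(int), n_bins - 1)
    # left-closed, right-open: value exactly on an edge goes in the upper bin
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return DiameterHistogram(edges, counts / d.size, int(d.size))


def nearest_neighbor_distances(points_um, box_um=None) -> tuple[np.ndarray, float]:
    """Per-point nearest-neighbor distance and its mean.

    Parameters
    ----------
    points_um : (n, d) array
        Point coordinates in µm (cluster centroids).
    box_um : sequence of float, optional
        Periodic box lengths per axis; when given, distances wrap around
        the box (toroidal edge correction for spatial statistics).

    Returns
    -------
    (nnd, mean) : per-point distances in input order, and their mean.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if len(pts) < 2:
        raise InsufficientPointsError("nearest-neighbor distances need >= 2 points")
    tree = cKDTree(pts, boxsize=box_um)
    dist, _ = tree.query(pts, k=2)
    nnd = dist[:, 1]
    return nnd, float(nnd.mean())


def _alpha_shape(points_xy: np.ndarray, shrink: float) -> Polygon:
    """Concave boundary polygon enclosing all points.

    shrink = 0 gives the convex hull; larger values drop Delaunay
    triangles with large circumradii (down to the (1 - shrink) circumradius
    quantile) while keeping every point on the retained surface.
    """
    pts = np.asarray(points_xy, dtype=float)
    mp = MultiPoint([tuple(p) for p in pts])
    if len(pts) < 3:
        return mp.convex_hull.buffer(0)
    try:
        tri = Delaunay(pts)
    except Exception:
        return mp.convex_hull.buffer(0)
    simplices = tri.simplices
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    # circumradius = abc / (4 * area)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        radii = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    keep = np.ones(len(simplices), dtype=bool)
    if shrink > 0:
        finite = radii[np.isfinite(radii)]
        if finite.size:
            alpha = np.quantile(finite, 1.0 - shrink)
            order = np.argsort(radii)[::-1]
            covered = np.zeros(len(pts), dtype=int)
            for s in simplices[keep]:
                covered[s] += 1
            for i in order:
                if not np.isfinite(radii[i]) or radii[i] > alpha:
                    verts = simplices[i]
                    if (covered[verts] > 1).all():  # removal keeps all points covered
                        keep[i] = False
                        covered[verts] -= 1
    polys = [Polygon(pts[s]) for s in simplices[keep]]
    merged = unary_union(polys)
    return merged.buffer(0)


def coverage_fraction(
    projection,
    roi_polygon_um,
    spacing_yx: tuple[float, float] = (1.0, 1.0),
    shrink: float = 0.5,
) -> float:
    """Percent of an ROI covered by the boundary of the foreground cloud.

    ``projection`` is either a binary Z-max projection (foreground pixel
    centers become points) or an (n, 2) array of (x, y) points in µm. The
    boundary polygon (alpha shape with ``shrink``; convex hull at 0) is
    intersected with the ROI, and its area is reported as a percentage of
    the ROI area. No foreground gives 0 %.
    """
    roi = Polygon(roi_polygon_um) if not isinstance(roi_polygon_um, Polygon) else roi_polygon_um
    if roi.area <= 0:
        raise ValueError("ROI polygon must have positive area")
    proj = np.asarray(projection)
    if proj.ndim == 2 and proj.dtype == bool or (proj.ndim == 2 and proj.shape[1] != 2):
        ys, xs = np.nonzero(proj)
        pts = np.column_stack([(xs + 0.5) * spacing_yx[1], (ys + 0.5) * spacing_yx[0]])
    else:
        pts = np.atleast_2d(proj.astype(float))
    if len(pts) == 0:
        return 0.0
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must be in [0, 1]")
    boundary = _alpha_shape(pts, shrink)
    return 100.0 * boundary.intersection(roi).area / roi.area


def internalization_fraction(clusters: ClusterSet, compartment_mask: np.ndarray) -> float:
    """Percent of clusters whose centroid voxel lies inside a compartment.

    Membership by centroid makes the counts partition-exact: every cluster
    is either inside or outside, and the in/out percentages sum to 100.
    """
    if len(clusters) == 0:
        raise EmptyClusterSetError("internalization fraction undefined without clusters")
    mask = np.asarray(compartment_mask).astype(bool)
    if mask.ndim == 2:
        mask = mask[None]
    spacing = np.asarray(clusters.spacing)
    idx = np.floor(clusters.centroids_um / spacing).astype(int)
    idx = np.clip(idx, 0, np.array(mask.shape) - 1)
    inside = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    return 100.0 * float(inside.sum()) / len(clusters)


def manders_coefficients(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    mode: str = "area",
    intensities_a: np.ndarray | None = None,
    intensities_b: np.ndarray | None = None,
) -> ColocResult:
    """Manders split colocalization coefficients M1 and M2.

    Area mode (default): M1 = |A∩B| / |A| and M2 = |A∩B| / |B| on binary
    masks. Intensity mode: M1 = sum of A's intensity inside B divided by
    A's total intensity (and symmetrically for M2), the standard
    intensity-weighted split coefficients.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one geometry")
    overlap = a & b
    if mode == "area":
        na, nb = int(a.sum()), int(b.sum())
        m1 = overlap.sum() / na if na else np.nan
        m2 = overlap.sum() / nb if nb else np.nan
        return ColocResult(float(m1), float(m2), "area", na > 0, nb > 0)
    if mode == "intensity":
        if intensities_a is None or intensities_b is None:
            raise ValueError("intensity mode needs both intensity arrays")
        ia = np.asarray(intensities_a, dtype=float)
        ib = np.asarray(intensities_b, dtype=float)
        if ia.shape != a.shape or ib.shape != a.shape:
            raise ValueError("intensities must share the mask geometry")
        ta, tb = float(ia[a].sum()), float(ib[b].sum())
        m1 = float(ia[a & b].sum()) / ta if ta > 0 else np.nan
        m2 = float(ib[b & a].sum()) / tb if tb > 0 else np.nan
        return ColocResult(m1, m2, "intensity", ta > 0, tb > 0)
    raise ValueError("mode must be 'area' or 'intensity'")


def integrated_density(
    channel: np.ndarray, rois: list, projection: str = "sum"
) -> tuple[np.ndarray, float]:
    """Integrated intensity within polygon ROIs of a projected stack.

    The stack is sum-projected along Z (a 2D image is its own projection);
    each ROI polygon, in pixel coordinates as (x, y) vertices, selects the
    pixels whose centers fall inside it; their projected intensities are
    summed. Returns per-ROI integrated densities and their mean.
    """
    from skimage.draw import polygon as draw_polygon

    arr = np.asarray(channel, dtype=float)
    if arr.ndim == 3:
        if projection != "sum":
            raise ValueError("only sum projection is supported")
        img = arr.sum(axis=0)
    elif arr.ndim == 2:
        img = arr
    else:
        raise ValueError("channel must be 2D or 3D")
    if not rois:
        raise ValueError("need at least one ROI")
    values = []
    for poly in rois:
        poly = np.asarray(poly, dtype=float)
        if (
            poly[:, 0].min() < 0
            or poly[:, 1].min() < 0
            or poly[:, 0].max() > img.shape[1]
            or poly[:, 1].max() > img.shape[0]
        ):
            raise ValueError("ROI polygon extends outside the image")
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        values.append(float(img[rr, cc].sum()))
    values = np.asarray(values)
    return values, float(values.mean())


@dataclass
class ParticleReport:
    """Bundle of the per-stack nanoparticle distribution metrics."""

    clusters: ClusterSet
    histogram: DiameterHistogram
    nnd_um: np.ndarray = field(repr=False)
    mean_nnd_um: float = float("nan")
    internalized_pct: float | None = None
    coverage_pct: float | None = None


def quantify_particles(
    stack: ImageStack,
    channel: str,
    compartment_mask: np.ndarray | None = None,
    roi_polygon_um=None,
    connectivity: int = 26,
    shrink: float = 0.5,
    n_hist_bins: int = 256,
    min_voxels: int = 4,
    threshold_scope: str = "global",
) -> ParticleReport:
    """Full nanoparticle pipeline on one stack.

    Moments auto-threshold on the whole-stack histogram, global
    binarization, connected components, per-cluster major diameters, 250-nm
    diameter histogram, nearest-neighbor distances, and (given the inputs)
    internalization percent against a compartment mask and percent ROI
    coverage from the Z-max projection boundary.

    ``min_voxels`` drops components below the optical resolution: the
    moment-preserving split of a sparse bright-object histogram lands in
    the tail of the background noise, so isolated supra-threshold noise
    voxels would otherwise be counted as clusters.

    ``threshold_scope`` is "global" (one threshold from the whole-stack
    histogram; volumes are binarized as volumes) or "per_slice" (a Moments
    threshold per z-slice, for stacks with strong depth-dependent
    illumination); the recorded threshold provenance is then the slice
    mean.
    """
    arr = stack.channel(channel)

    def _threshold(a: np.ndarray) -> float:
        lo, hi = float(a.min()), float(a.max())
        if hi == lo:
            return lo
        scaled = ((a - lo) / (hi - lo) * (n_hist_bins - 1)).round().astype(int)
        hist = np.bincount(scaled.ravel(), minlength=n_hist_bins)
        return lo + moments_threshold(hist) * (hi - lo) / (n_hist_bins - 1)

    if threshold_scope == "global":
        threshold = _threshold(arr)
        mask = binarize(arr, threshold)
    elif threshold_scope == "per_slice":
        slice_thresholds = [_threshold(sl) for sl in arr]
        mask = np.stack([sl > t for sl, t in zip(arr, slice_thresholds)])
        threshold = float(np.mean(slice_thresholds))
    else:
        raise ValueError("threshold_scope must be 'global' or 'per_slice'")
    clusters = connected_components(
        mask, spacing=stack.spacing, connectivity=connectivity, threshold=threshold, channel=channel
    )
    if min_voxels > 1 and len(clusters):
        keep = clusters.table["n_voxels"] >= min_voxels
        clusters.table = clusters.table[keep].reset_index(drop=True)
        clusters.voxels = {i: clusters.voxels[i] for i in clusters.table["id"]}
    measure_clusters(clusters)
    hist_d = diameter_histogram(clusters.table.get("major_diameter_um", pd.Series(dtype=float)))
    if len(clusters) >= 2:
        nnd, mean_nnd = nearest_neighbor_distances(clusters.centroids_um)
    else:
        nnd, mean_nnd = np.array([]), float("nan")
    internal = (
        internalization_fraction(clusters, compartment_mask)
        if compartment_mask is not None and len(clusters)
        else None
    )
    coverage = None
    if roi_polygon_um is not None:
        coverage = coverage_fraction(
            mask.max(axis=0), roi_polygon_um, spacing_yx=stack.spacing[1:], shrink=shrink
        )
    return ParticleReport(clusters, hist_d, nnd, mean_nnd, internal, coverage)
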