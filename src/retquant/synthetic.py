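"""Synthetic inputs with ground truth for every pipeline stage.

Each generator emulates one input class of the experiment and returns,
alongside the data, a ground-truth table enumerating exactly the objects
it generated, so downstream measurements can be validated without any
acquired data:

* confocal Z-stacks of clustered sub-micron fluorescent puncta confined to
  a thin subretinal layer (log-normal diameters, main mode near 0.85 µm),
  with an RPE band holding a controlled internalized fraction;
* microglia masks in ramified (random process trees) or ameboid
  (near-circular blob) states;
* hexagonal RPE mosaics as Voronoi tessellations of a jittered lattice;
* evoked LFP sweeps (stereotyped deflection on 1/f background noise) and
  pattern-series amplitudes decaying linearly in log spatial frequency
  with a known acuity cutoff;
* Poisson spike trains with a post-stimulus rate gain;
* optomotor and freezing state traces with exact state durations.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; identical arguments and seed give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, Voronoi, cKDTree

from .ephys import TrialRecording


class PackingError(RuntimeError):
    """Requested objects cannot be placed under the non-overlap constraint."""


@dataclass
class GroundTruth:
    """Tables enumerating exactly the generated objects (one row each)."""

    clusters: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    ephys: pd.DataFrame | None = None
    behavior: pd.DataFrame | None = None


@dataclass
class StackSpec:
    """Recipe for a synthetic nanoparticle Z-stack.

    Defaults emulate the acquisition geometry of the source experiments: a
    ~64 x 64 µm field at 0.283 µm/pixel XY with a 700-nm Z-step, cluster
    diameters log-normal with mode 0.85 µm, and 30 % of the clusters
    placed in the RPE band. ``shape_xyz``/``spacing_xyz``/bands are in
    (x, y, z) voxel/µm order; bands are half-open voxel intervals.
    """

    shape_xyz: tuple[int, int, int] = (226, 226, 60)
    spacing_xyz: tuple[float, float, float] = (0.283, 0.283, 0.3)
    n_clusters: int = 100
    diameter_mode_um: float = 0.85
    diameter_sigma: float = 0.25
    layer_band_z: tuple[int, int] = (4, 56)
    psf_sigma_um: float = 0.05
    noise_gaussian_sd: float = 20.0
    noise_poisson_scale: float = 0.0
    rpe_band_z: tuple[int, int] = (40, 56)
    internalized_fraction: float = 0.3
    amplitude: float = 1000.0
    min_separation_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz = self.shape_xyz[2]
        for name, band in ("layer_band_z", self.layer_band_z), ("rpe_band_z", self.rpe_band_z):
            if not (0 <= band[0] < band[1] <= nz):
                raise ValueError(f"{name} {band} not within the stack depth [0, {nz})")
        if self.diameter_mode_um <= 0:
            raise ValueError("diameter mode must be positive")
        if not 0.0 <= self.internalized_fraction <= 1.0:
            raise ValueError("internalized_fraction must be in [0, 1]")


def _draw_centers(
    rng: np.random.Generator,
    n: int,
    radii_um: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    z_bands: list[tuple[float, float]],
    min_sep_extra: float,
    max_attempts_per: int = 2000,
) -> np.ndarray:
    """Place sphere centers with separation >= sum of radii + margin.

    ``z_bands[i]`` bounds the z coordinate of center i; x/y bounds are
    shared. Raises PackingError when the retry budget is exhausted.
    """
    centers = np.empty((n, 3))
    for i in range(n):
        zlo, zhi = z_bands[i]
        if zhi <= zlo:
            raise PackingError("z band too thin for the drawn cluster radius")
        placed = False
        for _ in range(max_attempts_per):
            cand = np.array(
                [
                    rng.uniform(lo[0], hi[0]),
                    rng.uniform(lo[1], hi[1]),
                    rng.uniform(zlo, zhi),
                ]
            )
            if i == 0:
                placed = True
            else:
                d = np.linalg.norm(centers[:i] - cand, axis=1)
                placed = bool((d >= radii_um[:i] + radii_um[i] + min_sep_extra).all())
            if placed:
                centers[i] = cand
                break
        if not placed:
            raise PackingError(
                f"could not place cluster {i + 1}/{n} under the non-overlap constraint"
            )
    return centers


def generate_np_stack(spec: StackSpec):
    """Render a nanoparticle Z-stack with known cluster ground truth.

    Clusters are solid spheres of log-normal diameter (center-sampled:
    a voxel belongs to the sphere when its center is within the radius),
    blurred by a Gaussian PSF, with noise applied after the blur.
    ``round(internalized_fraction * n_clusters)`` cluster centers are
    placed in the RPE z-band, the rest in the retinal part of the layer
    band.

    Returns
    -------
    (stack, masks, ground_truth)
        ``stack`` is an :class:`~retquant.imaging.ImageStack` with one
        channel ``"np"``; ``masks`` maps ``"rpe"`` and ``"retina"`` to
        boolean compartment masks; ``ground_truth.clusters`` has one row
        per cluster (id, x/y/z_um, diameter_um, compartment).
    """
    from .imaging import ImageStack

    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape_xyz
    sx, sy, sz = spec.spacing_xyz
    shape_zyx = (nz, ny, nx)
    spacing_zyx = (sz, sy, sx)

    n = int(spec.n_clusters)
    gt_rows: list[dict] = []
    arr = np.zeros(shape_zyx, dtype=float)

    if n > 0:
        mu = math.log(spec.diameter_mode_um) + spec.diameter_sigma**2
        diameters = rng.lognormal(mean=mu, sigma=spec.diameter_sigma, size=n)
        radii = diameters / 2.0
        n_internal = int(round(spec.internalized_fraction * n))
        compartments = np.array(["RPE"] * n_internal + ["retina"] * (n - n_internal))

        # shared x/y bounds use the largest radius margin for simplicity
        m = float(radii.max()) + 0.5
        lo_xy = np.array([m, m])
        hi_xy = np.array([nx * sx - m, ny * sy - m])
        if (hi_xy <= lo_xy).any():
            raise PackingError("field too small for the drawn cluster sizes")
        rpe_lo, rpe_hi = spec.rpe_band_z[0] * sz, spec.rpe_band_z[1] * sz
        lay_lo = spec.layer_band_z[0] * sz
        ret_hi = rpe_lo if rpe_lo > lay_lo else spec.layer_band_z[1] * sz
        z_bands = []
        for i in range(n):
            pad = radii[i] + 0.5 * sz
            if compartments[i] == "RPE":
                z_bands.append((rpe_lo + pad, rpe_hi - pad))
            else:
                z_bands.append((lay_lo + pad, ret_hi - pad))
        centers = _draw_centers(
            rng, n, radii, lo_xy, hi_xy, z_bands, spec.min_separation_um
        )  # (n, 3) in (x, y, z) µm

        zc = (np.arange(nz) + 0.5) * sz
        yc = (np.arange(ny) + 0.5) * sy
        xc = (np.arange(nx) + 0.5) * sx
        for i in range(n):
            cxu, cyu, czu = centers[i]
            r = radii[i]
            zi = np.flatnonzero(np.abs(zc - czu) <= r)
            yi = np.flatnonzero(np.abs(yc - cyu) <= r)
            xi = np.flatnonzero(np.abs(xc - cxu) <= r)
            if zi.size and yi.size and xi.size:
                dz2 = (zc[zi] - czu) ** 2
                dy2 = (yc[yi] - cyu) ** 2
                dx2 = (xc[xi] - cxu) ** 2
                inside = (
                    dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
                ) <= r * r
                sub = arr[np.ix_(zi, yi, xi)]
                sub[inside] = spec.amplitude
                arr[np.ix_(zi, yi, xi)] = sub
            gt_rows.append(
                {
                    "id": i + 1,
                    "x_um": cxu,
                    "y_um": cyu,
                    "z_um": czu,
                    "diameter_um": diameters[i],
                    "compartment": compartments[i],
                }
            )

    if spec.psf_sigma_um > 0:
        sigma_vox = [spec.psf_sigma_um / s for s in spacing_zyx]
        arr = ndimage.gaussian_filter(arr, sigma=sigma_vox)
    if spec.noise_poisson_scale > 0:
        arr = rng.poisson(np.clip(arr, 0, None) * spec.noise_poisson_scale) / (
            spec.noise_poisson_scale
        )
    if spec.noise_gaussian_sd > 0:
        arr = arr + rng.normal(0.0, spec.noise_gaussian_sd, size=arr.shape)

    zidx = np.arange(nz)[:, None, None]
    rpe_mask = np.broadcast_to(
        (zidx >= spec.rpe_band_z[0]) & (zidx < spec.rpe_band_z[1]), shape_zyx
    ).copy()
    layer = (zidx >= spec.layer_band_z[0]) & (zidx < spec.layer_band_z[1])
    retina_mask = np.broadcast_to(layer, shape_zyx).copy() & ~rpe_mask

    gt = GroundTruth(
        clusters=pd.DataFrame(
            gt_rows, columns=["id", "x_um", "y_um", "z_um", "diameter_um", "compartment"]
        )
    )
    stack = ImageStack(channels={"np": arr}, spacing=spacing_zyx)
    return stack, {"rpe": rpe_mask, "retina": retina_mask}, gt


# ---------------------------------------------------------------------------
# microglia


def _draw_segment(canvas: np.ndarray, y0: float, x0: float, angle: float, length: float):
    from skimage.draw import line

    y1 = y0 + length * math.sin(angle)
    x1 = x0 + length * math.cos(angle)
    rr, cc = line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
    ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[ok], cc[ok]] = True
    return y1, x1


def _ramified_cell(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center: tuple[float, float],
    soma_radius_px: float,
    n_primary: int,
    segment_px: float,
    depth: int,
    branch_p: float,
    angle_jitter: float,
) -> np.ndarray:
    from skimage.draw import disk as draw_disk

    canvas = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, soma_radius_px, shape=shape)
    canvas[rr, cc] = True
    base = rng.uniform(0, 2 * math.pi)
    tips = []
    for kk in range(n_primary):
        tips.append((center[0], center[1], base + 2 * math.pi * kk / n_primary, 0))
    while tips:
        y, x, ang, d = tips.pop()
        y1, x1 = _draw_segment(canvas, y, x, ang, segment_px)
        if d + 1 < depth:
            if branch_p > 0 and rng.random() < branch_p:
                split = rng.uniform(0.3, 0.7)
                tips.append((y1, x1, ang + split * angle_jitter, d + 1))
                tips.append((y1, x1, ang - (1 - split) * angle_jitter, d + 1))
            else:
                jit = rng.uniform(-angle_jitter, angle_jitter) if angle_jitter > 0 else 0.0
                tips.append((y1, x1, ang + jit, d + 1))
    return canvas


def _blob_polygon(rng: np.random.Generator, radius_px: float, irregularity: float,
                  n_vertices: int = 256) -> np.ndarray:
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, float(radius_px))
    if irregularity > 0:
        for k in (2, 3, 5):
            r += radius_px * irregularity * rng.uniform(-1, 1) * np.cos(
                k * theta + rng.uniform(0, 2 * math.pi)
            )
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_microglia(
    n_cells: int,
    state: str,
    image_shape: tuple[int, int] = (512, 512),
    spacing_um: float = 0.5,
    soma_radius_px: float = 6.0,
    n_primary: int = 4,
    segment_px: float = 10.0,
    depth: int = 4,
    branch_p: float = 0.5,
    angle_jitter: float = 0.6,
    blob_radius_px: float = 20.0,
    blob_irregularity: float = 0.08,
    seed: int = 0,
    max_attempts: int = 200,
):
    """Synthetic microglia as a label image plus ground truth.

    ``state="ramified"`` renders random trees of 1-pixel-wide processes
    growing from a soma disk; the true branching span is the maximum
    root-to-tip Euclidean distance actually drawn. ``state="ameboid"``
    renders near-circular blobs whose true circularity is computed
    analytically from the generating polygon. Somata are placed with a
    retry budget; exhausting it raises PackingError.
    """
    from skimage.draw import polygon as draw_polygon

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if state not in ("ramified", "ameboid"):
        raise ValueError("state must be 'ramified' or 'ameboid'")
    rng = np.random.default_rng(seed)
    labels = np.zeros(image_shape, dtype=np.uint16)
    reach = (soma_radius_px + segment_px * depth) if state == "ramified" else blob_radius_px * 1.5
    centers: list[tuple[float, float]] = []
    rows = []
    for cid in range(1, n_cells + 1):
        placed = None
        for _ in range(max_attempts):
            cy = rng.uniform(reach, image_shape[0] - reach)
            cx = rng.uniform(reach, image_shape[1] - reach)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * reach) ** 2 for y, x in centers):
                placed = (cy, cx)
                break
        if placed is None:
            raise PackingError(f"could not place soma {cid}/{n_cells}")
        centers.append(placed)
        cy, cx = placed
        if state == "ramified":
            cell = _ramified_cell(
                rng, image_shape, placed, soma_radius_px, n_primary, segment_px,
                depth, branch_p, angle_jitter,
            )
            ys, xs = np.nonzero(cell)
            span_px = float(np.sqrt(((ys - cy) ** 2 + (xs - cx) ** 2).max()))
            labels[cell & (labels == 0)] = cid
            rows.append(
                {
                    "id": cid,
                    "soma_y_px": cy,
                    "soma_x_px": cx,
                    "span_um": span_px * spacing_um,
                    "circularity": np.nan,
                    "state": state,
                }
            )
        else:
            poly = _blob_polygon(rng, blob_radius_px, blob_irregularity)
            verts = poly + [cx, cy]
            rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=image_shape)
            labels[rr, cc] = cid
            x, y = poly[:, 0], poly[:, 1]
            area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            closed = np.vstack([poly, poly[:1]])
            perim = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
            rows.append(
                {
                    "id": cid,
                    "soma_y_px": cy,
                    "soma_x_px": cx,
                    "span_um": np.nan,
                    "circularity": 4 * math.pi * area / perim**2,
                    "state": state,
                }
            )
    return labels, GroundTruth(cells=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RPE mosaic


def generate_rpe_mosaic(
    n_cells: int,
    jitter: float = 0.15,
    spacing_um: float = 1.0,
    pitch_px: float = 24.0,
    seed: int = 0,
):
    """Voronoi mosaic of a jittered hexagonal lattice as a label image.

    ``n_cells`` is rounded up to a full rows x columns hexagonal lattice;
    the ground-truth table enumerates the cells actually generated.
    ``jitter`` displaces each seed uniformly by up to ``jitter * pitch``
    per axis; at 0 every interior cell is a regular hexagon with exactly
    6 neighbors. Ground-truth neighbor counts come from the tessellation
    adjacency (Delaunay edges of the seed points restricted to pairs of
    generated cells); the measured label image assigns each pixel to its
    nearest seed.

    Returns (label_image, ground_truth); ``ground_truth.cells`` columns:
    id, seed_y_px, seed_x_px, neighbors, is_border. The attribute
    ``ground_truth.cells.attrs["density_per_um2"]`` is the exact
    cell count / field area density.
    """
    if n_cells < 7:
        raise ValueError("need at least 7 cells for a mosaic with an interior")
    rng = np.random.default_rng(seed)
    cols = int(math.ceil(math.sqrt(n_cells)))
    rows_n = int(math.ceil(n_cells / cols))
    dy = pitch_px * math.sqrt(3) / 2
    seeds = []
    for r in range(rows_n):
        off = 0.25 * pitch_px if r % 2 == 0 else -0.25 * pitch_px
        for c in range(cols):
            seeds.append((r * dy, c * pitch_px + off))
    seeds = np.asarray(seeds, dtype=float)
    seeds += rng.uniform(-jitter * pitch_px, jitter * pitch_px, size=seeds.shape) if jitter > 0 else 0.0
    # shift into a field with a half-pitch border
    seeds -= seeds.min(axis=0)
    seeds += [0.5 * dy, 0.5 * pitch_px]
    h = int(math.ceil(seeds[:, 0].max() + 0.5 * dy))
    w = int(math.ceil(seeds[:, 1].max() + 0.5 * pitch_px))

    tri = Delaunay(seeds)
    indptr, indices = tri.vertex_neighbor_vertices

    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel() + 0.5, xx.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(pix)
    labels = (nearest + 1).astype(np.uint16).reshape(h, w)
    # border cells: region reaches the field edge, or adjacent to one that
    # does (their tessellation neighbor counts are deflated by truncation)
    edge_ids = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    open_region = np.zeros(len(seeds), dtype=bool)
    open_region[edge_ids - 1] = True
    ring = [
        i
        for i in range(len(seeds))
        if not open_region[i] and open_region[indices[indptr[i]:indptr[i + 1]]].any()
    ]
    open_region[ring] = True

    rows = []
    for i in range(len(seeds)):
        nb = indices[indptr[i]:indptr[i + 1]]
        rows.append(
            {
                "id": i + 1,
                "seed_y_px": seeds[i, 0],
                "seed_x_px": seeds[i, 1],
                "neighbors": int(len(nb)),
                "is_border": bool(open_region[i]),
            }
        )
    cells = pd.DataFrame(rows)
    cells.attrs["density_per_um2"] = len(seeds) / (h * w * spacing_um**2)
    cells.attrs["field_shape"] = (h, w)
    return labels, GroundTruth(cells=cells)


# ---------------------------------------------------------------------------
# electrophysiology


def one_over_f_noise(rng: np.random.Generator, n_samples: int, fs: float, sd: float,
                     f_floor_hz: float = 1.0) -> np.ndarray:
    """Noise with a 1/f amplitude spectrum, scaled to a target SD.

    White Gaussian noise is shaped in the frequency domain by 1/f (flat
    below ``f_floor_hz`` to keep the variance finite), matching the
    power-law background of cortical field potentials.
    """
    white = rng.normal(0.0, 1.0, n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.maximum(f, f_floor_hz)
    spec *= shaping
    out = np.fft.irfft(spec, n=n_samples)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def generate_vep_recording(
    n_trials: int = 200,
    fs: float = 5000.0,
    evoked_amplitude_uv: float = 100.0,
    latency_ms: float = 100.0,
    noise_sd_uv: float = 30.0,
    acuity_c_per_deg: float = 0.4,
    slope_uv_per_decade: float = 20.0,
    freqs_c_per_deg=(0.015, 0.05, 0.1, 0.2, 0.3),
    amp_noise_sd_uv: float = 0.0,
    trial_s: float = 1.0,
    onset_s: float = 0.2,
    deflection_sd_ms: float = 10.0,
    seed: int = 0,
):
    """Synthetic evoked-potential sweeps plus a pattern amplitude series.

    Each trial is 1/f background noise plus a stereotyped negative
    Gaussian-shaped deflection of the given peak amplitude and latency.
    The pattern series follows A(f) = -slope * (log10 f - log10 acuity)
    plus Gaussian noise, clipped at 0, so A(acuity) = 0 by construction.

    Returns (TrialRecording, amplitude table, ground truth).
    """
    if fs < 1000:
        raise ValueError("sampling rate must be at least 1 kHz")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    n_samples = int(round(trial_s * fs))
    t = np.arange(n_samples) / fs
    deflection = -evoked_amplitude_uv * np.exp(
        -((t - onset_s - latency_ms / 1000.0) ** 2) / (2 * (deflection_sd_ms / 1000.0) ** 2)
    )
    data = np.empty((1, n_samples, n_trials))
    for j in range(n_trials):
        noise = (
            one_over_f_noise(rng, n_samples, fs, noise_sd_uv) if noise_sd_uv > 0 else 0.0
        )
        data[0, :, j] = deflection + noise
    rec = TrialRecording(data=data, fs=fs, onsets=np.full(n_trials, onset_s))

    f = np.asarray(freqs_c_per_deg, dtype=float)
    amps = -slope_uv_per_decade * (np.log10(f) - math.log10(acuity_c_per_deg))
    if amp_noise_sd_uv > 0:
        amps = amps + rng.normal(0.0, amp_noise_sd_uv, size=f.shape)
    amps = np.clip(amps, 0.0, None)
    table = pd.DataFrame({"freq_c_per_deg": f, "amplitude_uv": amps})

    gt = GroundTruth(
        ephys=pd.DataFrame(
            [
                {
                    "evoked_amplitude_uv": evoked_amplitude_uv,
                    "latency_ms": latency_ms,
                    "acuity_c_per_deg": acuity_c_per_deg,
                    "slope_uv_per_decade": slope_uv_per_decade,
                    "responsive": evoked_amplitude_uv > 0,
                }
            ]
        )
    )
    return rec, table, gt


def generate_spike_trains(
    n_units: int = 20,
    baseline_rate_hz: float = 10.0,
    gain: float = 3.0,
    response_window_s: tuple[float, float] = (0.15, 0.5),
    n_trials: int = 50,
    trial_s: float = 1.0,
    onset_s: float = 0.25,
    seed: int = 0,
):
    """Inhomogeneous-Poisson spike tables with a post-stimulus rate gain.

    Within each trial the rate is ``baseline_rate_hz`` except inside
    ``response_window_s`` (relative to stimulus onset) where it is
    baseline x gain; gain 1 is a homogeneous Poisson process. Returns
    (spike table with columns unit/trial/t_s, onsets array, ground truth).
    """
    if baseline_rate_hz < 0 or gain < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    w0 = onset_s + response_window_s[0]
    w1 = min(trial_s, onset_s + response_window_s[1])
    segments = [(0.0, w0, baseline_rate_hz), (w0, w1, baseline_rate_hz * gain),
                (w1, trial_s, baseline_rate_hz)]
    segments = [(a, b, r) for a, b, r in segments if b > a]
    units, trials, times = [], [], []
    for u in range(n_units):
        for tr in range(n_trials):
            for a, b, r in segments:
                k = rng.poisson(r * (b - a))
                if k:
                    ts = np.sort(rng.uniform(a, b, size=k))
                    units.append(np.full(k, u))
                    trials.append(np.full(k, tr))
                    times.append(ts)
    if units:
        spikes = pd.DataFrame(
            {
                "unit": np.concatenate(units).astype(int),
                "trial": np.concatenate(trials).astype(int),
                "t_s": np.concatenate(times),
            }
        )
    else:
        spikes = pd.DataFrame({"unit": [], "trial": [], "t_s": []}).astype(
            {"unit": int, "trial": int, "t_s": float}
        )
    gt = GroundTruth(
        ephys=pd.DataFrame(
            {
                "unit": np.arange(n_units),
                "baseline_rate_hz": baseline_rate_hz,
                "gain": gain,
            }
        )
    )
    onsets = np.full(n_trials, onset_s)
    return spikes, onsets, gt


# ---------------------------------------------------------------------------
# behavior


def _trace_from_counts(rng: np.random.Generator, counts: dict[str, int], dt: float
                       ) -> pd.DataFrame:
    states = np.concatenate([np.repeat(s, c) for s, c in counts.items() if c > 0])
    rng.shuffle(states)
    t = np.arange(len(states)) * dt
    return pd.DataFrame({"t_s": t, "state": states})


def generate_omr_trace(
    concordant_s: float,
    discordant_s: float,
    neither_s: float = 0.0,
    session_s: float | None = None,
    dt_s: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """State trace whose summed state durations equal the request exactly.

    Durations are realized as whole sample counts at ``dt_s`` and the
    samples are randomly interleaved. Durations exceeding the session
    length raise ValueError.
    """
    if min(concordant_s, discordant_s, neither_s) < 0:
        raise ValueError("durations must be non-negative")
    total = concordant_s + discordant_s + neither_s
    if session_s is not None and total > session_s + 1e-9:
        raise ValueError("requested durations exceed the session duration")
    rng = np.random.default_rng(seed)
    counts = {
        "concordant": int(round(concordant_s / dt_s)),
        "discordant": int(round(discordant_s / dt_s)),
        "neither": int(round(neither_s / dt_s)),
    }
    return _trace_from_counts(rng, counts, dt_s)


def generate_freezing_trace(
    freezing_fraction: float,
    session_s: float,
    dt_s: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Freezing/active trace with an exact freezing fraction.

    The number of freezing samples is round(fraction x session samples),
    so e.g. fraction 0.25 of a 300-s session yields exactly 75 s frozen.
    """
    if not 0.0 <= freezing_fraction <= 1.0:
        raise ValueError("freezing_fraction must be in [0, 1]")
    if session_s <= 0:
        raise ValueError("session duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(session_s / dt_s))
    n_freeze = int(round(freezing_fraction * n))
    counts = {"freezing": n_freeze, "active": n - n_freeze}
    return _trace_from_counts(rng, counts, dt_s)


def generate_conditioning_session(
    pairing_fractions=(0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.55),
    cue_dark_fraction: float = 0.1,
    cue_cs_fraction: float = 0.5,
    context_fraction: float = 0.15,
    pairing_s: float = 18.0,
    dt_s: float = 0.1,
    seed: int = 0,
):
    """Phase-labeled freezing traces for a full conditioning protocol.

    Seven CS-US pairings with a rising (learned) freezing fraction, the
    cue-test dark (2 min) and CS (3 min) sub-periods, and the context test
    (5 min). Returns (dict of phase -> trace, ground-truth table of the
    exact per-phase freezing fractions).
    """
    if len(pairing_fractions) != 7:
        raise ValueError("protocol has exactly 7 CS-US pairings")
    rng = np.random.default_rng(seed)
    traces: dict[str, pd.DataFrame] = {}
    rows = []
    phases = [(f"pairing_{i+1}", fr, pairing_s) for i, fr in enumerate(pairing_fractions)]
    phases += [("cue_dark", cue_dark_fraction, 120.0), ("cue_cs", cue_cs_fraction, 180.0),
               ("context", context_fraction, 300.0)]
    for phase, fraction, dur in phases:
        traces[phase] = generate_freezing_trace(
            fraction, dur, dt_s, seed=int(rng.integers(0, 2**31 - 1))
        )
        n = int(round(dur / dt_s))
        exact = int(round(fraction * n)) / n
        rows.append({"phase": phase, "freezing_fraction": exact, "duration_s": dur})
    return traces, GroundTruth(behavior=pd.DataFrame(rows))
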