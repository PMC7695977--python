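"""Synthetic ground-truth generators for every pipeline input.

Every generator is a pure function of its seed. Ground-truth objects use the
exact same polynomial bases and coefficient ordering as the fitting modules
(:mod:`streamspa.poly`), so recovery can be asserted coefficient-wise.

SNR is defined throughout as the ratio of signal variance to noise variance
over the full frame; ``snr=None`` (or ``inf``) disables noise.

The planted local-motion ground truth is restricted to monomials that are
odd in time and zero-mean in space (x*t, y*t, x*y*t per axis): the global
alignment stage absorbs the spatial mean of any local motion and per-patch
trajectories are centered in time, so only this gauge-free subspace of the
full trivariate basis is recoverable from images. The full 20-term basis
remains exercised directly by the deformation-fit oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from streamspa import poly
from streamspa.ctf import CtfParams, ctf_eval
from streamspa.io_formats import MovieStack
from streamspa.stream2d import ClassMetrics


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------


@dataclass
class MotionGroundTruth:
    """Planted motion: per-frame global shifts + local deformation polynomial.

    ``local_coeffs_x/y`` are coefficients in the trivariate 3rd-order basis
    of :data:`streamspa.poly.TRIVARIATE_EXPONENTS` over normalized (x, y, t).
    """

    global_shifts: np.ndarray                       # (n_frames, 2)
    local_coeffs_x: np.ndarray | None = None        # 20-term basis
    local_coeffs_y: np.ndarray | None = None
    seed: int = 0

    def local_shift(self, xn, yn, tn) -> np.ndarray:
        """Local (dx, dy) at normalized coordinates in [-1, 1]."""
        if self.local_coeffs_x is None:
            shape = np.broadcast_shapes(np.shape(xn), np.shape(tn))
            return np.zeros(shape + (2,))
        coords = np.stack(np.broadcast_arrays(
            np.asarray(xn, float), np.asarray(yn, float),
            np.asarray(tn, float)), axis=-1).reshape(-1, 3)
        exps = poly.TRIVARIATE_EXPONENTS
        dx = poly.eval_poly(self.local_coeffs_x, coords, exps)
        dy = poly.eval_poly(self.local_coeffs_y, coords, exps)
        shape = np.broadcast_shapes(np.shape(xn), np.shape(tn))
        return np.stack([dx, dy], axis=-1).reshape(shape + (2,))


@dataclass
class CtfGroundTruth:
    """Planted CTF: base parameters + optional bivariate defocus field.

    ``field_dfx/dfy`` are coefficients in the 10-term basis of
    :data:`streamspa.poly.BIVARIATE_EXPONENTS` over normalized (x, y); when
    absent the defocus is ``base.dfx/dfy`` everywhere.
    """

    base: CtfParams
    field_dfx: np.ndarray | None = None
    field_dfy: np.ndarray | None = None

    def local_defocus(self, xn: float, yn: float) -> tuple[float, float]:
        if self.field_dfx is None:
            return self.base.dfx, self.base.dfy
        coord = np.array([[xn, yn]])
        exps = poly.BIVARIATE_EXPONENTS
        return (float(poly.eval_poly(self.field_dfx, coord, exps)[0]),
                float(poly.eval_poly(self.field_dfy, coord, exps)[0]))


def random_ctf_params(seed: int = 0, df_range=(0.8, 3.0),
                      max_astigmatism: float = 0.2,
                      pixel_size: float = 1.0) -> CtfParams:
    """Random realistic CTF ground truth: mean defocus in ``df_range`` um
    and modest astigmatism (|dfx - dfy| up to ``max_astigmatism`` um, the
    regime the restrained astigmatism search is designed for).
    """
    rng = np.random.default_rng(seed)
    mean_df = rng.uniform(*df_range)
    ast = rng.uniform(0.0, max_astigmatism)
    ang = rng.uniform(0.0, 180.0)
    return CtfParams(dfx=mean_df + ast / 2, dfy=mean_df - ast / 2,
                     ang_ast=ang, pixel_size=pixel_size)


def linear_defocus_field(base_df: float, edge_to_edge_x: float = 0.0,
                         edge_to_edge_y: float = 0.0) -> np.ndarray:
    """Bivariate coefficients of a linear defocus tilt in um.

    ``edge_to_edge_*`` is the total defocus change across the field.
    """
    coeffs = np.zeros(len(poly.BIVARIATE_EXPONENTS))
    exps = poly.BIVARIATE_EXPONENTS
    coeffs[exps.index((0, 0))] = base_df
    coeffs[exps.index((1, 0))] = edge_to_edge_x / 2.0
    coeffs[exps.index((0, 1))] = edge_to_edge_y / 2.0
    return coeffs


def random_motion_truth(n_frames: int = 16, total_drift: float = 8.0,
                        max_local: float = 3.0, seed: int = 0,
                        with_local: bool = True) -> MotionGroundTruth:
    """Random smooth drift (total path <= total_drift px) + local polynomial.

    Local motion uses the gauge-free monomials x*t, y*t, x*y*t (see module
    docstring), scaled so the maximum local displacement is ~max_local px.
    """
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0, 2 * np.pi)
    mag = total_drift * rng.uniform(0.6, 1.0)
    u = np.linspace(0.0, 1.0, n_frames)
    curve = rng.uniform(-0.3, 0.3)
    path = np.stack([
        mag * np.cos(angle) * (u + curve * u ** 2) / (1 + curve),
        mag * np.sin(angle) * (u + curve * u ** 2) / (1 + curve),
    ], axis=1)
    cx = cy = None
    if with_local:
        exps = poly.TRIVARIATE_EXPONENTS
        active = [exps.index(e) for e in ((1, 0, 1), (0, 1, 1), (1, 1, 1))]
        cx = np.zeros(len(exps))
        cy = np.zeros(len(exps))
        amp = rng.uniform(-1.0, 1.0, size=(2, 3))
        amp *= max_local / max(np.abs(amp).sum(axis=1).max(), 1e-9)
        cx[active] = amp[0]
        cy[active] = amp[1]
    return MotionGroundTruth(global_shifts=path, local_coeffs_x=cx,
                             local_coeffs_y=cy, seed=seed)


# ---------------------------------------------------------------------------
# Scene and movie generation
# ---------------------------------------------------------------------------


def blob_scene(dims: tuple[int, int], seed: int = 0,
               density: float = 1 / 4000.0) -> np.ndarray:
    """Fixed structured scene: a seeded mixture of Gaussian blobs."""
    rng = np.random.default_rng(seed)
    ny, nx = dims
    scene = np.zeros((ny, nx))
    n_blobs = max(int(ny * nx * density), 10)
    xs = rng.uniform(0, nx, n_blobs)
    ys = rng.uniform(0, ny, n_blobs)
    sigmas = rng.uniform(2.0, 6.0, n_blobs)
    amps = rng.uniform(0.5, 1.5, n_blobs) * rng.choice([-1, 1], n_blobs)
    for x0, y0, s, a in zip(xs, ys, sigmas, amps):
        r = int(np.ceil(4 * s))
        xi0, xi1 = max(int(x0) - r, 0), min(int(x0) + r + 1, nx)
        yi0, yi1 = max(int(y0) - r, 0), min(int(y0) + r + 1, ny)
        yy, xx = np.mgrid[yi0:yi1, xi0:xi1]
        scene[yi0:yi1, xi0:xi1] += a * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s ** 2))
    return scene


def make_movie(truth: MotionGroundTruth, dims: tuple[int, int] = (1024, 1024),
               snr: float | None = 0.5, seed: int = 0,
               pixel_size: float = 1.0,
               dose_per_frame: float | None = 1.0) -> MovieStack:
    """Render a movie: the blob scene displaced per frame by the planted
    global + local motion, plus white Gaussian noise at the requested SNR.
    """
    ny, nx = dims
    if min(dims) < 256:
        raise ValueError("movie dimensions must be at least 256x256")
    n_frames = truth.global_shifts.shape[0]
    rng = np.random.default_rng(seed)
    scene = blob_scene(dims, seed=seed)
    prefiltered = ndimage.spline_filter(scene, order=3)
    Y, X = np.mgrid[0:ny, 0:nx].astype(np.float64)
    xn = poly.normalize_coords(X, nx - 1)
    yn = poly.normalize_coords(Y, ny - 1)
    frames = np.empty((n_frames, ny, nx))
    sig_var = scene.var()
    noise_std = 0.0
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        noise_std = np.sqrt(sig_var / snr)
    for t in range(n_frames):
        tn = poly.normalize_coords(float(t), n_frames - 1)
        s = truth.local_shift(xn, yn, np.full_like(xn, tn))
        sx = s[..., 0] + truth.global_shifts[t, 0]
        sy = s[..., 1] + truth.global_shifts[t, 1]
        # frame(x) = scene(x - shift): content displaced by the planted shift
        frames[t] = ndimage.map_coordinates(prefiltered, [Y - sy, X - sx],
                                            order=3, prefilter=False,
                                            mode="grid-wrap")
        if noise_std > 0:
            frames[t] += rng.normal(0.0, noise_std, (ny, nx))
    return MovieStack(frames=frames, pixel_size=pixel_size,
                      dose_per_frame=dose_per_frame)


# ---------------------------------------------------------------------------
# CTF fixtures
# ---------------------------------------------------------------------------


def _ctf_filter_noise(noise: np.ndarray, params: CtfParams) -> np.ndarray:
    ny, nx = noise.shape
    fy = np.fft.fftfreq(ny, d=params.pixel_size)[:, None]
    fx = np.fft.fftfreq(nx, d=params.pixel_size)[None, :]
    g = np.hypot(fx, fy)
    theta = np.arctan2(np.broadcast_to(fy, (ny, nx)),
                       np.broadcast_to(fx, (ny, nx)))
    H = np.abs(ctf_eval(params, g, theta))
    return np.fft.ifft2(np.fft.fft2(noise) * H).real


def make_ctf_micrograph(truth: CtfGroundTruth, dims: tuple[int, int] = (2048, 2048),
                        snr: float | None = None, seed: int = 0,
                        block: int = 512) -> np.ndarray:
    """White Gaussian noise filtered in Fourier space by |CTF|.

    With a defocus field present the image is synthesized block-wise, each
    block filtered with the local CTF at its center, so tile power spectra
    show Thon rings at the locally planted defoci.
    """
    rng = np.random.default_rng(seed)
    ny, nx = dims
    noise = rng.normal(size=(ny, nx))
    from dataclasses import replace
    if truth.field_dfx is None:
        out = _ctf_filter_noise(noise, truth.base)
    else:
        out = np.empty((ny, nx))
        for y0 in range(0, ny, block):
            for x0 in range(0, nx, block):
                y1, x1 = min(y0 + block, ny), min(x0 + block, nx)
                cx = poly.normalize_coords((x0 + x1 - 1) / 2.0, nx - 1)
                cy = poly.normalize_coords((y0 + y1 - 1) / 2.0, ny - 1)
                dfx, dfy = truth.local_defocus(cx, cy)
                p = replace(truth.base, dfx=dfx, dfy=dfy)
                out[y0:y1, x0:x1] = _ctf_filter_noise(noise[y0:y1, x0:x1], p)
    out /= out.std()
    if snr is not None and np.isfinite(snr):
        out += rng.normal(0.0, np.sqrt(1.0 / snr), size=(ny, nx))
    return out


# ---------------------------------------------------------------------------
# Picking fixtures
# ---------------------------------------------------------------------------


def particle_reference(box: int = 48, seed: int = 7) -> np.ndarray:
    """Asymmetric multi-lobe particle template in a box (zero background)."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:box, 0:box].astype(float)
    c = (box - 1) / 2.0
    ref = np.zeros((box, box))
    for _ in range(4):
        dx, dy = rng.uniform(-box / 6, box / 6, 2)
        s = rng.uniform(box / 12, box / 7)
        a = rng.uniform(0.6, 1.2)
        ref += a * np.exp(-((xx - c - dx) ** 2 + (yy - c - dy) ** 2)
                          / (2 * s ** 2))
    # soft circular support
    r = np.hypot(xx - c, yy - c)
    ref *= np.clip((box / 2.0 - 2 - r) / 3.0, 0.0, 1.0)
    return ref


def shape_templates(box: int = 48, smooth: float = 1.5) -> list[np.ndarray]:
    """Four geometrically distinct view templates (disk, ring, bar, wedge).

    Deliberately dissimilar, emulating well-separated projection views for
    classification fixtures; each is softly low-passed.
    """
    yy, xx = np.mgrid[0:box, 0:box].astype(float)
    c = (box - 1) / 2.0
    r = np.hypot(xx - c, yy - c)
    shapes = [
        (r < box / 6).astype(float),
        ((r > box / 4.8) & (r < box / 3.2)).astype(float),
        ((np.abs(xx - c) < box / 3) & (np.abs(yy - c) < box / 12)).astype(float),
        ((yy - c > -box / 4.8) & (yy - c < 2 * (xx - c) + box / 6)
         & (yy - c < -2 * (xx - c) + box / 6)).astype(float),
    ]
    return [ndimage.gaussian_filter(s, smooth) for s in shapes]


def make_classification_chunk(n: int = 200, box: int = 48, snr: float = 0.5,
                              seed: int = 0, max_shift: int = 3):
    """Rotated/shifted noisy copies of the four shape templates.

    Returns (stack, truth labels, templates).
    """
    rng = np.random.default_rng(seed)
    templates = shape_templates(box)
    labels = rng.integers(0, len(templates), size=n)
    chunk = np.empty((n, box, box))
    for i in range(n):
        t = templates[labels[i]]
        img = ndimage.rotate(t, rng.uniform(0, 360), reshape=False, order=1)
        img = np.roll(img, rng.integers(-max_shift, max_shift + 1, 2),
                      axis=(0, 1))
        chunk[i] = img + rng.normal(0, np.sqrt(t.var() / snr), (box, box))
    return chunk, labels, templates


def plant_particles(background: np.ndarray, reference: np.ndarray,
                    coords, amplitude: float = 1.0):
    """Add the reference at each (x, y) box-center coordinate.

    Coordinates must lie at least one box size from the image edges and be
    pairwise separated by more than the box size. Returns (image, coords).
    """
    background = np.asarray(background, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    box = reference.shape[0]
    ny, nx = background.shape
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    for x, y in coords:
        if not (box <= x <= nx - 1 - box and box <= y <= ny - 1 - box):
            raise ValueError(f"coordinate ({x}, {y}) closer than one box "
                             "size to the edge")
    if len(coords) > 1:
        d = np.hypot(*(coords[:, None, :] - coords[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        if d.min() <= box:
            raise ValueError("planted coordinates overlap (separation <= box)")
    out = background.copy()
    half = box // 2
    for x, y in coords:
        xi, yi = int(round(x)), int(round(y))
        out[yi - half:yi - half + box, xi - half:xi - half + box] \
            += amplitude * reference
    return out, coords


def make_picking_micrograph(n_particles: int = 30,
                            dims: tuple[int, int] = (1024, 1024),
                            snr: float = 0.3, seed: int = 0, box: int = 48,
                            min_separation: float | None = None):
    """Noise micrograph with planted particles at random valid coordinates.

    Returns (micrograph, truth coords, reference). SNR is the planted-signal
    variance over the noise variance.
    """
    rng = np.random.default_rng(seed)
    ny, nx = dims
    ref = particle_reference(box=box, seed=7)
    sep = float(min_separation if min_separation is not None else box + 2)
    coords: list[tuple[float, float]] = []
    attempts = 0
    while len(coords) < n_particles and attempts < 20000:
        attempts += 1
        x = rng.uniform(box + 1, nx - box - 2)
        y = rng.uniform(box + 1, ny - box - 2)
        if all(np.hypot(x - cx, y - cy) > sep for cx, cy in coords):
            coords.append((x, y))
    if len(coords) < n_particles:
        raise ValueError("could not place the requested number of particles")
    clean = np.zeros((ny, nx))
    clean, coords = plant_particles(clean, ref, coords)
    noise_std = np.sqrt(clean.var() / snr)
    micrograph = clean + rng.normal(0.0, noise_std, (ny, nx))
    return micrograph, np.asarray(coords), ref


# ---------------------------------------------------------------------------
# EPU session fixtures
# ---------------------------------------------------------------------------

_EPU_XML = """<?xml version="1.0" encoding="utf-8"?>
<MicroscopeImage xmlns="http://schemas.datacontract.org/2004/07/Fei.SharedObjects">
  <microscopeData>
    <optics>
      <BeamShift xmlns:a="http://schemas.datacontract.org/2004/07/Fei.Types">
        <a:_x>{x:.8f}</a:_x>
        <a:_y>{y:.8f}</a:_y>
      </BeamShift>
    </optics>
  </microscopeData>
</MicroscopeImage>
"""


def make_epu_session(out_dir, n_clusters: int = 4, shots_per_hole: int = 2,
                     movies_per_cluster: int = 20, spread: float = 0.01,
                     seed: int = 0):
    """Synthetic EPU session: clustered beam shifts + shot-encoding filenames.

    Beam shifts are drawn from ``n_clusters`` well-separated Gaussian centers
    (unit inter-center distance, standard deviation ``spread``); filenames
    follow the FoilHole_<hole>_Data_<id1>_<id2>_... pattern with the Data
    identifiers encoding the shot position (1..shots_per_hole) within the
    hole template. Returns a list of (xml_path, movie_filename,
    (cluster, shot)) tuples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n_clusters) / max(n_clusters, 1)
    radius = 0.0 if n_clusters == 1 else 0.5 / np.sin(np.pi / n_clusters)
    centers = np.stack([radius * np.cos(angles), radius * np.sin(angles)],
                       axis=1)
    session = []
    for c in range(n_clusters):
        for m in range(movies_per_cluster):
            shot = m % shots_per_hole + 1
            hole = c * movies_per_cluster + m // shots_per_hole + 1
            sx, sy = centers[c] + rng.normal(0.0, spread, 2) if spread > 0 \
                else centers[c]
            name = (f"FoilHole_{hole:07d}_Data_{1000 + shot}_{2000 + shot}"
                    f"_20200101_{c:02d}{m:04d}")
            xml_path = out_dir / f"{name}.xml"
            xml_path.write_text(_EPU_XML.format(x=sx, y=sy))
            session.append((xml_path, f"{name}.mrc", (c, shot)))
    return session


# ---------------------------------------------------------------------------
# Class-metric fixtures
# ---------------------------------------------------------------------------


def make_class_metrics(n_classes: int = 20, n_bad: int = 2, seed: int = 0,
                       box: int = 128, pixel_size: float = 1.3):
    """Class-quality metrics with ``n_bad`` planted low-quality classes.

    Good classes are drawn near (high spectral index g, high correlation cc);
    bad ones are planted three good-population standard deviations below
    both means, which leaves them >1.5 pooled standard deviations below the
    pooled means for modest n_bad. Returns (metrics, truth bad-class ids).
    """
    if n_bad >= n_classes:
        raise ValueError("n_bad must be smaller than n_classes")
    rng = np.random.default_rng(seed)
    mu_g, sd_g = 18.0, 1.5
    mu_cc, sd_cc = 0.60, 0.04
    metrics = []
    bad_ids = set(rng.choice(n_classes, size=n_bad, replace=False).tolist())
    for i in range(n_classes):
        if i in bad_ids:
            g = mu_g - 3.0 * sd_g + rng.normal(0, 0.2)
            cc = mu_cc - 3.0 * sd_cc + rng.normal(0, 0.005)
        else:
            g = rng.normal(mu_g, sd_g)
            cc = rng.normal(mu_cc, sd_cc)
        g_index = max(int(round(g)), 1)
        res = box * pixel_size / g_index
        metrics.append(ClassMetrics(class_id=i, res=res, g_index=g_index,
                                    cc=float(cc),
                                    n_members=int(rng.integers(50, 200))))
    return metrics, sorted(bad_ids)
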