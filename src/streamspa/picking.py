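"""Template-based particle identification and extraction.

One locally normalized correlation map is computed per (rotationally
augmented) reference via Fourier-domain convolutions; the maps are fused by
pixelwise maximum, segmented into peak/non-peak regions by a two-dimensional
Otsu threshold on the joint (value, 3x3 neighborhood mean) histogram, and
peaks are read per connected component. A greedy distance filter keeps only
the highest peak of any pair closer than ``dist_factor * particle_radius``
(default 2.7x), and statistical outlier rejection on window statistics
(standard deviation, mean power-spectral value, dynamic range) discards
residual false positives such as contamination. Extracted particles are
normalized by the mean and standard deviation of the background annulus
outside the particle radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class PickConfig:
    particle_radius: float = 24.0
    box_size: int = 64
    dist_factor: float = 2.7
    outlier_sigma: float = 3.0
    rotation_step: float | None = 10.0   # degrees; None disables augmentation

    def __post_init__(self) -> None:
        if self.box_size <= 2 * self.particle_radius:
            raise ValueError("box_size must exceed the particle diameter")
        if self.dist_factor <= 0:
            raise ValueError("dist_factor must be positive")

    @property
    def min_distance(self) -> float:
        return self.dist_factor * self.particle_radius


@dataclass
class PickedParticle:
    x: float
    y: float
    score: float
    stats: tuple[float, float, float] | None = None  # (std, spec mean, range)
    accepted: bool = True
    reject_reason: str = "none"    # none | distance | outlier | edge

    def __post_init__(self) -> None:
        if self.accepted and self.reject_reason != "none":
            raise ValueError("accepted particle cannot carry a reject reason")


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------


def _padded_fft_kernel(kernel: np.ndarray, shape: tuple[int, int]):
    """FFT of the kernel centered at the origin of a shape-sized array."""
    ny, nx = shape
    ky, kx = kernel.shape
    big = np.zeros(shape)
    big[:ky, :kx] = kernel
    # center the kernel on (0, 0) so correlation peaks land on box centers
    big = np.roll(big, (-(ky // 2), -(kx // 2)), axis=(0, 1))
    return np.fft.fft2(big)


def local_correlation(micrograph: np.ndarray, reference: np.ndarray,
                      mask_radius: float | None = None,
                      _micrograph_ffts=None) -> np.ndarray:
    """Locally normalized cross-correlation map.

    The correlation at each position is normalized by the mean and variance
    of the micrograph under a circular mask of ``mask_radius`` (default:
    half the reference box) carried along with the reference, computed with
    FFT convolutions; values lie in [-1, 1] up to numerical error.
    """
    micrograph = np.asarray(micrograph, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape[0] > micrograph.shape[0] or \
            reference.shape[1] > micrograph.shape[1]:
        raise ValueError("reference larger than micrograph")
    box = reference.shape[0]
    if mask_radius is None:
        mask_radius = box / 2.0 - 1.0
    yy, xx = np.mgrid[0:box, 0:reference.shape[1]].astype(float)
    c = (box - 1) / 2.0
    mask = (np.hypot(xx - c, yy - c) <= mask_radius).astype(float)
    n_mask = mask.sum()
    t = reference * mask
    t = t - mask * (t.sum() / n_mask)
    t_norm = np.sqrt((t ** 2).sum())
    if t_norm < 1e-12:
        raise ValueError("reference has zero variance under the mask")
    t /= t_norm

    shape = micrograph.shape
    if _micrograph_ffts is None:
        F = np.fft.fft2(micrograph)
        F2 = np.fft.fft2(micrograph ** 2)
    else:
        F, F2 = _micrograph_ffts
    # correlation kernels must be flipped for convolution-style FFT products
    K_t = np.conj(_padded_fft_kernel(t, shape))
    K_m = np.conj(_padded_fft_kernel(mask, shape))
    num = np.fft.ifft2(F * K_t).real
    local_sum = np.fft.ifft2(F * K_m).real
    local_sum2 = np.fft.ifft2(F2 * K_m).real
    local_var = np.maximum(local_sum2 - local_sum ** 2 / n_mask, 0.0)
    denom = np.sqrt(local_var)
    out = np.where(denom > 1e-9 * max(denom.max(), 1e-30), num / (denom + 1e-300), 0.0)
    return out


def micrograph_ffts(micrograph: np.ndarray):
    """Precompute the FFTs reused across references/rotations."""
    m = np.asarray(micrograph, dtype=np.float64)
    return np.fft.fft2(m), np.fft.fft2(m ** 2)


def augment_rotations(reference: np.ndarray, step: float | None):
    """In-plane rotated copies of a reference at ``step``-degree intervals."""
    if step is None:
        return [reference]
    return [ndimage.rotate(reference, ang, reshape=False, order=1)
            for ang in np.arange(0.0, 360.0, step)]


def combine_maps(maps) -> np.ndarray:
    """Pixelwise maximum over all correlation images."""
    maps = list(maps)
    if len(maps) == 0:
        raise ValueError("no correlation maps to combine")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("correlation maps differ in shape")
    return np.maximum.reduce(maps)


# ---------------------------------------------------------------------------
# Segmentation and peak detection
# ---------------------------------------------------------------------------


def segment_otsu2d(cmap: np.ndarray, bins: int = 64) -> np.ndarray:
    """Two-dimensional Otsu segmentation of the correlation map.

    The threshold pair (on pixel value and on 3x3 neighborhood mean) is
    chosen to maximize the between-class variance of the joint histogram's
    diagonal quadrants; the mask is true on the jointly-above (peak) class.
    """
    cmap = np.asarray(cmap, dtype=np.float64)
    lo, hi = cmap.min(), cmap.max()
    if hi - lo < 1e-12:
        warnings.warn("constant correlation map; empty segmentation")
        return np.zeros(cmap.shape, dtype=bool)
    smooth = ndimage.uniform_filter(cmap, size=3, mode="nearest")
    v = np.clip(((cmap - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    s = np.clip(((smooth - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    H = np.zeros((bins, bins))
    np.add.at(H, (v.ravel(), s.ravel()), 1.0)
    P = H / H.sum()
    vi = np.arange(bins, dtype=float)
    # cumulative mass and first moments over the [0..i, 0..j] rectangle
    W = P.cumsum(axis=0).cumsum(axis=1)
    Mx = (P * vi[:, None]).cumsum(axis=0).cumsum(axis=1)
    My = (P * vi[None, :]).cumsum(axis=0).cumsum(axis=1)
    mu_tx, mu_ty = Mx[-1, -1], My[-1, -1]
    # class 0 = below both thresholds (the rectangle); class 1 = above both,
    # by inclusion-exclusion: 1 - P(v<=i) - P(s<=j) + P(rect)
    w0 = W
    w1 = 1.0 - W[:, -1:] - W[-1:, :] + W
    m1x = mu_tx - Mx[:, -1:] - Mx[-1:, :] + Mx
    m1y = mu_ty - My[:, -1:] - My[-1:, :] + My
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0x, mu0y = Mx / w0, My / w0
        mu1x, mu1y = m1x / w1, m1y / w1
        sigma_b = (w0 * ((mu0x - mu_tx) ** 2 + (mu0y - mu_ty) ** 2)
                   + w1 * ((mu1x - mu_tx) ** 2 + (mu1y - mu_ty) ** 2))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    sigma_b[w0 <= 0] = -np.inf
    sigma_b[w1 <= 0] = -np.inf
    i, j = np.unravel_index(np.argmax(sigma_b), sigma_b.shape)
    return (v > i) & (s > j)


def detect_and_filter_peaks(cmap: np.ndarray, mask: np.ndarray,
                            cfg: PickConfig) -> list[PickedParticle]:
    """Per-component peak extraction followed by greedy distance filtering.

    Candidates are the per-connected-component maxima of the map within the
    mask, processed in descending score order; a candidate survives iff no
    already-kept peak lies within ``cfg.min_distance``. The returned list is
    sorted by score (kept peaks first, then distance-rejected ones).
    """
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return []
    positions = ndimage.maximum_position(cmap, labels,
                                         index=np.arange(1, n_comp + 1))
    if n_comp == 1:
        positions = [positions]
    cands = [(float(cmap[y, x]), float(x), float(y)) for (y, x) in positions]
    cands.sort(reverse=True)
    kept: list[PickedParticle] = []
    rejected: list[PickedParticle] = []
    for score, x, y in cands:
        if any(np.hypot(x - k.x, y - k.y) < cfg.min_distance for k in kept):
            rejected.append(PickedParticle(x, y, score, accepted=False,
                                           reject_reason="distance"))
        else:
            kept.append(PickedParticle(x, y, score))
    return kept + rejected


# ---------------------------------------------------------------------------
# Outlier rejection and extraction
# ---------------------------------------------------------------------------


def _window_stats(window: np.ndarray) -> tuple[float, float, float]:
    spec = np.abs(np.fft.fft2(window - window.mean())) ** 2
    spec_mean = (spec.sum() - spec[0, 0]) / (spec.size - 1)
    return (float(window.std()), float(spec_mean),
            float(window.max() - window.min()))


def _robust_z(values: np.ndarray) -> np.ndarray:
    # MAD-based z with the scale floored at 2% of the median magnitude:
    # for near-homogeneous populations a vanishing MAD would otherwise turn
    # ordinary members into formal outliers
    med = np.median(values)
    scale = max(np.median(np.abs(values - med)) * 1.4826, 0.02 * abs(med))
    if scale < 1e-30:
        return np.zeros_like(values)
    return (values - med) / scale


def reject_outliers(micrograph: np.ndarray, peaks: list[PickedParticle],
                    cfg: PickConfig) -> list[PickedParticle]:
    """Flag peaks whose window statistics are robust-z outliers.

    Statistics (window standard deviation, mean power-spectral value
    excluding the zero frequency, dynamic pixel range) are compared to the
    population median; any statistic deviating by more than
    ``cfg.outlier_sigma`` robust standard deviations (median/MAD) rejects
    the peak. Windows crossing the image edge are dropped outright.
    """
    ny, nx = micrograph.shape
    half = cfg.box_size // 2
    valid: list[PickedParticle] = []
    out: list[PickedParticle] = []
    windows = []
    for p in peaks:
        if not p.accepted:
            out.append(p)
            continue
        xi, yi = int(round(p.x)), int(round(p.y))
        if not (half <= xi <= nx - half - 1 and half <= yi <= ny - half - 1):
            out.append(PickedParticle(p.x, p.y, p.score, accepted=False,
                                      reject_reason="edge"))
            continue
        w = micrograph[yi - half:yi - half + cfg.box_size,
                       xi - half:xi - half + cfg.box_size]
        windows.append(_window_stats(w))
        valid.append(p)
    if len(valid) < 5:
        if valid:
            warnings.warn("fewer than 5 peaks; skipping outlier rejection")
        for p, st in zip(valid, windows):
            p.stats = st
            out.append(p)
        return out
    stats = np.asarray(windows)
    z = np.column_stack([_robust_z(stats[:, k]) for k in range(3)])
    for p, st, zrow in zip(valid, windows, z):
        if np.any(np.abs(zrow) > cfg.outlier_sigma):
            out.append(PickedParticle(p.x, p.y, p.score, stats=st,
                                      accepted=False, reject_reason="outlier"))
        else:
            p.stats = st
            out.append(p)
    return out


def extract_particles(micrograph: np.ndarray, peaks: list[PickedParticle],
                      cfg: PickConfig, invert_contrast: bool = False):
    """Extract box windows around accepted peaks, background-normalized.

    Each window is normalized by subtracting the mean and dividing by the
    standard deviation of the pixels outside the particle radius (the
    background annulus). Returns an (n, box, box) stack.
    """
    ny, nx = micrograph.shape
    half = cfg.box_size // 2
    b = cfg.box_size
    yy, xx = np.mgrid[0:b, 0:b].astype(float)
    c = (b - 1) / 2.0
    bg_mask = np.hypot(xx - c, yy - c) > cfg.particle_radius
    stack = []
    for p in peaks:
        if not p.accepted:
            continue
        xi, yi = int(round(p.x)), int(round(p.y))
        if not (half <= xi <= nx - half - 1 and half <= yi <= ny - half - 1):
            continue
        w = micrograph[yi - half:yi - half + b, xi - half:xi - half + b].copy()
        bg = w[bg_mask]
        w = (w - bg.mean()) / (bg.std() + 1e-300)
        if invert_contrast:
            w = -w
        stack.append(w)
    return np.array(stack) if stack else np.empty((0, b, b))


def pick_particles(micrograph: np.ndarray, references, cfg: PickConfig):
    """Full picking chain; returns (all peaks, accepted extracted stack)."""
    if np.ndim(references) == 2:
        references = [np.asarray(references)]
    ffts = micrograph_ffts(micrograph)
    maps = []
    for ref in references:
        for rot in augment_rotations(ref, cfg.rotation_step):
            maps.append(local_correlation(micrograph, rot,
                                          mask_radius=cfg.particle_radius,
                                          _micrograph_ffts=ffts))
    cmap = combine_maps(maps)
    mask = segment_otsu2d(cmap)
    peaks = detect_and_filter_peaks(cmap, mask, cfg)
    peaks = reject_outliers(micrograph, peaks, cfg)
    stack = extract_particles(micrograph, peaks, cfg)
    return peaks, stack
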