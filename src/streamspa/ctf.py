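"""Per-micrograph and patch-based anisotropic CTF estimation.

The contrast transfer function follows the CTFFIND4 model,

    CTF(g, theta) = -sin(chi),
    chi = pi*lambda*g^2*df(theta) - (pi/2)*lambda^3*g^4*Cs + dphi + A,

with the astigmatic defocus df(theta) = (dfx + dfy)/2 +
(dfx - dfy)/2 * cos(2*(theta - ang_ast)) and the amplitude-contrast phase
A = atan(w / sqrt(1 - w^2)). Underfocus is positive; defocus is carried in
micrometres, converted to Angstrom only inside the phase function.

Per-micrograph estimation proceeds in three steps: (1) a uniform 1D defocus
grid search against the rotationally averaged spectrum, (2) stochastic
(Differential Evolution) maximization of the 2D correlation over the
astigmatism angle (and optionally the phase-plate shift) with the defoci
restrained to +/-0.1 um of the 1D estimate, (3) bounded quasi-Newton
(L-BFGS-B) refinement of the defoci with analytic gradients of the score

    f = cc + f_pen,    f_pen = -(1/(2N)) * ((dfx - dfy)/ddf_tol)^2,

where cc is the normalized correlation between the background-subtracted
power spectrum and CTF^2 within a 30-5 A annulus and N the number of
frequency samples scored. The fit quality is summarized by f and by the
highest resolution at which a rolling-window radial correlation stays
above CC_fit = 0.75.

The anisotropic model evaluates local defocus anywhere on the micrograph:
a square grid with 512-px spacing is laid over the exposed area, each grid
point receives a Gaussian distance-weighted average of the nearest tile
spectra, the defoci are refit per point (astigmatism angle held fixed), and
two 2D 3rd-order polynomials over normalized (x, y) are least-squares
fitted to the per-point defoci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import differential_evolution, minimize

from streamspa import poly


@dataclass
class CtfParams:
    """Microscope constants and per-image CTF parameters.

    dfx/dfy in um (underfocus positive), ang_ast in degrees from the image
    x-axis (modulo 180), phshift in radians, amp_contrast as a fraction,
    cs in mm, pixel_size in A/px.
    """

    dfx: float = 1.0
    dfy: float = 1.0
    ang_ast: float = 0.0
    phshift: float = 0.0
    amp_contrast: float = 0.07
    cs: float = 2.7
    voltage_kV: float = 300.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amp_contrast < 1.0):
            raise ValueError("amp_contrast must be in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        v = self.voltage_kV * 1e3
        return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass
class PowerSpectrum2d:
    """Background-subtracted, cross-dampened average tile power spectrum.

    ``values`` is square with the zero frequency at the center
    (tile_size // 2, tile_size // 2).
    """

    values: np.ndarray
    pixel_size: float
    tile_size: int
    n_tiles: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("spectrum must be square")
        self.values = v

    def freq_grids(self):
        """(g magnitude A^-1, theta radians) on the centered grid."""
        n = self.tile_size
        f = np.fft.fftshift(np.fft.fftfreq(n)) / self.pixel_size
        gy, gx = np.meshgrid(f, f, indexing="ij")
        return np.hypot(gx, gy), np.arctan2(gy, gx)

    def radial_average(self):
        """(g bin centers A^-1, mean spectrum per integer-radius shell)."""
        n = self.tile_size
        c = n // 2
        Y, X = np.mgrid[0:n, 0:n]
        r = np.hypot(X - c, Y - c).astype(int)
        nshell = n // 2
        sums = np.bincount(r.ravel(), self.values.ravel(), minlength=nshell)
        cnts = np.bincount(r.ravel(), minlength=nshell)
        prof = sums[:nshell] / np.maximum(cnts[:nshell], 1)
        g = np.arange(nshell) / (n * self.pixel_size)
        return g, prof


@dataclass
class CtfFitResult:
    params: CtfParams
    cc: float
    score_f: float
    fit_resolution: float
    n_freq: int
    low_confidence: bool = False


@dataclass
class AnisoCtfModel:
    """Two 2D 3rd-order defocus polynomials over normalized (x, y)."""

    poly_dfx: np.ndarray
    poly_dfy: np.ndarray
    ang_ast: float
    phshift: float
    base: CtfParams
    dims: tuple[int, int]
    grid: list = field(default_factory=list)   # [(center_xy, CtfFitResult)]


# ---------------------------------------------------------------------------
# CTF model
# ---------------------------------------------------------------------------


def _chi(params: CtfParams, g, theta):
    """Phase function chi(g, theta); g in A^-1, defocus converted um -> A."""
    lam = params.wavelength
    ang = np.radians(params.ang_ast)
    df = 0.5 * ((params.dfx + params.dfy)
                + (params.dfx - params.dfy) * np.cos(2.0 * (theta - ang))) * 1e4
    amp_phase = np.arctan(params.amp_contrast
                          / np.sqrt(1.0 - params.amp_contrast ** 2))
    return (np.pi * lam * g ** 2 * df
            - 0.5 * np.pi * lam ** 3 * g ** 4 * (params.cs * 1e7)
            + params.phshift + amp_phase)


def ctf_eval(params: CtfParams, g, theta=0.0):
    """CTF(g, theta) = -sin(chi); g in A^-1, theta in radians."""
    return -np.sin(_chi(params, np.asarray(g, float), theta))


def canonical_astigmatism(params: CtfParams) -> CtfParams:
    """Resolve the (dfx, dfy, ang) <-> (dfy, dfx, ang+90) degeneracy.

    Returns the equivalent parameter set with dfx >= dfy and the angle in
    [0, 180); use before comparing fitted astigmatism to a reference.
    """
    dfx, dfy, ang = params.dfx, params.dfy, params.ang_ast % 180.0
    if dfx < dfy:
        dfx, dfy, ang = dfy, dfx, (ang + 90.0) % 180.0
    return replace(params, dfx=dfx, dfy=dfy, ang_ast=ang)


# ---------------------------------------------------------------------------
# Power spectrum
# ---------------------------------------------------------------------------


def tile_positions(dim: int, tile_size: int, overlap: float) -> np.ndarray:
    step = int(round(tile_size * (1.0 - overlap)))
    if step <= 0:
        raise ValueError("overlap too large")
    n = (dim - tile_size) // step + 1
    return np.arange(n) * step


def iter_tiles(shape: tuple[int, int], tile_size: int, overlap: float):
    """Yield (y0, x0) top-left corners of the overlapping tile grid."""
    ys = tile_positions(shape[0], tile_size, overlap)
    xs = tile_positions(shape[1], tile_size, overlap)
    for y0 in ys:
        for x0 in xs:
            yield int(y0), int(x0)


def _postprocess_spectrum(avg: np.ndarray, tile_size: int, pixel_size: float,
                          bg_resolution: float = 40.0) -> np.ndarray:
    """Background subtraction (Gaussian low-pass estimate) + cross dampening."""
    sigma = tile_size * pixel_size / bg_resolution  # 1/(40 A) kernel width
    background = ndimage.gaussian_filter(avg, sigma=max(sigma, 1.0),
                                         mode="nearest")
    out = avg - background
    c = tile_size // 2
    out[c - 1:c + 2, :] = 0.0
    out[:, c - 1:c + 2] = 0.0
    return out


def compute_spectrum(micrograph: np.ndarray, pixel_size: float,
                     tile_size: int = 512,
                     overlap: float = 0.5) -> PowerSpectrum2d:
    """Average power spectrum of overlapping square tiles."""
    micrograph = np.asarray(micrograph, dtype=np.float64)
    if min(micrograph.shape) < tile_size:
        raise ValueError("micrograph smaller than the spectral tile size")
    avg = np.zeros((tile_size, tile_size))
    n_tiles = 0
    for y0, x0 in iter_tiles(micrograph.shape, tile_size, overlap):
        tile = micrograph[y0:y0 + tile_size, x0:x0 + tile_size]
        tile = tile - tile.mean()
        avg += np.abs(np.fft.fftshift(np.fft.fft2(tile))) ** 2
        n_tiles += 1
    avg /= n_tiles * tile_size ** 2
    values = _postprocess_spectrum(avg, tile_size, pixel_size)
    return PowerSpectrum2d(values=values, pixel_size=pixel_size,
                           tile_size=tile_size, n_tiles=n_tiles)


# ---------------------------------------------------------------------------
# Scoring (Eq. 4 / Eq. 5 conventions)
# ---------------------------------------------------------------------------


def _annulus_mask(spectrum: PowerSpectrum2d, res_range=(30.0, 5.0)):
    g, theta = spectrum.freq_grids()
    g_lo, g_hi = 1.0 / res_range[0], 1.0 / res_range[1]
    nyquist = 0.5 / spectrum.pixel_size
    if g_lo >= nyquist:
        raise ValueError("resolution range outside Nyquist")
    g_hi = min(g_hi, nyquist)
    mask = (g >= g_lo) & (g <= g_hi)
    if not mask.any():
        raise ValueError("empty scoring annulus")
    return mask, g[mask], theta[mask]


def score_cc(spectrum: PowerSpectrum2d, params: CtfParams,
             res_range=(30.0, 5.0)) -> float:
    """Normalized correlation of the spectrum with CTF^2 over the annulus."""
    mask, g, theta = _annulus_mask(spectrum, res_range)
    F = spectrum.values[mask]
    C = ctf_eval(params, g, theta) ** 2
    denom = np.sqrt((F ** 2).sum() * (C ** 2).sum())
    if denom == 0:
        return 0.0
    return float((F * C).sum() / denom)


def _score_f_and_grad(F, g, theta, params: CtfParams, dftol: float):
    """Score f = cc + f_pen and its analytic gradient wrt (dfx, dfy)."""
    lam = params.wavelength
    ang = np.radians(params.ang_ast)
    cos2 = np.cos(2.0 * (theta - ang))
    chi = _chi(params, g, theta)
    ctf = -np.sin(chi)
    C = ctf ** 2
    SF2 = (F ** 2).sum()
    SC2 = (C ** 2).sum()
    SFC = (F * C).sum()
    denom = np.sqrt(SF2 * SC2) + 1e-300
    cc = SFC / denom
    # dC/ddf_eff, with chi linear in the effective defocus (A)
    dchi_ddfeff = np.pi * lam * g ** 2 * 1e4      # per um
    dC = 2.0 * ctf * (-np.cos(chi)) * dchi_ddfeff
    ddfeff_ddfx = 0.5 * (1.0 + cos2)
    ddfeff_ddfy = 0.5 * (1.0 - cos2)
    grads = []
    for ddf in (ddfeff_ddfx, ddfeff_ddfy):
        dCd = dC * ddf
        dSFC = (F * dCd).sum()
        dSC2 = 2.0 * (C * dCd).sum()
        grads.append(dSFC / denom - SFC * dSC2 / (2.0 * denom * SC2))
    N = F.size
    diff = params.dfx - params.dfy
    fpen = -0.5 / N * (diff / dftol) ** 2
    gpen = diff / (N * dftol ** 2)
    return (cc + fpen, np.array([grads[0] - gpen, grads[1] + gpen]),
            cc, fpen)


# ---------------------------------------------------------------------------
# Three-step per-micrograph estimation
# ---------------------------------------------------------------------------


def _shell_model(spectrum: PowerSpectrum2d, params: CtfParams) -> np.ndarray:
    """CTF^2 averaged over the same integer-radius shells as the spectrum.

    Shell averaging (over radius within the shell and over angle, so
    astigmatism is honored) matches how the radial spectrum profile smears
    the model oscillations near Nyquist.
    """
    n = spectrum.tile_size
    c = n // 2
    Y, X = np.mgrid[0:n, 0:n]
    r = np.hypot(X - c, Y - c).astype(int)
    g, theta = spectrum.freq_grids()
    C2 = ctf_eval(params, g, theta) ** 2
    nshell = n // 2
    sums = np.bincount(r.ravel(), C2.ravel(), minlength=nshell)
    cnts = np.bincount(r.ravel(), minlength=nshell)
    return sums[:nshell] / np.maximum(cnts[:nshell], 1)


def search_defocus_1d(spectrum: PowerSpectrum2d, base: CtfParams,
                      df_range=(0.3, 5.0), step: float = 0.01,
                      phase_plate: bool = False,
                      res_range=(30.0, 5.0), subsamples: int = 8):
    """Step 1: uniform defocus grid search on the rotationally averaged
    spectrum (astigmatism ignored; dphi = pi/2 in phase-plate mode).

    The model profile is averaged over ``subsamples`` radii per shell to
    match the shell-averaged experimental profile.

    Returns (defocus estimate um, correlation, low_confidence flag).
    """
    g, prof = spectrum.radial_average()
    g_lo, g_hi = 1.0 / res_range[0], min(1.0 / res_range[1],
                                         0.5 / spectrum.pixel_size)
    sel = (g >= g_lo) & (g <= g_hi)
    F = prof[sel]
    if F.std() < 1e-30:
        return float(np.mean(df_range)), 0.0, True
    shell_idx = np.where(sel)[0]
    n = spectrum.tile_size
    # sub-shell radii, averaged to emulate the shell binning of the profile
    sub = (shell_idx[:, None] + (np.arange(subsamples) + 0.5) / subsamples)
    g_sub = sub / (n * spectrum.pixel_size)
    phshift = np.pi / 2 if phase_plate else 0.0
    dfs = np.arange(df_range[0], df_range[1] + step / 2, step)
    best_df, best_cc = dfs[0], -np.inf
    norm_F = np.sqrt((F ** 2).sum())
    for df in dfs:
        p = replace(base, dfx=df, dfy=df, ang_ast=0.0, phshift=phshift)
        C = (ctf_eval(p, g_sub) ** 2).mean(axis=1)
        cc = (F * C).sum() / (norm_F * np.sqrt((C ** 2).sum()) + 1e-300)
        if cc > best_cc:
            best_df, best_cc = df, cc
    return float(best_df), float(best_cc), False


def refine_astigmatism(spectrum: PowerSpectrum2d, base: CtfParams,
                       init_df: float, restraint: float = 0.1,
                       fit_phase: bool = False, seed: int = 42,
                       res_range=(30.0, 5.0), maxiter: int = 40) -> CtfParams:
    """Step 2: Differential Evolution over the astigmatism angle (and
    optionally the phase shift), defoci restrained to init_df +/- restraint.
    """
    mask, g, theta = _annulus_mask(spectrum, res_range)
    F = spectrum.values[mask]
    normF = np.sqrt((F ** 2).sum()) + 1e-300

    def neg_cc(x):
        p = replace(base, dfx=x[0], dfy=x[1], ang_ast=x[2],
                    phshift=(x[3] if fit_phase else base.phshift))
        C = ctf_eval(p, g, theta) ** 2
        return -float((F * C).sum() / (normF * np.sqrt((C ** 2).sum())
                                       + 1e-300))

    bounds = [(max(init_df - restraint, 0.05), init_df + restraint)] * 2 \
        + [(0.0, 180.0)]
    if fit_phase:
        bounds.append((0.0, np.pi))
    try:
        res = differential_evolution(neg_cc, bounds, seed=seed,
                                     maxiter=maxiter, tol=1e-7, polish=True)
        x = res.x
    except Exception:
        warnings.warn("astigmatism search failed; keeping 1D defocus, "
                      "zero astigmatism")
        return replace(base, dfx=init_df, dfy=init_df, ang_ast=0.0)
    return replace(base, dfx=float(x[0]), dfy=float(x[1]),
                   ang_ast=float(x[2] % 180.0),
                   phshift=float(x[3]) if fit_phase else base.phshift)


def refine_defocus(spectrum: PowerSpectrum2d, params: CtfParams,
                   dftol: float = 0.05, res_range=(30.0, 5.0),
                   df_bound: float = 0.3) -> CtfFitResult:
    """Step 3: L-BFGS-B over (dfx, dfy) maximizing f = cc + f_pen with
    analytic gradients; the astigmatism angle and phase shift stay fixed.
    """
    mask, g, theta = _annulus_mask(spectrum, res_range)
    F = spectrum.values[mask]

    def objective(x):
        p = replace(params, dfx=x[0], dfy=x[1])
        f, grad, _, _ = _score_f_and_grad(F, g, theta, p, dftol)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite CTF score gradient")
        return -f, -grad

    x0 = np.array([params.dfx, params.dfy])
    bounds = [(max(x0[0] - df_bound, 0.05), x0[0] + df_bound),
              (max(x0[1] - df_bound, 0.05), x0[1] + df_bound)]
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-12})
    fitted = replace(params, dfx=float(res.x[0]), dfy=float(res.x[1]))
    f, _, cc, _ = _score_f_and_grad(F, g, theta, fitted, dftol)
    fres, flagged = fit_resolution(spectrum, fitted, res_range=res_range)
    return CtfFitResult(params=fitted, cc=float(cc), score_f=float(f),
                        fit_resolution=fres, n_freq=F.size,
                        low_confidence=flagged)


def fit_resolution(spectrum: PowerSpectrum2d, params: CtfParams,
                   cc_fit: float = 0.75, window: int = 11,
                   res_range=(30.0, 5.0)):
    """Highest resolution with a reasonable radial fit (CC_fit crossing).

    A rolling-window Pearson correlation between the radially averaged
    spectrum and the model CTF^2 is tracked from low to high frequency;
    the resolution of the last shell before it drops below ``cc_fit`` is
    returned. Returns (resolution A, flagged) where flagged means the fit
    never reached the threshold and the low-resolution bound was returned.
    """
    g, prof = spectrum.radial_average()
    sel = (g >= 1.0 / res_range[0]) & (g <= 0.5 / spectrum.pixel_size)
    gs, F = g[sel], prof[sel]
    C = _shell_model(spectrum, params)[sel]
    half = window // 2
    n = len(gs)
    if n < window:
        return res_range[0], True
    corr = np.full(n, np.nan)
    for i in range(half, n - half):
        a = F[i - half:i + half + 1]
        b = C[i - half:i + half + 1]
        sa, sb = a.std(), b.std()
        corr[i] = 0.0 if sa == 0 or sb == 0 else \
            float(np.corrcoef(a, b)[0, 1])
    good = corr[half:n - half] >= cc_fit
    if not good.any() or not good[0]:
        return res_range[0], True
    drop = np.argmin(good)  # first False; 0 means never drops
    last = (n - half - 1) if good.all() else (half + drop - 1)
    return float(1.0 / gs[last]), False


def estimate_ctf(spectrum: PowerSpectrum2d, base: CtfParams,
                 df_range=(0.3, 5.0), step: float = 0.01,
                 restraint: float = 0.1, dftol: float = 0.05,
                 phase_plate: bool = False, seed: int = 42,
                 res_range=(30.0, 5.0)) -> CtfFitResult:
    """Full three-step per-micrograph CTF estimation."""
    df1, _, low_conf = search_defocus_1d(spectrum, base, df_range, step,
                                         phase_plate, res_range)
    base1 = replace(base, phshift=(np.pi / 2 if phase_plate else base.phshift))
    params2 = refine_astigmatism(spectrum, base1, df1, restraint,
                                 fit_phase=phase_plate, seed=seed,
                                 res_range=res_range)
    result = refine_defocus(spectrum, params2, dftol, res_range)
    result.low_confidence = result.low_confidence or low_conf
    return result


# ---------------------------------------------------------------------------
# Patch-based anisotropic model
# ---------------------------------------------------------------------------


def grid_points_1d(dim: int, spacing: int) -> np.ndarray:
    """Centers of a square grid with the given spacing, centered on [0, dim)."""
    n = max(dim // spacing, 1)
    margin = (dim - (n - 1) * spacing) / 2.0
    return margin + spacing * np.arange(n)


def build_patch_grid(dims: tuple[int, int], spacing: int = 512,
                     tile_size: int = 512, overlap: float = 0.5,
                     n_tiles_max: int = 32, min_contribution: float = 0.01):
    """Grid points over the exposed area with Gaussian tile weights.

    For each grid point the nearest tiles (up to ``n_tiles_max``, radially
    sampled) receive weights w_ij = exp(-d_ij^2/2) / sum_k exp(-d_ik^2/2)
    with d expressed in units of the grid spacing; tiles contributing less
    than ``min_contribution`` are dropped and the weights renormalized.

    Returns (points, tile_centers, weight_table) where ``points`` is an
    (n_points, 2) array of (x, y), ``tile_centers`` an (n_tiles, 2) array
    and ``weight_table`` a list of (tile_indices, weights) per point.
    """
    ny, nx = dims
    if min(ny, nx) < spacing:
        warnings.warn("micrograph smaller than the grid spacing; "
                      "using a single central point")
        points = np.array([[nx / 2.0, ny / 2.0]])
    else:
        gx = grid_points_1d(nx, spacing)
        gy = grid_points_1d(ny, spacing)
        points = np.array([(x, y) for y in gy for x in gx])
    centers = np.array([
        (x0 + tile_size / 2.0, y0 + tile_size / 2.0)
        for y0, x0 in iter_tiles(dims, tile_size, overlap)
    ])
    table = []
    for p in points:
        d = np.hypot(*(centers - p).T) / spacing
        order = np.argsort(d)[:n_tiles_max]
        w = np.exp(-0.5 * d[order] ** 2)
        w = w / w.sum()
        keep = w > min_contribution
        idx, w = order[keep], w[keep]
        w = w / w.sum()
        table.append((idx, w))
    return points, centers, table


def _local_defocus_scan(spectrum: PowerSpectrum2d, params: CtfParams,
                        half_width: float = 0.3, step: float = 0.01,
                        res_range=(30.0, 5.0)) -> CtfParams:
    """Shift both defoci jointly over a local grid, keeping their difference
    and the astigmatism angle; returns the best-correlating start point.
    """
    mask, g, theta = _annulus_mask(spectrum, res_range)
    F = spectrum.values[mask]
    normF = np.sqrt((F ** 2).sum()) + 1e-300
    best, best_cc = params, -np.inf
    for delta in np.arange(-half_width, half_width + step / 2, step):
        p = replace(params, dfx=params.dfx + delta, dfy=params.dfy + delta)
        if p.dfy <= 0.05 or p.dfx <= 0.05:
            continue
        C = ctf_eval(p, g, theta) ** 2
        cc = (F * C).sum() / (normF * np.sqrt((C ** 2).sum()) + 1e-300)
        if cc > best_cc:
            best, best_cc = p, cc
    return best


def fit_patch_ctf(micrograph: np.ndarray, global_fit: CtfFitResult,
                  spacing: int = 512, tile_size: int = 512,
                  overlap: float = 0.5, dftol: float = 0.05,
                  res_range=(30.0, 5.0)) -> AnisoCtfModel:
    """Per-grid-point defocus refits + 2D 3rd-order polynomial field.

    Each grid point's distance-weighted average tile spectrum is refit
    (defoci only; the astigmatism angle and phase shift are shared from the
    global fit, which also initializes the defoci). The defocus field is
    then least-squares fitted over the grid results. Falls back with an
    error when more than half of the grid points fail.
    """
    micrograph = np.asarray(micrograph, dtype=np.float64)
    dims = micrograph.shape
    base = global_fit.params
    points, centers, table = build_patch_grid(dims, spacing, tile_size,
                                              overlap)
    # accumulate weighted raw spectra per grid point in one pass over tiles
    accum = np.zeros((len(points), tile_size, tile_size))
    tile_list = list(iter_tiles(dims, tile_size, overlap))
    contributions: dict[int, list[tuple[int, float]]] = {}
    for pi, (idx, w) in enumerate(table):
        for ti, wi in zip(idx, w):
            contributions.setdefault(int(ti), []).append((pi, float(wi)))
    for ti, (y0, x0) in enumerate(tile_list):
        if ti not in contributions:
            continue
        tile = micrograph[y0:y0 + tile_size, x0:x0 + tile_size]
        tile = tile - tile.mean()
        spec = np.abs(np.fft.fftshift(np.fft.fft2(tile))) ** 2 / tile_size ** 2
        for pi, wi in contributions[ti]:
            accum[pi] += wi * spec

    results: list[tuple[np.ndarray, CtfFitResult]] = []
    failures = 0
    for pi, p in enumerate(points):
        values = _postprocess_spectrum(accum[pi], tile_size, base.pixel_size)
        spec = PowerSpectrum2d(values=values, pixel_size=base.pixel_size,
                               tile_size=tile_size, n_tiles=len(table[pi][0]))
        try:
            # the cc landscape oscillates with defocus: re-center the start
            # with a coarse local scan so L-BFGS-B lands in the right basin
            init = _local_defocus_scan(spec, base, res_range=res_range)
            fit = refine_defocus(spec, init, dftol, res_range)
            results.append((p, fit))
        except Exception:
            failures += 1
    if failures > len(points) / 2:
        raise RuntimeError(
            f"anisotropic CTF fit failed at {failures}/{len(points)} grid "
            "points; falling back to per-micrograph parameters is advised"
        )
    ny, nx = dims
    coords = np.array([
        (poly.normalize_coords(p[0], nx - 1), poly.normalize_coords(p[1], ny - 1))
        for p, _ in results
    ])
    dfx = np.array([fit.params.dfx for _, fit in results])
    dfy = np.array([fit.params.dfy for _, fit in results])
    exps = poly.BIVARIATE_EXPONENTS
    cx, _ = poly.fit_least_squares(coords, dfx, exps)
    cy, _ = poly.fit_least_squares(coords, dfy, exps)
    return AnisoCtfModel(poly_dfx=cx, poly_dfy=cy, ang_ast=base.ang_ast,
                         phshift=base.phshift, base=base, dims=dims,
                         grid=results)


def evaluate_local_ctf(model: AnisoCtfModel, x, y) -> CtfParams:
    """Local CTF parameters at micrograph position (x, y) in pixels."""
    ny, nx = model.dims
    coord = np.array([[poly.normalize_coords(float(x), nx - 1),
                       poly.normalize_coords(float(y), ny - 1)]])
    exps = poly.BIVARIATE_EXPONENTS
    dfx = float(poly.eval_poly(model.poly_dfx, coord, exps)[0])
    dfy = float(poly.eval_poly(model.poly_dfy, coord, exps)[0])
    return replace(model.base, dfx=dfx, dfy=dfy, ang_ast=model.ang_ast,
                   phshift=model.phshift)
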