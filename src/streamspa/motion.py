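"""Two-stage movie motion correction.

Stage 1 (global): every frame is aligned to an iteratively evolving
weighted-average reference, first by a rapid coarse integer-pixel
correlation-peak search, then by continuous bounded quasi-Newton (L-BFGS-B)
maximization of the frame-to-reference correlations with analytic shift
gradients. Alignment is restricted to a resolution band that ramps from
``res_start`` to ``res_final`` (linearly in 1/resolution) with B-factor
damping of the noisy high-frequency shells, and correlation-based frame
weights marginalize the influence of the fast-moving first frames and the
radiation-damaged last frames.

Stage 2 (local): the globally corrected frames are subdivided into patches,
each patch is aligned with the same coarse+refine strategy (with per-patch
trajectories smoothed by 3rd-order 1D polynomials in time during the coarse
iterations), and all patch shifts are least-squares fitted by a trivariate
3rd-order polynomial in (x, y, t), yielding a smooth per-pixel deformation
model. The corrected frames are finally resampled, optionally dose-weighted
with the critical-exposure filter, weighted and summed into the integrated
micrograph.

Shift convention: ``shifts[j] = (dx, dy)`` is the displacement such that
``frame_j(x + dx, y + dy)`` is aligned to the common reference; arrays are
indexed ``image[y, x]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from streamspa import poly
from streamspa.io_formats import MovieStack


@dataclass
class ShiftTrajectory:
    """Per-frame whole-frame (or per-patch) shifts in pixels."""

    shifts: np.ndarray          # (n_frames, 2): (dx, dy)
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("trajectory contains non-finite shifts")

    def centered(self) -> "ShiftTrajectory":
        return ShiftTrajectory(self.shifts - self.shifts.mean(axis=0),
                               self.converged, self.iterations)


@dataclass
class FrameWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w < 0):
            raise ValueError("frame weights must be nonnegative")
        total = self.w.sum()
        if total <= 0:
            raise ValueError("frame weights must not all be zero")
        self.w = self.w / total


@dataclass
class AlignConfig:
    """Alignment controls.

    res_start/res_final: resolution band limits in Angstrom; the limit ramps
    linearly in 1/resolution across outer iterations. bfactor: Gaussian
    damping of high shells in A^2. patch_grid: requested patch grid, capped
    so each patch keeps at least ``min_patch_size`` pixels per side.
    """

    res_start: float = 8.0
    res_final: float = 5.0
    bfactor: float = 50.0
    max_iter: int = 10
    tol: float = 0.02
    max_shift: float = 20.0
    coarse_iters: int = 3
    refine_rounds: int = 3
    patch_grid: tuple[int, int] = (5, 5)
    min_patch_size: int = 256
    smoothing: bool = True

    def validate(self, pixel_size: float) -> None:
        if not (self.res_start >= self.res_final > 2.0 * pixel_size):
            raise ValueError(
                "need res_start >= res_final > 2*pixel_size "
                f"(got {self.res_start}, {self.res_final}, px {pixel_size})"
            )


@dataclass
class DeformationModel:
    """Global trajectory + trivariate 3rd-order local deformation polynomial.

    Polynomial coordinates are normalized to [-1, 1] over the exposed area
    (x, y) and the exposure (t = frame index / (n_frames - 1)).
    """

    coeffs_x: np.ndarray | None = None
    coeffs_y: np.ndarray | None = None
    global_traj: ShiftTrajectory | None = None
    weights: FrameWeights | None = None
    rmsd_fit: float = 0.0
    dims: tuple[int, int] = (0, 0)      # (ny, nx)
    n_frames: int = 0

    @property
    def fitted(self) -> bool:
        return self.coeffs_x is not None and self.global_traj is not None


# ---------------------------------------------------------------------------
# Fourier helpers
# ---------------------------------------------------------------------------


def _freq_grids(shape: tuple[int, int], pixel_size: float):
    """Spatial frequencies in cycles/pixel (fx, fy) and A^-1 magnitude."""
    ny, nx = shape
    fx = np.fft.fftfreq(nx)[None, :]
    fy = np.fft.fftfreq(ny)[:, None]
    g = np.sqrt(fx ** 2 + fy ** 2) / pixel_size
    return fx, fy, g


def _band_weight(g: np.ndarray, res_limit: float, bfactor: float) -> np.ndarray:
    """B-factor-damped low-pass weight; zero beyond 1/res_limit."""
    w = np.exp(-0.25 * bfactor * g ** 2)
    w[g > 1.0 / res_limit] = 0.0
    w[0, 0] = 0.0  # mean term carries no alignment signal
    return w


def shift_frame_fourier(frame: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Return frame(x + dx, y + dy) via a Fourier phase ramp."""
    F = np.fft.fft2(frame)
    fx, fy, _ = _freq_grids(frame.shape, 1.0)
    phase = np.exp(2j * np.pi * (fx * shift[0] + fy * shift[1]))
    return np.fft.ifft2(F * phase).real


def _phase_ramp(fx, fy, shift):
    return np.exp(2j * np.pi * (fx * shift[0] + fy * shift[1]))


def _res_schedule(res_start: float, res_final: float, n: int) -> np.ndarray:
    """Resolution limits linear in 1/res across n outer iterations."""
    if n == 1:
        return np.array([res_final])
    return 1.0 / np.linspace(1.0 / res_start, 1.0 / res_final, n)


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------


def align_global(stack: MovieStack, cfg: AlignConfig | None = None,
                 _record_objective: list | None = None) -> ShiftTrajectory:
    """Whole-frame alignment: coarse peak search then L-BFGS-B refinement."""
    cfg = cfg or AlignConfig()
    cfg.validate(stack.pixel_size)
    F = np.fft.fft2(stack.frames)
    shifts, n_coarse, ok_coarse = _coarse_align(
        F, stack.pixel_size, cfg, smooth_time=False)
    shifts, n_ref, ok_ref = _refine_align(
        F, shifts, stack.pixel_size, cfg, _record_objective)
    traj = ShiftTrajectory(shifts, converged=ok_coarse and ok_ref,
                           iterations=n_coarse + n_ref)
    return traj.centered()


def _coarse_align(F: np.ndarray, pixel_size: float, cfg: AlignConfig,
                  smooth_time: bool, weights: np.ndarray | None = None):
    """Iterative integer-pixel alignment to the evolving average reference."""
    n, ny, nx = F.shape
    fx, fy, g = _freq_grids((ny, nx), pixel_size)
    shifts = np.zeros((n, 2))
    if weights is None:
        weights = np.full(n, 1.0 / n)
    res_sched = _res_schedule(cfg.res_start, cfg.res_final, cfg.coarse_iters)
    win = int(np.ceil(cfg.max_shift))
    iters = 0
    converged = False
    for it in range(cfg.coarse_iters):
        W = _band_weight(g, res_sched[it], cfg.bfactor)
        A = F * _phase_ramp(fx, fy, (shifts[:, 0, None, None],
                                     shifts[:, 1, None, None]))
        ref = np.einsum("j,jyx->yx", weights, A)
        max_step = 0.0
        new_shifts = shifts.copy()
        for j in range(n):
            ref_j = ref - weights[j] * A[j]
            cmap = np.fft.ifft2(W * A[j] * np.conj(ref_j)).real
            d = _windowed_peak(cmap, win)
            new_shifts[j] += d
            max_step = max(max_step, np.abs(d).max())
        shifts = new_shifts - new_shifts.mean(axis=0)
        if smooth_time and n >= 5:
            shifts = _smooth_trajectory(shifts)
        iters += 1
        if max_step < max(cfg.tol, 0.5):  # integer search cannot go below 1 px
            converged = True
            break
    return shifts, iters, converged or cfg.coarse_iters == 0


def _windowed_peak(cmap: np.ndarray, win: int) -> np.ndarray:
    """Peak of the wrapped correlation map within +/- win pixels of zero."""
    c = np.fft.fftshift(cmap)
    ny, nx = c.shape
    cy, cx = ny // 2, nx // 2
    sub = c[cy - win:cy + win + 1, cx - win:cx + win + 1]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    return np.array([ix - win, iy - win], dtype=float)


def _smooth_trajectory(shifts: np.ndarray) -> np.ndarray:
    """3rd-order polynomial smoothing in time, per axis."""
    n = shifts.shape[0]
    t = np.linspace(-1.0, 1.0, n)
    out = np.empty_like(shifts)
    for ax in range(2):
        coef = np.polynomial.polynomial.polyfit(t, shifts[:, ax], 3)
        out[:, ax] = np.polynomial.polynomial.polyval(t, coef)
    return out


def _refine_align(F: np.ndarray, shifts: np.ndarray, pixel_size: float,
                  cfg: AlignConfig, record: list | None = None,
                  weights: np.ndarray | None = None):
    """Continuous L-BFGS-B refinement with analytic correlation gradients.

    The leave-one-out references are held fixed within each round and
    rebuilt between rounds while the resolution limit ramps to res_final.
    """
    n, ny, nx = F.shape
    fx2, fy2, g = _freq_grids((ny, nx), pixel_size)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    res_sched = _res_schedule(cfg.res_start, cfg.res_final, cfg.refine_rounds)
    total_iters = 0
    converged = True
    for rnd in range(cfg.refine_rounds):
        W = _band_weight(g, res_sched[rnd], cfg.bfactor)
        mask = W > 0
        wv = W[mask]
        fxv = np.broadcast_to(fx2, (ny, nx))[mask]
        fyv = np.broadcast_to(fy2, (ny, nx))[mask]
        Av = np.stack([
            (F[j] * _phase_ramp(fx2, fy2, shifts[j]))[mask] for j in range(n)
        ])
        ref = np.einsum("j,jk->k", weights, Av)
        P = np.empty_like(Av)
        norms = np.empty(n)
        for j in range(n):
            ref_j = ref - weights[j] * Av[j]
            P[j] = (wv ** 2) * Av[j] * np.conj(ref_j)
            norms[j] = (np.linalg.norm(wv * Av[j])
                        * np.linalg.norm(wv * ref_j)) + 1e-300

        def objective(d_flat: np.ndarray):
            d = d_flat.reshape(n, 2)
            phase = np.exp(2j * np.pi * (np.outer(d[:, 0], fxv)
                                         + np.outer(d[:, 1], fyv)))
            Z = P * phase
            cc = Z.real.sum(axis=1) / norms
            gx = -2.0 * np.pi * (Z.imag @ fxv) / norms
            gy = -2.0 * np.pi * (Z.imag @ fyv) / norms
            grad = np.stack([gx, gy], axis=1)
            return -cc.sum(), -grad.ravel()

        history: list[float] = []
        cb = (lambda xk: history.append(-objective(xk)[0]))
        res = minimize(objective, np.zeros(2 * n), jac=True, method="L-BFGS-B",
                       bounds=[(-3.0, 3.0)] * (2 * n),
                       options={"maxiter": cfg.max_iter, "ftol": 1e-12,
                                "gtol": 1e-10},
                       callback=cb)
        if record is not None:
            record.append(history)
        d = res.x.reshape(n, 2)
        shifts = shifts + d
        shifts = shifts - shifts.mean(axis=0)
        total_iters += res.nit
        if not res.success and res.nit >= cfg.max_iter:
            converged = False
    return shifts, total_iters, converged


# ---------------------------------------------------------------------------
# Frame weights
# ---------------------------------------------------------------------------


def compute_frame_weights(stack: MovieStack, traj: ShiftTrajectory,
                          cfg: AlignConfig | None = None) -> FrameWeights:
    """Correlation-based frame weights.

    Each frame's weight is proportional to max(0, correlation of the aligned
    frame with the leave-one-out average reference) in the final resolution
    band, normalized to sum 1. If no frame correlates positively a uniform
    weighting is returned with a warning.
    """
    cfg = cfg or AlignConfig()
    n = stack.n_frames
    fx, fy, g = _freq_grids(stack.shape, stack.pixel_size)
    W = _band_weight(g, cfg.res_final, cfg.bfactor)
    F = np.fft.fft2(stack.frames)
    A = F * _phase_ramp(fx, fy, (traj.shifts[:, 0, None, None],
                                 traj.shifts[:, 1, None, None]))
    total = A.mean(axis=0)
    corr = np.empty(n)
    for j in range(n):
        ref_j = (total * n - A[j]) / (n - 1)
        num = np.sum((W * A[j]) * np.conj(W * ref_j)).real
        den = (np.linalg.norm(W * A[j]) * np.linalg.norm(W * ref_j)) + 1e-300
        corr[j] = num / den
    w = np.maximum(corr, 0.0)
    if w.sum() <= 0:
        warnings.warn("no frame correlates positively; using uniform weights")
        w = np.ones(n)
    return FrameWeights(w)


# ---------------------------------------------------------------------------
# Patch alignment and deformation fitting
# ---------------------------------------------------------------------------


def _patch_layout(shape: tuple[int, int], cfg: AlignConfig):
    """Patch grid positions honoring the minimum patch-size floor."""
    ny, nx = shape
    gx = min(cfg.patch_grid[0], max(1, nx // cfg.min_patch_size))
    gy = min(cfg.patch_grid[1], max(1, ny // cfg.min_patch_size))
    px, py = nx // gx, ny // gy
    xs = [(i * px, (i + 1) * px if i < gx - 1 else nx) for i in range(gx)]
    ys = [(i * py, (i + 1) * py if i < gy - 1 else ny) for i in range(gy)]
    return xs, ys


def align_patches(stack: MovieStack, global_traj: ShiftTrajectory,
                  cfg: AlignConfig | None = None):
    """Per-patch alignment of the globally corrected frames.

    Returns (trajectories, centers, flags): per-patch ShiftTrajectory, patch
    center coordinates (x, y) in pixels, and a validity flag per patch
    (False for near-zero-variance patches excluded from the fit).
    """
    cfg = cfg or AlignConfig()
    cfg.validate(stack.pixel_size)
    n = stack.n_frames
    corrected = np.stack([
        shift_frame_fourier(stack.frames[j], global_traj.shifts[j])
        for j in range(n)
    ])
    xs, ys = _patch_layout(stack.shape, cfg)
    pcfg = AlignConfig(**{**cfg.__dict__, "max_shift": 6.0})
    trajs, centers, flags = [], [], []
    global_var = corrected.var()
    for y0, y1 in ys:
        for x0, x1 in xs:
            patch = corrected[:, y0:y1, x0:x1]
            centers.append(((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0))
            if patch.var() < 1e-6 * global_var:
                trajs.append(ShiftTrajectory(np.zeros((n, 2)), False, 0))
                flags.append(False)
                continue
            Fp = np.fft.fft2(patch)
            shifts, ci, ok1 = _coarse_align(Fp, stack.pixel_size, pcfg,
                                            smooth_time=cfg.smoothing)
            shifts, ri, ok2 = _refine_align(Fp, shifts, stack.pixel_size, pcfg)
            trajs.append(ShiftTrajectory(shifts, ok1 and ok2, ci + ri))
            flags.append(True)
    return trajs, centers, flags


def fit_deformation(patch_trajs, patch_centers, n_frames: int,
                    dims: tuple[int, int], flags=None,
                    global_traj: ShiftTrajectory | None = None,
                    weights: FrameWeights | None = None) -> DeformationModel:
    """Least-squares fit of patch shifts to a trivariate 3rd-order polynomial.

    Samples are (patch center x, patch center y, frame index t) triples in
    coordinates normalized to [-1, 1]; x- and y-shifts are fitted
    independently. Raises on rank deficiency (e.g. too few patches to
    determine the full basis).
    """
    ny, nx = dims
    if flags is None:
        flags = [True] * len(patch_trajs)
    coords, vx, vy = [], [], []
    for traj, (cx, cy), ok in zip(patch_trajs, patch_centers, flags):
        if not ok:
            continue
        for t in range(n_frames):
            coords.append((
                poly.normalize_coords(cx, nx - 1),
                poly.normalize_coords(cy, ny - 1),
                poly.normalize_coords(t, n_frames - 1),
            ))
            vx.append(traj.shifts[t, 0])
            vy.append(traj.shifts[t, 1])
    coords = np.asarray(coords)
    exps = poly.TRIVARIATE_EXPONENTS
    cx_, rx = poly.fit_least_squares(coords, np.asarray(vx), exps)
    cy_, ry = poly.fit_least_squares(coords, np.asarray(vy), exps)
    return DeformationModel(
        coeffs_x=cx_, coeffs_y=cy_, global_traj=global_traj,
        weights=weights, rmsd_fit=float(np.hypot(rx, ry) / np.sqrt(2)),
        dims=(ny, nx), n_frames=n_frames,
    )


def evaluate_deformation(model: DeformationModel, x, y, t) -> np.ndarray:
    """Total shift (dx, dy) at pixel (x, y), frame t: global + local.

    Accepts scalars or arrays (broadcast together); extrapolation outside the
    exposed area is the polynomial's natural continuation.
    """
    if not model.fitted:
        raise ValueError("deformation model is not fitted")
    ny, nx = model.dims
    x, y, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float),
                                  np.asarray(t, float))
    coords = np.stack([
        poly.normalize_coords(x.ravel(), nx - 1),
        poly.normalize_coords(y.ravel(), ny - 1),
        poly.normalize_coords(t.ravel(), model.n_frames - 1),
    ], axis=1)
    exps = poly.TRIVARIATE_EXPONENTS
    dx = poly.eval_poly(model.coeffs_x, coords, exps)
    dy = poly.eval_poly(model.coeffs_y, coords, exps)
    ti = np.clip(np.round(t.ravel()).astype(int), 0, model.n_frames - 1)
    gshift = model.global_traj.shifts[ti]
    out = np.stack([dx, dy], axis=1) + gshift
    return out.reshape(x.shape + (2,))


# ---------------------------------------------------------------------------
# Dose weighting and integration
# ---------------------------------------------------------------------------


@dataclass
class DoseConfig:
    """Critical-exposure dose filter parameterization.

    The per-frequency critical exposure is Dc(g) = a*g**b + c (e-/A^2, g in
    A^-1) with the published defaults; a frame with accumulated exposure D
    is attenuated by exp(-D / (2*Dc(g))). ``voltage_scale`` rescales the
    critical exposure (1.0 at 300 kV, commonly 0.8 at 200 kV).
    """

    enabled: bool = True
    a: float = 0.24499
    b: float = -1.6649
    c: float = 2.8141
    voltage_scale: float = 1.0

    def critical_dose(self, g: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            dc = self.a * np.power(np.maximum(g, 1e-12), self.b) + self.c
        return dc * self.voltage_scale


def dose_filter(g: np.ndarray, accumulated_dose: float,
                cfg: DoseConfig) -> np.ndarray:
    return np.exp(-accumulated_dose / (2.0 * cfg.critical_dose(g)))


def integrate_movie(stack: MovieStack, model: DeformationModel,
                    dose_cfg: DoseConfig | None = None) -> np.ndarray:
    """Resample, dose-filter, weight and sum the frames into a micrograph."""
    if not model.fitted:
        raise ValueError("deformation model is not fitted")
    dose_cfg = dose_cfg or DoseConfig(enabled=False)
    if dose_cfg.enabled and stack.dose_per_frame is None:
        raise ValueError("dose filtering requires dose_per_frame metadata")
    ny, nx = stack.shape
    n = stack.n_frames
    weights = (model.weights.w if model.weights is not None
               else np.full(n, 1.0 / n))
    Y, X = np.mgrid[0:ny, 0:nx].astype(np.float64)
    _, _, g = _freq_grids((ny, nx), stack.pixel_size)
    out = np.zeros((ny, nx))
    for j in range(n):
        s = evaluate_deformation(model, X, Y, np.full_like(X, float(j)))
        frame = ndimage.map_coordinates(stack.frames[j],
                                        [Y + s[..., 1], X + s[..., 0]],
                                        order=1, mode="nearest")
        if dose_cfg.enabled:
            dose = stack.dose_per_frame * (j + 1)
            frame = np.fft.ifft2(np.fft.fft2(frame)
                                 * dose_filter(g, dose, dose_cfg)).real
        out += weights[j] * frame
    return out


def motion_correct(stack: MovieStack, cfg: AlignConfig | None = None,
                   dose_cfg: DoseConfig | None = None):
    """Full two-stage motion correction; returns (micrograph, model)."""
    cfg = cfg or AlignConfig()
    traj = align_global(stack, cfg)
    weights = compute_frame_weights(stack, traj, cfg)
    trajs, centers, flags = align_patches(stack, traj, cfg)
    try:
        model = fit_deformation(trajs, centers, stack.n_frames, stack.shape,
                                flags=flags, global_traj=traj,
                                weights=weights)
    except np.linalg.LinAlgError:
        # too few patches for the full spatiotemporal basis (small frames):
        # keep the global trajectory with a zero local model
        warnings.warn("patch grid too coarse for the local deformation "
                      "basis; using global shifts only")
        nterms = len(poly.TRIVARIATE_EXPONENTS)
        model = DeformationModel(coeffs_x=np.zeros(nterms),
                                 coeffs_y=np.zeros(nterms),
                                 global_traj=traj, weights=weights,
                                 dims=stack.shape, n_frames=stack.n_frames)
    micrograph = integrate_movie(stack, model, dose_cfg)
    return micrograph, model
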