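"""Chunked streaming 2D analysis bookkeeping and class rejection.

Incoming particles are buffered into fixed-size chunks; each chunk is
classified by a reference 2D aligner (in-plane rotation + shift alignment
to iteratively updated class averages — deliberately simple plumbing, the
stream logic is engine-agnostic behind :func:`classify_chunk`). Per class,
gold-standard even/odd half-set averages yield a Fourier ring correlation
resolution at the 0.143 criterion (``res_i`` with spectral shell index
``g_i``) and the mean particle-to-average correlation ``cc_i``. A class is
softly rejected when it is simultaneously a low-resolution outlier
(standardized g-index below ``z_cut``, or resolution worse than an absolute
bound) and a weak-correlation outlier (standardized cc below ``z_cut``).
Surviving classes and particles expand the global set; the refined fraction
delta starts at 40% and is adaptively lowered so that a capped number of
particles (500 K) is always refined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class ClassMetrics:
    class_id: int
    res: float          # A, FRC = 0.143 estimate
    g_index: int        # spectral shell index of res
    cc: float           # mean particle-to-average correlation
    n_members: int = 0

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError("resolution must be positive")
        if self.n_members < 0:
            raise ValueError("n_members must be nonnegative")


@dataclass
class RejectionConfig:
    z_cut: float = -1.5
    res_abs: float = 30.0
    strict_absolute: bool = False   # reject on res alone, ignoring cc

    def __post_init__(self) -> None:
        if self.z_cut >= 0:
            raise ValueError("z_cut must be negative")
        if self.res_abs <= 0:
            raise ValueError("res_abs must be positive")


@dataclass
class StreamState:
    chunks_done: int = 0
    global_particle_count: int = 0
    delta: float = 0.4
    cap: int = 500_000
    delta_max: float = 0.4
    n_global_classes: int = 0
    refine_subset: np.ndarray | None = None
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Chunk formation
# ---------------------------------------------------------------------------


class ChunkBuffer:
    """Accumulates streamed particles and emits fixed-size chunks in order."""

    def __init__(self, chunk_size: int):
        if chunk_size <= 0:
            raise ValueError("chunk_size must be positive")
        self.chunk_size = chunk_size
        self._held: list = []
        self.emitted = 0

    def add(self, items) -> list[list]:
        """Add items; returns the list of complete chunks now ready."""
        self._held.extend(items)
        chunks = []
        while len(self._held) >= self.chunk_size:
            chunks.append(self._held[:self.chunk_size])
            self._held = self._held[self.chunk_size:]
            self.emitted += 1
        return chunks

    def flush(self) -> list:
        """Emit the held remainder as a final short chunk."""
        rest, self._held = self._held, []
        if rest:
            self.emitted += 1
        return rest

    @property
    def held(self) -> int:
        return len(self._held)


def form_chunks(stream, chunk_size: int):
    """Generator of consecutive non-overlapping chunks in arrival order."""
    buf = ChunkBuffer(chunk_size)
    for item in stream:
        yield from buf.add([item])
    rest = buf.flush()
    if rest:
        yield rest


# ---------------------------------------------------------------------------
# Reference 2D aligner (plumbing)
# ---------------------------------------------------------------------------


class _Matcher:
    """Best (rotation, shift) correlation of every particle to a reference."""

    def __init__(self, chunk: np.ndarray, angles: np.ndarray, max_shift: int):
        self.n, self.b, _ = chunk.shape
        self.angles = angles
        self.max_shift = max_shift
        self.F = np.fft.fft2(chunk - chunk.mean(axis=(1, 2))[:, None, None])
        self.Fnorm = np.sqrt((np.abs(self.F) ** 2).sum(axis=(1, 2)))

    def match(self, reference: np.ndarray):
        """Returns (cc, angle index, (dy, dx)) per particle, cc normalized."""
        n, b, ms = self.n, self.b, self.max_shift
        c0 = b // 2
        best_cc = np.full(n, -np.inf)
        best_rot = np.zeros(n, dtype=int)
        best_shift = np.zeros((n, 2), dtype=int)
        for r, ang in enumerate(self.angles):
            rot = ndimage.rotate(reference, ang, reshape=False, order=1)
            G = np.fft.fft2(rot - rot.mean())
            Gnorm = np.sqrt((np.abs(G) ** 2).sum())
            cmap = np.fft.ifft2(self.F * np.conj(G)[None]).real
            cmap = np.fft.fftshift(cmap, axes=(1, 2))
            sub = cmap[:, c0 - ms:c0 + ms + 1, c0 - ms:c0 + ms + 1]
            flat = sub.reshape(n, -1)
            arg = flat.argmax(axis=1)
            # real-space peak correlation, normalized (Parseval scaling)
            cc = flat[np.arange(n), arg] * (b * b) / (self.Fnorm * Gnorm
                                                      + 1e-300)
            better = cc > best_cc
            best_cc[better] = cc[better]
            best_rot[better] = r
            dy, dx = np.unravel_index(arg, sub.shape[1:])
            best_shift[better, 0] = dy[better] - ms
            best_shift[better, 1] = dx[better] - ms
        return best_cc, best_rot, best_shift


def _aligned(chunk, idx, rots, shifts, angles):
    """Particles transformed into the reference frame of their class."""
    out = []
    for i in idx:
        p = np.roll(chunk[i], (-shifts[i, 0], -shifts[i, 1]), axis=(0, 1))
        out.append(ndimage.rotate(p, -angles[rots[i]], reshape=False,
                                  order=1))
    return np.array(out)


def classify_chunk(chunk: np.ndarray, n_classes: int, seed: int = 0,
                   pixel_size: float = 1.0, n_iter: int = 8,
                   rot_step: float = 15.0, max_shift: int = 6,
                   ref_smooth: float = 1.5):
    """Reference 2D aligner: rotation+shift alignment to evolving averages.

    Initial references are picked greedily from the particles themselves
    under ``seed`` (first at random, then the particle least correlated to
    any reference so far, covering distinct views); each iteration matches
    every particle against the lightly smoothed class averages over in-plane
    rotations and shifts, then rebuilds the averages from the aligned
    members. Even/odd half-set averages (by member order within a class)
    provide the gold-standard FRC resolution per class; ``cc_i`` is the mean
    member-to-reference correlation at the best alignment.

    Returns (class_averages, metrics, assignments, converged).
    """
    chunk = np.asarray(chunk, dtype=np.float64)
    n, b, _ = chunk.shape
    if n < n_classes * 10:
        raise ValueError("chunk too small for the requested class count")
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 360.0, rot_step)
    matcher = _Matcher(chunk, angles, max_shift)
    smooth = (lambda im: ndimage.gaussian_filter(im, ref_smooth)) \
        if ref_smooth else (lambda im: im)

    # greedy dissimilarity seeding
    seed_idx = [int(rng.integers(n))]
    cc_rows = [matcher.match(smooth(chunk[seed_idx[0]]))]
    for _ in range(n_classes - 1):
        best_any = np.max([row[0] for row in cc_rows], axis=0)
        cand = int(np.argmin(best_any))
        seed_idx.append(cand)
        cc_rows.append(matcher.match(smooth(chunk[cand])))

    assign = np.argmax([row[0] for row in cc_rows], axis=0)
    rows = cc_rows
    converged = False
    for it in range(n_iter):
        rots = np.zeros(n, dtype=int)
        shifts = np.zeros((n, 2), dtype=int)
        for k in range(n_classes):
            sel = assign == k
            rots[sel] = rows[k][1][sel]
            shifts[sel] = rows[k][2][sel]
        averages = np.empty((n_classes, b, b))
        for k in range(n_classes):
            members = np.where(assign == k)[0]
            if len(members) == 0:
                averages[k] = chunk[int(rng.integers(n))]
            else:
                averages[k] = _aligned(chunk, members, rots, shifts,
                                       angles).mean(axis=0)
        rows = [matcher.match(smooth(averages[k])) for k in range(n_classes)]
        new_assign = np.argmax([row[0] for row in rows], axis=0)
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign

    rots = np.zeros(n, dtype=int)
    shifts = np.zeros((n, 2), dtype=int)
    best_cc = np.zeros(n)
    for k in range(n_classes):
        sel = assign == k
        best_cc[sel] = rows[k][0][sel]
        rots[sel] = rows[k][1][sel]
        shifts[sel] = rows[k][2][sel]
    averages = np.empty((n_classes, b, b))
    metrics = []
    for k in range(n_classes):
        members = np.where(assign == k)[0]
        aligned = _aligned(chunk, members, rots, shifts, angles) \
            if len(members) else np.zeros((0, b, b))
        averages[k] = aligned.mean(axis=0) if len(aligned) else 0.0
        if len(aligned) >= 2:
            ha, hb = aligned[0::2].mean(axis=0), aligned[1::2].mean(axis=0)
        else:
            ha = hb = np.zeros((b, b))
        res, g_idx, _ = class_resolution(ha, hb, pixel_size)
        metrics.append(ClassMetrics(
            class_id=k, res=res, g_index=g_idx,
            cc=float(best_cc[members].mean()) if len(members) else 0.0,
            n_members=len(members)))
    return averages, metrics, assign, converged


# ---------------------------------------------------------------------------
# FRC resolution
# ---------------------------------------------------------------------------


def fourier_ring_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """FRC per integer-radius shell (shell 1 .. Nyquist)."""
    if a.shape != b.shape:
        raise ValueError("half-set averages differ in shape")
    n = a.shape[0]
    Fa = np.fft.fftshift(np.fft.fft2(a))
    Fb = np.fft.fftshift(np.fft.fft2(b))
    c = n // 2
    Y, X = np.mgrid[0:n, 0:n]
    r = np.hypot(X - c, Y - c).astype(int).ravel()
    nshell = n // 2
    num = np.bincount(r, (Fa * np.conj(Fb)).real.ravel(), minlength=nshell + 1)
    da = np.bincount(r, (np.abs(Fa) ** 2).ravel(), minlength=nshell + 1)
    db = np.bincount(r, (np.abs(Fb) ** 2).ravel(), minlength=nshell + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(da * db)
    frc = frc[1:nshell + 1]
    frc[~np.isfinite(frc)] = 0.0
    return frc


def class_resolution(half_avg_a: np.ndarray, half_avg_b: np.ndarray,
                     pixel_size: float, threshold: float = 0.143):
    """FRC = 0.143 resolution of a class from its half-set averages.

    Returns (resolution A, shell index g, at_nyquist flag). The resolution
    is that of the last shell before the FRC first drops below threshold;
    if it never drops, Nyquist is returned with the flag set.
    """
    n = half_avg_a.shape[0]
    frc = fourier_ring_correlation(half_avg_a, half_avg_b)
    below = frc < threshold
    if not below.any():
        g = len(frc)
        return 2.0 * pixel_size, g, True
    first_bad = int(np.argmax(below))
    g = max(first_bad, 1)   # shell index of the last accepted shell (1-based)
    res = n * pixel_size / g
    return float(res), g, False


# ---------------------------------------------------------------------------
# Class rejection and the global set
# ---------------------------------------------------------------------------


def reject_classes(metrics, cfg: RejectionConfig | None = None) -> np.ndarray:
    """Boolean keep-flags implementing the soft rejection rule.

    Class j is rejected iff [z(g_j) < z_cut OR res_j > res_abs] AND
    z(cc_j) < z_cut, with z the population standardization; a zero standard
    deviation makes the corresponding z-criterion false for all classes.
    In ``strict_absolute`` mode res_j > res_abs alone rejects.
    """
    cfg = cfg or RejectionConfig()
    metrics = list(metrics)
    if len(metrics) < 2:
        if metrics:
            warnings.warn("single class; rejection skipped")
        return np.ones(len(metrics), dtype=bool)
    g = np.array([m.g_index for m in metrics], dtype=float)
    cc = np.array([m.cc for m in metrics], dtype=float)
    res = np.array([m.res for m in metrics], dtype=float)
    sg, scc = g.std(), cc.std()
    z_g = (g - g.mean()) / sg < cfg.z_cut if sg > 0 else np.zeros(len(g), bool)
    z_cc = (cc - cc.mean()) / scc < cfg.z_cut if scc > 0 \
        else np.zeros(len(cc), bool)
    res_bad = res > cfg.res_abs
    if cfg.strict_absolute:
        reject = ((z_g | res_bad) & z_cc) | res_bad
    else:
        reject = (z_g | res_bad) & z_cc
    return ~reject


def update_global(state: StreamState, n_new_particles: int,
                  n_new_classes: int, seed: int = 0) -> StreamState:
    """Expand the global set and update the adaptive refinement fraction.

    delta = min(delta_max, cap / count); a uniformly random subset of
    round(delta * count) particle indices (seeded) is marked for the next
    refinement pass, so at most ``cap`` (default 500 K) particles are ever
    refined at once.
    """
    state.chunks_done += 1
    state.global_particle_count += int(n_new_particles)
    state.n_global_classes += int(n_new_classes)
    count = state.global_particle_count
    if count > 0:
        state.delta = min(state.delta_max, state.cap / count)
        subset_size = min(int(round(state.delta * count)), count)
        rng = np.random.default_rng(seed)
        state.refine_subset = rng.choice(count, size=subset_size,
                                         replace=False)
    state.history.append((state.chunks_done, count, state.delta))
    return state
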