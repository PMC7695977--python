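"""Stream orchestration: watch a directory, preprocess each movie once.

A polling watcher picks up newly appearing movies (a file is considered
settled when its size is stable across two polls), runs motion correction,
CTF estimation and — when references are supplied — particle picking and
extraction, and appends the results to per-project STAR tables. Each
execution runs in a directory named ``<index>_<program>`` with a strictly
increasing index; a plain-text ledger of processed movies gives exactly-once
semantics across restarts. A failing movie is recorded and skipped without
halting the stream.
"""

from __future__ import annotations

import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from streamspa import ctf as ctf_mod
from streamspa import io_formats as iof
from streamspa import motion as motion_mod
from streamspa import picking as picking_mod

log = logging.getLogger("streamspa")


@dataclass
class StreamConfig:
    watch_dir: Path
    out_dir: Path
    pixel_size: float | None = None      # None: take from movie headers
    voltage_kV: float = 300.0
    cs: float = 2.7
    amp_contrast: float = 0.07
    align: "motion_mod.AlignConfig" = field(default_factory=lambda: motion_mod.AlignConfig())
    dose: "motion_mod.DoseConfig" = field(default_factory=lambda: motion_mod.DoseConfig(enabled=False))
    pick: "picking_mod.PickConfig | None" = None
    references: np.ndarray | None = None
    patch_ctf: bool = False
    poll_interval: float = 1.0
    max_polls: int | None = None         # stop after this many idle polls
    max_movies: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.poll_interval <= 0:
            raise ValueError("poll_interval must be positive")
        self.watch_dir = Path(self.watch_dir)
        self.out_dir = Path(self.out_dir)


@dataclass
class ProjectRecord:
    execution_index: int
    program: str
    directory: Path
    status: str = "running"    # running | finished | failed


def next_execution_dir(project_dir: Path, program: str) -> tuple[int, Path]:
    """Allocate the next ``<index>_<program>`` execution directory."""
    project_dir.mkdir(parents=True, exist_ok=True)
    taken = []
    for p in project_dir.iterdir():
        if p.is_dir() and "_" in p.name and p.name.split("_", 1)[0].isdigit():
            taken.append(int(p.name.split("_", 1)[0]))
    index = max(taken, default=0) + 1
    d = project_dir / f"{index}_{program}"
    d.mkdir()
    return index, d


class MovieLedger:
    """Plain-text record of processed movies (exactly-once across restarts)."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self._seen: set[str] = set()
        if self.path.exists():
            self._seen = set(self.path.read_text().split())

    def __contains__(self, name: str) -> bool:
        return name in self._seen

    def mark(self, name: str) -> None:
        self._seen.add(name)
        with open(self.path, "a") as fh:
            fh.write(name + "\n")


def process_movie(movie_path: Path, cfg: StreamConfig, out_dir: Path) -> dict:
    """Motion-correct, CTF-estimate and optionally pick one movie."""
    stack = iof.read_movie(movie_path)
    if cfg.pixel_size:
        stack.pixel_size = cfg.pixel_size
    stack.voltage_kV = cfg.voltage_kV
    if cfg.dose.enabled and stack.dose_per_frame is None:
        stack.dose_per_frame = 1.0
    micrograph, model = motion_mod.motion_correct(stack, cfg.align, cfg.dose)
    stem = movie_path.stem
    mic_path = out_dir / f"{stem}_intg.mrc"
    iof.write_micrograph(micrograph, mic_path, stack.pixel_size)
    iof.write_motion_star(model, out_dir / f"{stem}_motion.star")

    base = ctf_mod.CtfParams(cs=cfg.cs, amp_contrast=cfg.amp_contrast,
                             voltage_kV=cfg.voltage_kV,
                             pixel_size=stack.pixel_size)
    tile = min(512, 1 << int(np.log2(min(micrograph.shape))))
    spectrum = ctf_mod.compute_spectrum(micrograph, stack.pixel_size,
                                        tile_size=tile)
    fit = ctf_mod.estimate_ctf(spectrum, base, seed=cfg.seed)
    aniso = None
    if cfg.patch_ctf and min(micrograph.shape) >= 1024:
        try:
            aniso = ctf_mod.fit_patch_ctf(micrograph, fit, tile_size=tile,
                                          spacing=tile)
        except Exception:
            log.warning("patch CTF failed for %s; keeping global fit", stem)

    result = {
        "movie": stem, "micrograph": mic_path, "ctf": fit, "aniso": aniso,
        "n_particles": 0,
    }
    if cfg.references is not None and cfg.pick is not None:
        peaks, stack2 = picking_mod.pick_particles(micrograph, cfg.references,
                                                   cfg.pick)
        accepted = [p for p in peaks if p.accepted]
        per_particle_ctf = [
            ctf_mod.evaluate_local_ctf(aniso, p.x, p.y) if aniso is not None
            else fit.params
            for p in accepted
        ]
        iof.write_particles_star(accepted, out_dir / f"{stem}_particles.star",
                                 ctf_params=per_particle_ctf,
                                 pixel_size=stack.pixel_size)
        if len(stack2):
            with_mrc = out_dir / f"{stem}_ptcls.mrc"
            import mrcfile
            with mrcfile.new(with_mrc, overwrite=True) as mrc:
                mrc.set_data(stack2.astype(np.float32))
                mrc.voxel_size = stack.pixel_size
        result["n_particles"] = len(accepted)
    return result


def run_preprocess_stream(cfg: StreamConfig):
    """Poll ``watch_dir`` and process each settled movie exactly once.

    Returns the list of per-movie result dicts (failures carry an "error"
    key). The stream stops after ``max_movies`` successes or ``max_polls``
    consecutive idle polls.
    """
    index, out_dir = next_execution_dir(cfg.out_dir, "preprocess_stream")
    record = ProjectRecord(index, "preprocess_stream", out_dir)
    ledger = MovieLedger(out_dir / "processed_movies.txt")
    results: list[dict] = []
    ctf_rows = []
    sizes: dict[str, int] = {}
    idle = 0
    while True:
        new_work = False
        for movie in sorted(cfg.watch_dir.glob("*.mrc")) + \
                sorted(cfg.watch_dir.glob("*.mrcs")):
            name = movie.name
            if name in ledger:
                continue
            size = movie.stat().st_size
            if sizes.get(name) != size:
                sizes[name] = size   # not settled yet; re-check next poll
                continue
            new_work = True
            ledger.mark(name)
            try:
                res = process_movie(movie, cfg, out_dir)
                fit = res["ctf"]
                ctf_rows.append({
                    "rlnMicrographName": res["micrograph"].name,
                    "rlnDefocusU": fit.params.dfx * 1e4,
                    "rlnDefocusV": fit.params.dfy * 1e4,
                    "rlnDefocusAngle": fit.params.ang_ast,
                    "rlnCtfFigureOfMerit": fit.score_f,
                    "rlnCtfMaxResolution": fit.fit_resolution,
                })
                results.append(res)
                log.info("processed %s (%d particles)", name,
                         res["n_particles"])
            except Exception as exc:
                log.error("movie %s failed: %s", name, exc)
                results.append({"movie": movie.stem, "error": str(exc),
                                "traceback": traceback.format_exc()})
        if new_work:
            idle = 0
        else:
            idle += 1
        done = sum(1 for r in results if "error" not in r)
        if cfg.max_movies is not None and done >= cfg.max_movies:
            break
        if cfg.max_polls is not None and idle >= cfg.max_polls:
            break
        time.sleep(cfg.poll_interval if not new_work else 0.0)
    if ctf_rows:
        iof.write_star({"micrographs": pd.DataFrame(ctf_rows)},
                       out_dir / "micrographs_ctf.star")
    record.status = "finished"
    return results, record


def export_selection(particle_blocks, selected_class_ids, assignments,
                     out_dir: Path, aniso_models=None):
    """Write a particles STAR restricted to members of the selected classes.

    ``particle_blocks`` is a DataFrame with at least coordinate columns and
    a classNumber column; per-particle defoci are recomputed from the
    anisotropic model when one is supplied per micrograph.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = set(int(c) for c in selected_class_ids)
    if not selected:
        raise ValueError("empty class selection")
    df = particle_blocks[particle_blocks["classNumber"].astype(int)
                         .isin(selected)].copy()
    if aniso_models is not None and "rlnMicrographName" in df.columns:
        dfu, dfv = [], []
        for _, row in df.iterrows():
            model = aniso_models.get(row["rlnMicrographName"])
            if model is None:
                dfu.append(row.get("rlnDefocusU", np.nan))
                dfv.append(row.get("rlnDefocusV", np.nan))
            else:
                p = ctf_mod.evaluate_local_ctf(model, row["rlnCoordinateX"],
                                               row["rlnCoordinateY"])
                dfu.append(p.dfx * 1e4)
                dfv.append(p.dfy * 1e4)
        df["rlnDefocusU"] = dfu
        df["rlnDefocusV"] = dfv
    path = out_dir / "particles_selected.star"
    iof.write_star({"particles": df}, path)
    return path
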