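"""Ground-truthed synthetic tissue for end-to-end pipeline testing.

The generator emulates the statistical structure the decoder assumes:
multiple fields of view (FOVs) tiling a global frame with a configurable
overlap, non-overlapping circular cells on a jittered grid, per-cell
Poisson transcript counts, and per-round pseudo-color spot fields with

* isotropic Gaussian positional jitter per spot,
* independent per-spot dropout,
* false-positive spots as a spatial Poisson process with uniform random
  round and pseudo-color,
* rigid per-round registration shifts (recorded so they can be undone).

Every stage draws from a named substream of one master seed, so stages are
independently reproducible and every spot traces back to its ground-truth
transcript through the provenance map (false spots map to -1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from .codebook import Codebook

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlacementError",
    "simulate_tissue",
    "render_spots",
    "render_image",
    "render_images",
]

SPOT_COLUMNS = ["spot_id", "fov", "round", "color", "x", "y", "intensity"]

# substream labels hung off the master seed; one per stochastic stage
_STREAMS = {"cells": 1, "counts": 2, "placement": 3, "jitter": 4,
            "dropout": 5, "false": 6, "noise": 7}


class PlacementError(RuntimeError):
    """Cells cannot be placed without overlap at the requested density."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    All lengths are in pixels; coordinates are 0-based with origin at the
    top-left of each FOV, x rightward, y downward, sub-pixel floats.
    """

    n_fovs: int = 4
    fov_size_px: tuple[int, int] = (512, 512)  # (width, height)
    n_cells_per_fov: int = 50
    cell_radius_px: float = 12.0
    mean_counts_per_gene: float | np.ndarray = 0.08
    jitter_sigma_px: float = 0.0
    dropout_prob: float = 0.0
    false_spot_rate_per_px2: float = 0.0
    round_shifts_px: Optional[np.ndarray] = None  # (R, 2) as (dx, dy)
    fov_overlap_px: float = 0.0
    psf_sigma_px: float = 1.5
    background: float = 100.0
    amplitude: float = 500.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.false_spot_rate_per_px2 < 0:
            raise ValueError("false_spot_rate_per_px2 must be >= 0")
        if min(self.fov_size_px) <= 0 or self.n_fovs < 1:
            raise ValueError("sizes must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stage],))
        )


@dataclass
class GroundTruth:
    """True transcripts and cells; the yardstick for decoder recall/precision."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, fov, x, y, cell_id
    cells: pd.DataFrame  # cell_id, fov, label, x, y  (centroids, local px)
    masks: list[np.ndarray] = field(default_factory=list)
    fov_origins: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


def _fov_origins(cfg: SimulationConfig) -> np.ndarray:
    """FOVs tile a single row of the global frame, overlapping by fov_overlap_px."""
    w, _ = cfg.fov_size_px
    step = w - cfg.fov_overlap_px
    return np.array([[i * step, 0.0] for i in range(cfg.n_fovs)])


def simulate_tissue(cfg: SimulationConfig, cb: Codebook) -> GroundTruth:
    """Place cells and draw per-cell, per-gene Poisson transcript counts.

    Cells are disks of ``cell_radius_px`` centred on a jittered square grid
    whose pitch guarantees zero overlap; transcripts are uniform inside
    their cell.  Raises :class:`PlacementError` when the grid cannot hold
    ``n_cells_per_fov`` disks.
    """
    w, h = cfg.fov_size_px
    r = cfg.cell_radius_px
    pitch = 2.0 * r + 2.0
    nx, ny = int(w // pitch), int(h // pitch)
    if cfg.n_cells_per_fov > 0 and nx * ny < cfg.n_cells_per_fov:
        raise PlacementError(
            f"grid holds {nx * ny} cells of radius {r}, requested {cfg.n_cells_per_fov}"
        )

    genes = cb.gene_ids
    rates = np.broadcast_to(
        np.asarray(cfg.mean_counts_per_gene, dtype=float), (len(genes),)
    )

    rng_cells = cfg.rng("cells")
    rng_counts = cfg.rng("counts")
    rng_place = cfg.rng("placement")

    cell_rows, tx_rows, masks = [], [], []
    cell_counter = 0
    tx_counter = 0
    jitter_amp = pitch / 2.0 - r  # stay inside the grid cell: no overlap
    for fov in range(cfg.n_fovs):
        mask = np.zeros((h, w), dtype=np.int32)
        slots = [(ix, iy) for iy in range(ny) for ix in range(nx)]
        order = rng_cells.permutation(len(slots))[: cfg.n_cells_per_fov]
        for label, slot_i in enumerate(order, start=1):
            ix, iy = slots[slot_i]
            cx = (ix + 0.5) * pitch + rng_cells.uniform(-jitter_amp, jitter_amp)
            cy = (iy + 0.5) * pitch + rng_cells.uniform(-jitter_amp, jitter_amp)
            cell_id = f"fov{fov}_cell{label}"
            rr, cc = _disk((cy, cx), r, shape=mask.shape)
            mask[rr, cc] = label
            cell_rows.append((cell_id, fov, label, cx, cy))

            counts = rng_counts.poisson(rates)
            for g_idx in np.nonzero(counts)[0]:
                for _ in range(int(counts[g_idx])):
                    rad = r * math.sqrt(rng_place.uniform())
                    ang = rng_place.uniform(0.0, 2.0 * math.pi)
                    tx_rows.append(
                        (
                            tx_counter,
                            genes[g_idx],
                            fov,
                            cx + rad * math.cos(ang),
                            cy + rad * math.sin(ang),
                            cell_id,
                        )
                    )
                    tx_counter += 1
            cell_counter += 1
        masks.append(mask)

    transcripts = pd.DataFrame(
        tx_rows, columns=["transcript_id", "gene_id", "fov", "x", "y", "cell_id"]
    )
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "fov", "label", "x", "y"])
    return GroundTruth(
        transcripts=transcripts, cells=cells, masks=masks, fov_origins=_fov_origins(cfg)
    )


def render_spots(
    truth: GroundTruth, cb: Codebook, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit the multi-round spot table a detector would produce.

    Each transcript emits one spot per round at its position plus
    independent 2-D normal jitter, colored by its gene's codeword; each
    spot is independently deleted with ``dropout_prob``; false spots are a
    spatial Poisson process with uniform round and color; per-round rigid
    shifts are added last and recorded in ``cfg.round_shifts_px``.

    Returns the spot table and a provenance Series mapping spot_id to the
    source transcript_id (-1 for false spots).
    """
    R = cb.rounds
    w, h = cfg.fov_size_px
    shifts = (
        np.zeros((R, 2)) if cfg.round_shifts_px is None
        else np.asarray(cfg.round_shifts_px, dtype=float)
    )
    if shifts.shape != (R, 2):
        raise ValueError(f"round_shifts_px must have shape ({R}, 2)")

    rng_j = cfg.rng("jitter")
    rng_d = cfg.rng("dropout")
    rng_f = cfg.rng("false")

    rows, prov = [], []
    spot_id = 0
    codes = {g: cb.codeword_for(g).colors for g in cb.gene_ids}
    for rec in truth.transcripts.itertuples(index=False):
        colors = codes[rec.gene_id]
        for rnd in range(1, R + 1):
            jx, jy = rng_j.normal(0.0, cfg.jitter_sigma_px, size=2) if cfg.jitter_sigma_px > 0 else (0.0, 0.0)
            dropped = cfg.dropout_prob > 0 and rng_d.uniform() < cfg.dropout_prob
            if dropped:
                continue
            dx, dy = shifts[rnd - 1]
            rows.append(
                (
                    spot_id,
                    rec.fov,
                    rnd,
                    colors[rnd - 1],
                    rec.x + jx + dx,
                    rec.y + jy + dy,
                    1.0,
                )
            )
            prov.append(rec.transcript_id)
            spot_id += 1

    if cfg.false_spot_rate_per_px2 > 0:
        lam = cfg.false_spot_rate_per_px2 * w * h
        for fov in range(cfg.n_fovs):
            n_false = rng_f.poisson(lam)
            for _ in range(int(n_false)):
                rnd = int(rng_f.integers(1, R + 1))
                col = int(rng_f.integers(1, cb.palette_size + 1))
                x = rng_f.uniform(0, w) + shifts[rnd - 1, 0]
                y = rng_f.uniform(0, h) + shifts[rnd - 1, 1]
                rows.append((spot_id, fov, rnd, col, x, y, 1.0))
                prov.append(-1)
                spot_id += 1

    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    provenance = pd.Series(prov, index=spots["spot_id"], name="transcript_id")
    return spots, provenance


def render_image(
    spots: pd.DataFrame,
    shape: tuple[int, int],
    psf_sigma_px: float = 1.5,
    background: float = 100.0,
    amplitude: float = 500.0,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one channel: isotropic 2-D Gaussians on a constant background.

    ``shape`` is (height, width).  Each spot contributes
    amplitude·exp(−r²/2σ²) centred at its sub-pixel (x, y).
    """
    h, w = shape
    img = np.full((h, w), float(background))
    half = max(1, int(math.ceil(4 * psf_sigma_px)))
    for rec in spots.itertuples(index=False):
        x0, y0 = rec.x, rec.y
        cx, cy = int(round(x0)), int(round(y0))
        xs = np.arange(max(0, cx - half), min(w, cx + half + 1))
        ys = np.arange(max(0, cy - half), min(h, cy + half + 1))
        if len(xs) == 0 or len(ys) == 0:
            continue
        gx = np.exp(-((xs - x0) ** 2) / (2 * psf_sigma_px**2))
        gy = np.exp(-((ys - y0) ** 2) / (2 * psf_sigma_px**2))
        img[np.ix_(ys, xs)] += amplitude * np.outer(gy, gx)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img


def render_images(
    spots: pd.DataFrame, cfg: SimulationConfig, cb: Codebook
) -> dict[tuple[int, int, int], np.ndarray]:
    """Per-(fov, round, color) image stack for the whole spot table."""
    w, h = cfg.fov_size_px
    rng = cfg.rng("noise")
    out: dict[tuple[int, int, int], np.ndarray] = {}
    for fov in range(cfg.n_fovs):
        for rnd in range(1, cb.rounds + 1):
            for col in range(1, cb.palette_size + 1):
                sub = spots[
                    (spots["fov"] == fov)
                    & (spots["round"] == rnd)
                    & (spots["color"] == col)
                ]
                out[(fov, rnd, col)] = render_image(
                    sub,
                    (h, w),
                    psf_sigma_px=cfg.psf_sigma_px,
                    background=cfg.background,
                    amplitude=cfg.amplitude,
                    noise_sigma=cfg.noise_sigma,
                    rng=rng,
                )
    return out
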