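"""Round-to-round registration and classical spot detection.

Registration is restricted to rigid translation — the dominant drift mode
between hybridization rounds imaged at a fixed stage position — estimated
by phase cross-correlation with sub-pixel refinement against the round-0
nuclear (DAPI) image.

Spot detection is a Laplacian-of-Gaussian blob detector with 3×3
center-of-mass sub-pixel refinement.  It is a documented classical
stand-in for a learned detector: it honours the same spot-table contract
(fov, round, color, x, y, intensity) that the decoder consumes, but no
equivalence with any particular trained model is implied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

__all__ = ["Shift", "estimate_shift", "apply_shift", "detect_spots"]


@dataclass(frozen=True)
class Shift:
    """Translation (moving → reference), pixels; +x rightward, +y downward."""

    dx: float
    dy: float

    def __neg__(self) -> "Shift":
        return Shift(-self.dx, -self.dy)


def estimate_shift(
    reference_image: np.ndarray,
    moving_image: np.ndarray,
    upsample_factor: int = 100,
) -> Shift:
    """Translation aligning ``moving_image`` onto ``reference_image``.

    Phase cross-correlation, refined to sub-pixel resolution by local
    upsampling of the correlation peak.  Integer shifts of periodic copies
    are recovered exactly.

    Raises
    ------
    ValueError
        On shape mismatch or a flat (zero-variance) image, for which the
        correlation peak is undefined.
    """
    ref = np.asarray(reference_image, dtype=float)
    mov = np.asarray(moving_image, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("flat image: shift estimation is degenerate")
    (dy, dx), _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample_factor
    )
    return Shift(dx=float(dx), dy=float(dy))


def apply_shift(spots: pd.DataFrame, shift: Shift) -> pd.DataFrame:
    """Translate spot coordinates; all other columns pass through unchanged."""
    out = spots.copy()
    out["x"] = out["x"] + shift.dx
    out["y"] = out["y"] + shift.dy
    return out


def detect_spots(
    image: np.ndarray,
    log_sigma: float = 1.5,
    min_intensity: float = 0.0,
    min_distance: int = 2,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in a single channel image.

    Local maxima of the (sign-flipped, scale-normalised) Laplacian-of-
    Gaussian response are kept where the underlying image value reaches
    ``min_intensity``; each detection is refined to sub-pixel precision by
    the center of mass of the background-subtracted 3×3 neighbourhood.

    Returns a DataFrame with columns x, y, intensity (image value at the
    peak pixel); the caller attaches fov/round/color context.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    response = -gaussian_laplace(img, sigma=log_sigma) * log_sigma**2
    peaks = peak_local_max(
        response, min_distance=min_distance, exclude_border=False
    )
    rows = []
    h, w = img.shape
    for py, px in peaks:
        if img[py, px] < min_intensity:
            continue
        y0, y1 = max(0, py - 1), min(h, py + 2)
        x0, x1 = max(0, px - 1), min(w, px + 2)
        win = img[y0:y1, x0:x1] - img[y0:y1, x0:x1].min()
        total = win.sum()
        if total > 0:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            cy = float((ys * win).sum() / total)
            cx = float((xs * win).sum() / total)
        else:
            cy, cx = float(py), float(px)
        rows.append((cx, cy, float(img[py, px])))
    out = pd.DataFrame(rows, columns=["x", "y", "intensity"])
    return out.sort_values(["y", "x"], kind="mergesort").reset_index(drop=True)
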