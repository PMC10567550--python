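"""Fiber-network metrics on binary masks: skeleton total length and
gliding-box lacunarity.

Total length skeletonizes the mask and sums chain steps (1 px for orthogonal
neighbours, sqrt(2) px for diagonal neighbours whose corner is not already
bridged by an orthogonal pixel), scaled by the pixel size. Lacunarity slides
an r x r window at stride 1 and reports var(mass)/mean(mass)^2 + 1 per box
size r; a spatially homogeneous mask gives exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize

__all__ = [
    "ActinMetrics",
    "total_length",
    "lacunarity",
    "compute_metrics",
    "read_mask",
]

SQRT2 = float(np.sqrt(2.0))
DEFAULT_BOX_SIZES = (2, 4, 8, 16)


@dataclass
class ActinMetrics:
    total_length_um: float
    lacunarity_by_box: dict[int, float]
    mean_lacunarity: float
    px_size: float


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (values 0/1)")
    return mask.astype(bool)


def read_mask(path) -> np.ndarray:
    """Read a PNG/TIFF mask; nonzero pixels are foreground."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return (img > 0).astype(np.uint8)


def total_length(mask: np.ndarray, px_size: float = 1.0) -> float:
    """Skeleton chain length in µm.

    Orthogonally adjacent skeleton pixels contribute 1 px per step, diagonal
    pairs contribute sqrt(2) px unless the two pixels already share an
    orthogonal skeleton neighbour (which would double-count the corner).
    """
    mask = _check_binary(mask)
    if px_size <= 0:
        raise ValueError("px_size must be positive")
    if not mask.any():
        return 0.0
    sk = skeletonize(mask)
    length_px = 0.0
    # orthogonal pairs
    length_px += float(np.sum(sk[:, :-1] & sk[:, 1:]))
    length_px += float(np.sum(sk[:-1, :] & sk[1:, :]))
    # diagonal pairs not short-circuited by a shared orthogonal neighbour
    dn = sk[:-1, :-1] & sk[1:, 1:]  # ↘ pairs at (r, c)-(r+1, c+1)
    bridged = sk[:-1, 1:] | sk[1:, :-1]
    length_px += SQRT2 * float(np.sum(dn & ~bridged))
    up = sk[1:, :-1] & sk[:-1, 1:]  # ↗ pairs at (r+1, c)-(r, c+1)
    bridged_up = sk[:-1, :-1] | sk[1:, 1:]
    length_px += SQRT2 * float(np.sum(up & ~bridged_up))
    return length_px * px_size


def lacunarity(mask: np.ndarray, box_sizes=DEFAULT_BOX_SIZES) -> dict[int, float]:
    """Gliding-box lacunarity per box size.

    For each r, an r x r window slides at stride 1; with M the window mass
    (foreground count), Lambda(r) = var(M)/mean(M)^2 + 1.
    """
    mask = _check_binary(mask)
    if not mask.any():
        raise ValueError("all-zero mask: lacunarity undefined (mean mass 0)")
    out: dict[int, float] = {}
    for r in box_sizes:
        r = int(r)
        if r < 1 or r > min(mask.shape):
            raise ValueError(f"box size {r} exceeds mask dimensions {mask.shape}")
        view = np.lib.stride_tricks.sliding_window_view(mask.astype(np.int64), (r, r))
        mass = view.sum(axis=(2, 3)).ravel()
        mean = mass.mean()
        out[r] = float(mass.var() / mean ** 2 + 1.0)
    return out


def compute_metrics(mask: np.ndarray, px_size: float = 1.0,
                    box_sizes=None) -> ActinMetrics:
    mask = _check_binary(mask).astype(np.uint8)
    if box_sizes is None:
        box_sizes = [r for r in DEFAULT_BOX_SIZES if r <= min(mask.shape)]
    lac = lacunarity(mask, box_sizes)
    return ActinMetrics(
        total_length_um=total_length(mask, px_size),
        lacunarity_by_box=lac,
        mean_lacunarity=float(np.mean(list(lac.values()))),
        px_size=px_size,
    )
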