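"""Summarized raster representations of segmentation results.

Given a label map and (optionally) the anatomical image it was computed
from, compile a grid of slices across the requested planes with the
segmentation overlaid — solid colors at a chosen opacity or 1-pixel
contours — as a static PNG or an animated GIF with a fading overlay.

Rendering is fully deterministic: identical inputs and options yield
byte-identical files, which makes snapshots safe to diff and cache.
Volumes are reoriented to RAS on load, so axis 0/1/2 correspond to
sagittal/coronal/axial planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["SnapshotSpec", "select_slices", "render_grid", "animate",
           "plot_segment", "contour_mask", "PLANE_AXES"]

PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


class EmptySegmentationError(ValueError):
    """The label map contains no nonzero voxel."""


@dataclass
class SnapshotSpec:
    """Rendering options for a segmentation snapshot."""

    planes: tuple = ("axial",)
    n_slices: int = 9
    opacity: float = 0.5
    contours: bool = False
    animated: bool = False
    labels: Optional[tuple] = None       # subset of labels to render
    colormap: dict = field(default_factory=dict)  # label -> (r, g, b) 0-255
    rowsize: int = 3
    margin: int = 2
    min_voxels: int = 1
    n_frames: int = 11                   # animation frames (odd: peak mid-way)

    def __post_init__(self):
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError(f"opacity {self.opacity} outside [0, 1]")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        unknown = set(self.planes) - set(PLANE_AXES)
        if unknown:
            raise ValueError(f"unknown planes {sorted(unknown)}")


def _categorical_palette(labels) -> dict:
    """Stable categorical colors keyed by sorted label value (tab20)."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colormaps

    cmap = colormaps["tab20"]
    palette = {}
    for i, label in enumerate(sorted(labels)):
        r, g, b, _ = cmap(i % 20)
        palette[label] = (int(r * 255), int(g * 255), int(b * 255))
    return palette


def select_slices(seg: np.ndarray, plane: str, n: int,
                  min_voxels: int = 1) -> list:
    """Evenly spaced slice indices inside the segmentation's support.

    Within the bounding range of nonzero segmentation along the plane
    axis, pick ``n`` evenly spaced indices among slices holding at least
    ``min_voxels`` nonzero voxels; ``n=1`` picks the support midpoint.
    Fewer than ``n`` are returned when the support is narrow.
    """
    axis = PLANE_AXES[plane]
    other = tuple(i for i in range(seg.ndim) if i != axis)
    counts = (seg != 0).sum(axis=other)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise EmptySegmentationError("empty segmentation")
    candidates = [int(i) for i in range(nz[0], nz[-1] + 1)
                  if counts[i] >= min_voxels]
    if not candidates:
        candidates = [int(i) for i in nz]
    if n >= len(candidates):
        return candidates
    positions = np.linspace(0, len(candidates) - 1, n + 2)[1:-1]
    picked = []
    for p in positions:
        idx = candidates[int(round(p))]
        if idx not in picked:
            picked.append(idx)
    return picked


def contour_mask(label_slice: np.ndarray) -> np.ndarray:
    """Boundary pixels: labeled pixels with >=1 differing 4-neighbor in-slice.

    Pixels on the array border count their missing neighbors as different
    (the object touches the edge of the field of view).
    """
    padded = np.pad(label_slice, 1, mode="constant", constant_values=-1)
    center = padded[1:-1, 1:-1]
    differs = np.zeros_like(center, dtype=bool)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = padded[1 + dy:padded.shape[0] - 1 + dy,
                          1 + dx:padded.shape[1] - 1 + dx]
        differs |= neighbor != center
    return differs & (center != 0)


def _window(bg: np.ndarray) -> np.ndarray:
    """Grayscale window to the 1st-99th intensity percentiles."""
    lo, hi = np.percentile(bg, [1, 99])
    if hi <= lo:
        hi = lo + 1.0
    return np.clip((bg.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)


def _slice2d(vol: np.ndarray, axis: int, index: int) -> np.ndarray:
    sl = np.take(vol, index, axis=axis)
    return np.rot90(sl)  # display convention: superior up


def _render_slice(bg01: Optional[np.ndarray], seg2d: np.ndarray,
                  spec: SnapshotSpec, palette: dict) -> np.ndarray:
    """RGB float64 (H, W, 3) rendering of one slice."""
    h, w = seg2d.shape
    base = np.zeros((h, w, 3)) if bg01 is None else np.repeat(
        bg01[:, :, None], 3, axis=2)
    out = base.copy()
    seg = seg2d.copy()
    if spec.labels is not None:
        seg[~np.isin(seg, list(spec.labels))] = 0
    if spec.contours:
        paint = contour_mask(seg)
    else:
        paint = seg != 0
    for label in [l for l in np.unique(seg) if l != 0]:
        mask = (seg == label) & paint
        if not mask.any():
            continue
        color = np.array(palette[int(label)], dtype=np.float64) / 255.0
        out[mask] = (1.0 - spec.opacity) * base[mask] + spec.opacity * color
    return out


def _assemble(tiles: list, rowsize: int, margin: int) -> np.ndarray:
    """Lay slice tiles out into a row-major grid with black margins."""
    th = max(t.shape[0] for t in tiles)
    tw = max(t.shape[1] for t in tiles)
    padded = []
    for t in tiles:
        canvas = np.zeros((th, tw, 3))
        y0 = (th - t.shape[0]) // 2
        x0 = (tw - t.shape[1]) // 2
        canvas[y0:y0 + t.shape[0], x0:x0 + t.shape[1]] = t
        padded.append(canvas)
    nrows = (len(padded) + rowsize - 1) // rowsize
    grid = np.zeros((nrows * th + (nrows + 1) * margin,
                     rowsize * tw + (rowsize + 1) * margin, 3))
    for i, tile in enumerate(padded):
        r, c = divmod(i, rowsize)
        y = margin + r * (th + margin)
        x = margin + c * (tw + margin)
        grid[y:y + th, x:x + tw] = tile
    return grid


def render_grid(bg: Optional[np.ndarray], seg: np.ndarray,
                spec: SnapshotSpec) -> np.ndarray:
    """Render the snapshot grid as a uint8 RGB array.

    ``bg`` (if given) must share the segmentation's voxel grid — a shape
    mismatch is an error, never silently resampled.
    """
    if bg is not None and bg.shape != seg.shape:
        raise ValueError(f"background shape {bg.shape} != "
                         f"segmentation shape {seg.shape}")
    labels_present = [int(l) for l in np.unique(seg) if l != 0]
    palette = _categorical_palette(labels_present)
    palette.update({int(k): tuple(v) for k, v in spec.colormap.items()})
    bg01 = _window(bg) if bg is not None else None
    plane_grids = []
    for plane in spec.planes:
        axis = PLANE_AXES[plane]
        indices = select_slices(seg, plane, spec.n_slices, spec.min_voxels)
        tiles = []
        for idx in indices:
            seg2d = _slice2d(seg, axis, idx)
            bg2d = _slice2d(bg01, axis, idx) if bg01 is not None else None
            tiles.append(_render_slice(bg2d, seg2d, spec, palette))
        plane_grids.append(_assemble(tiles, spec.rowsize, spec.margin))
    width = max(g.shape[1] for g in plane_grids)
    stacked = []
    for g in plane_grids:
        if g.shape[1] < width:
            pad = np.zeros((g.shape[0], width - g.shape[1], 3))
            g = np.concatenate([g, pad], axis=1)
        stacked.append(g)
    out = np.concatenate(stacked, axis=0)
    return (np.clip(out, 0, 1) * 255).round().astype(np.uint8)


def animate(bg: Optional[np.ndarray], seg: np.ndarray,
            spec: SnapshotSpec) -> list:
    """Frame sequence with the overlay fading 0 -> peak opacity -> 0.

    The first frame equals the pure background rendering; with an odd
    frame count the middle frame equals the static render at peak opacity.
    """
    from dataclasses import replace

    n = spec.n_frames
    frames = []
    for i in range(n):
        ramp = 1.0 - abs(2.0 * i / (n - 1) - 1.0) if n > 1 else 1.0
        frames.append(render_grid(bg, seg, replace(spec, opacity=spec.opacity * ramp,
                                                   animated=False)))
    return frames


def _load_ras(path) -> np.ndarray:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    return np.asanyarray(img.dataobj)


def plot_segment(seg_path, bg_path=None, spec: Optional[SnapshotSpec] = None,
                 out_path=None) -> Path:
    """Read NIfTI inputs, render, and write a PNG (static) or GIF (animated).

    The main offscreen entry point, usable from scripts and the CLI.
    """
    from PIL import Image

    spec = spec or SnapshotSpec()
    seg = np.round(_load_ras(seg_path)).astype(np.int32)
    bg = _load_ras(bg_path).astype(np.float64) if bg_path else None
    if out_path is None:
        suffix = ".gif" if spec.animated else ".png"
        out_path = Path(str(seg_path)).with_suffix("").with_suffix("")
        out_path = out_path.parent / (out_path.name + "_snapshot" + suffix)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if spec.animated:
        import imageio.v3 as iio

        frames = animate(bg, seg, spec)
        iio.imwrite(out_path, frames, extension=".gif", loop=0, duration=120)
    else:
        Image.fromarray(render_grid(bg, seg, spec)).save(out_path, format="PNG")
    return out_path
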