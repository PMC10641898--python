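"""Rigid motion correction of widefield stacks and ROI trace extraction.

Motion correction follows an enhanced-cross-correlation scheme: a mean
reference image is contrast-enhanced (background removal with a wide
Gaussian, edge boosting with a difference of narrow Gaussians, z-scoring),
each frame is enhanced the same way, and the integer displacement is read
off the peak of their circular cross-correlation.  Trace extraction
averages each ROI's pixels and subtracts a surrounding background ring
that excludes other ROIs and the frame border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

# Printed field of view: 1.343 mm across 1,024 pixels.
UM_PER_PX = 1.343e3 / 1024.0


@dataclass
class RegistrationResult:
    shifts: np.ndarray  # (n_frames, 2) integer (dy, dx)
    reference: np.ndarray


@dataclass
class RoiSet:
    """Per-cell pixel masks and centroids, in reference-frame coordinates."""

    masks: list[np.ndarray]  # boolean (H, W) each
    centroids: np.ndarray  # (n, 2) as (x, y) pixels
    um_per_px: float = UM_PER_PX

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class FluorescenceTrace:
    """Normalized per-cell dF/F in [0, 1] sampled at ``fs`` Hz."""

    cell_id: int
    values: np.ndarray
    centroid: tuple[float, float] = (0.0, 0.0)  # (x, y) pixels
    fs: float = 20.0
    flagged: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def build_reference(frames: np.ndarray, n_frames: int = 2047) -> np.ndarray:
    """Pixelwise mean of the first ``min(n_frames, N)`` frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("expected a non-empty (N, H, W) stack")
    return frames[: min(n_frames, frames.shape[0])].mean(axis=0)


def enhance(
    image: np.ndarray,
    sigma_bg: float = 50.0,
    sigma_lo: float = 2.0,
    sigma_hi: float = 1.0,
    edge_gain: float = 100.0,
) -> np.ndarray:
    """Contrast-enhance an image for registration.

    The wide ``sigma_bg`` Gaussian estimate of the non-uniform background is
    removed; edges are the difference between the ``sigma_lo`` and
    ``sigma_hi`` blurred versions of the background-removed image, scaled by
    ``edge_gain`` and added to the ``sigma_lo`` blur; the result is
    z-normalized to remove photobleaching-induced intensity shifts.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    bgfree = img - gaussian_filter(img, sigma_bg)
    lo = gaussian_filter(bgfree, sigma_lo)
    hi = gaussian_filter(bgfree, sigma_hi)
    out = lo + edge_gain * (lo - hi)
    sd = out.std()
    if sd == 0:
        raise ValueError("zero-variance image cannot be enhanced")
    return (out - out.mean()) / sd


def register_frame(ref_enh: np.ndarray, frame_enh: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) such that the frame is the reference shifted by it.

    The corrective shift to apply to the raw frame is the negation.  Uses
    the peak of the circular FFT cross-correlation of the mean-subtracted
    enhanced images.
    """
    if ref_enh.shape != frame_enh.shape:
        raise ValueError("reference and frame must share a shape")
    a = ref_enh - ref_enh.mean()
    b = frame_enh - frame_enh.mean()
    corr = np.fft.irfft2(np.fft.rfft2(b) * np.conj(np.fft.rfft2(a)), s=a.shape)
    py, px = np.unravel_index(np.argmax(corr), corr.shape)
    h, w = a.shape
    dy = py if py <= h // 2 else py - h
    dx = px if px <= w // 2 else px - w
    return int(dy), int(dx)


def register_stack(frames: np.ndarray, **enhance_kw) -> tuple[np.ndarray, RegistrationResult]:
    """Motion-correct a stack; returns the corrected stack and the shift log."""
    frames = np.asarray(frames, dtype=float)
    ref = build_reference(frames)
    ref_enh = enhance(ref, **enhance_kw)
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    corrected = np.empty_like(frames)
    for k, frame in enumerate(frames):
        dy, dx = register_frame(ref_enh, enhance(frame, **enhance_kw))
        shifts[k] = (dy, dx)
        corrected[k] = np.roll(frame, (-dy, -dx), axis=(0, 1))
    return corrected, RegistrationResult(shifts=shifts, reference=ref)


@dataclass
class RawTrace:
    values: np.ndarray
    flagged_empty_ring: bool = False


def extract_trace(
    video: np.ndarray,
    roi_index: int,
    rois: RoiSet,
    inner_px: float = 15.0,
    outer_px: float = 50.0,
    border_px: int = 25,
) -> RawTrace:
    """Background-subtracted raw fluorescence for one ROI.

    The per-frame ROI mean has the per-frame mean of a background ring
    subtracted.  The ring is centred on the ROI centroid with radii
    ``inner_px``..``outer_px`` and excludes pixels of any other ROI and a
    ``border_px`` margin at each frame edge (registration leaves bright
    strips there).  If nothing survives the exclusions the raw ROI mean is
    returned flagged, with no background removed.
    """
    video = np.asarray(video, dtype=float)
    _, h, w = video.shape
    mask = rois.masks[roi_index]
    if mask.shape != (h, w):
        raise ValueError("ROI mask does not match the frame shape")
    cx, cy = rois.centroids[roi_index]
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)
    ring = (r >= inner_px) & (r <= outer_px)
    for j, other in enumerate(rois.masks):
        if j != roi_index:
            ring &= ~other
    ring &= ~mask
    ring[:border_px, :] = False
    ring[-border_px:, :] = False
    ring[:, :border_px] = False
    ring[:, -border_px:] = False
    roi_mean = video[:, mask].mean(axis=1)
    if not ring.any():
        return RawTrace(values=roi_mean, flagged_empty_ring=True)
    bg_mean = video[:, ring].mean(axis=1)
    return RawTrace(values=roi_mean - bg_mean)


def normalize_trace(
    raw: np.ndarray,
    fs_in: float,
    fs_target: float = 20.0,
    cell_id: int = 0,
    centroid: tuple[float, float] = (0.0, 0.0),
) -> FluorescenceTrace:
    """Interpolate to ``fs_target`` Hz, linearly detrend, min-max scale to [0, 1]."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 samples")
    t_in = np.arange(raw.size) / fs_in
    t_out = np.arange(0.0, t_in[-1] + 0.5 / fs_target, 1.0 / fs_target)
    x = np.interp(t_out, t_in, raw)
    x = signal.detrend(x, type="linear")
    lo, hi = x.min(), x.max()
    if hi - lo <= 1e-12:
        raise ValueError("constant trace cannot be normalized")
    return FluorescenceTrace(
        cell_id=cell_id, values=(x - lo) / (hi - lo), centroid=centroid, fs=fs_target
    )
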