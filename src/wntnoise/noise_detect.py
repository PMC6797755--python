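"""Noise-pixel detection in reporter time-lapse stacks.

The classifier labels a pixel High when its intensity exceeds twice (the
configurable ``fold_threshold``) the statistic of its neighbouring in-embryo
pixels, and Low when it falls below half of it, frame by frame.  A temporal
persistence filter then keeps only pixel runs lasting at least ``min_frames``
frames *and* strictly more than ``min_duration_min`` minutes — these are the
physiological noise events.  Single-frame excursions are tallied separately as
transients (cosmic rays, detector noise) and excluded from the event list.

Pixels are tracked at fixed coordinates; there is no registration or cell
tracking.  All thresholds are ratios, so detection is invariant to a global
intensity rescaling of the stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImageStack",
    "NoiseParams",
    "NoiseEvent",
    "embryo_mask",
    "neighbour_stat",
    "classify_frame",
    "persistence_filter",
    "detect",
    "time_course_frame",
    "events_to_frame",
]

HIGH, LOW, NONE = 1, -1, 0


@dataclass(frozen=True)
class ImageStack:
    """A single-channel T×Y×X stack with physical calibration."""

    data: np.ndarray
    pixel_size_um: float = 6.5
    frame_interval_min: float = 3.5

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("stack must be a T×Y×X array with T >= 1")
        if np.any(arr < 0):
            raise ValueError("stack intensities must be nonnegative")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass(frozen=True)
class NoiseParams:
    """Classifier and persistence-filter parameters.

    Defaults implement the two-fold / ≥2-frame / >6-minute rule: strict
    inequalities throughout, so a fold of exactly ``fold_threshold`` is not
    noise.  ``neighbourhood_radius_px`` = 1 compares each pixel with its
    8-connected ring; ``neighbour_stat`` may be the masked mean (default) or
    median.  ``mask_quantile`` sets the automatic background threshold.
    """

    fold_threshold: float = 2.0
    min_frames: int = 2
    min_duration_min: float = 6.0
    neighbourhood_radius_px: int = 1
    neighbour_stat: Literal["mean", "median"] = "mean"
    mask_quantile: float = 0.1

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.neighbourhood_radius_px < 1:
            raise ValueError("neighbourhood_radius_px must be >= 1")
        if self.neighbour_stat not in ("mean", "median"):
            raise ValueError("neighbour_stat must be 'mean' or 'median'")
        if not 0 <= self.mask_quantile < 1:
            raise ValueError("mask_quantile must lie in [0, 1)")


@dataclass(frozen=True)
class NoiseEvent:
    """A persistent High/Low run at one pixel."""

    x: int
    y: int
    event_class: str  # "High" or "Low"
    start_frame: int
    end_frame: int
    peak_fold: float  # max fold for High runs, min fold for Low runs

    @property
    def run_length(self) -> int:
        return self.end_frame - self.start_frame + 1


def embryo_mask(stack: ImageStack, params: NoiseParams = NoiseParams()) -> np.ndarray:
    """Automatic per-frame embryo mask by intensity quantile.

    Pixels strictly above the per-frame ``mask_quantile`` intensity quantile,
    morphologically closed.  A constant positive frame masks fully; an
    all-zero frame yields an empty mask.  Supply an explicit mask to
    :func:`detect` to override this heuristic.
    """
    masks = np.zeros(stack.data.shape, dtype=bool)
    for t, frame in enumerate(stack.data):
        thr = np.quantile(frame, params.mask_quantile)
        m = frame > thr
        if not m.any() and frame.max() > 0:
            m = frame >= thr  # constant positive frame
        if m.any():
            # edge-pad before closing so the border is not eroded away
            p = np.pad(m, 1, mode="edge")
            p = ndimage.binary_closing(p, structure=np.ones((3, 3), bool))
            m = p[1:-1, 1:-1]
        masks[t] = m
    return masks


def neighbour_stat(
    frame: np.ndarray, mask: np.ndarray, params: NoiseParams = NoiseParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel statistic of masked neighbours (pixel itself excluded).

    The neighbourhood is the square ring of Chebyshev radius 1 to
    ``neighbourhood_radius_px``.  Returns ``(stat, has_neighbour)``; the
    statistic is undefined (0, flagged) where no masked neighbour exists.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    r = params.neighbourhood_radius_px
    k = 2 * r + 1
    footprint = np.ones((k, k), dtype=bool)
    footprint[r, r] = False
    if params.neighbour_stat == "mean":
        kernel = footprint.astype(float)
        num = ndimage.convolve(frame * mask, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
        has = den > 0.5
        stat = np.zeros_like(frame)
        np.divide(num, den, out=stat, where=has)
        return stat, has
    # masked median via a padded window scan; adequate for the small radii used
    pad = np.full((frame.shape[0] + 2 * r, frame.shape[1] + 2 * r), np.nan)
    pad[r:-r, r:-r] = np.where(mask, frame, np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(pad, (k, k))
    flat = windows.reshape(frame.shape[0], frame.shape[1], k * k)
    centre = r * k + r
    flat = np.delete(flat, centre, axis=2)
    has = ~np.all(np.isnan(flat), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        stat = np.nanmedian(flat, axis=2)
    stat = np.where(has, stat, 0.0)
    return stat, has


def classify_frame(
    frame: np.ndarray, mask: np.ndarray, params: NoiseParams = NoiseParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Label each masked pixel High / Low / none against its neighbourhood.

    Returns ``(labels, folds)``: labels ∈ {+1 High, −1 Low, 0 none}; the fold
    map stores pixel/statistic (1 where undefined, +inf where the statistic is
    zero but the pixel is positive — such pixels are labelled High and should
    be reviewed).
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    stat, has = neighbour_stat(frame, mask, params)
    labels = np.zeros(frame.shape, dtype=np.int8)
    folds = np.ones(frame.shape, dtype=float)
    valid = mask & has
    pos_stat = valid & (stat > 0)
    np.divide(frame, stat, out=folds, where=pos_stat)
    zero_stat = valid & (stat == 0) & (frame > 0)
    folds[zero_stat] = np.inf
    labels[pos_stat & (folds > params.fold_threshold)] = HIGH
    labels[pos_stat & (folds < 1.0 / params.fold_threshold)] = LOW
    labels[zero_stat] = HIGH
    return labels, folds


def persistence_filter(
    labels: np.ndarray,
    folds: np.ndarray,
    params: NoiseParams = NoiseParams(),
    frame_interval_min: float = 3.5,
) -> tuple[list[NoiseEvent], np.ndarray, list[NoiseEvent]]:
    """Split per-pixel call runs into events, transients and short runs.

    A maximal same-class consecutive run of length k is an event when
    k ≥ min_frames and k·frame_interval_min > min_duration_min (strictly).
    Length-1 runs failing the criteria are transients, tallied at their frame.
    Runs of length ≥ 2 failing only the duration test are dropped but returned
    separately for audit.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be T×Y×X")
    n_frames = labels.shape[0]
    transients = np.zeros(n_frames, dtype=int)
    events: list[NoiseEvent] = []
    dropped: list[NoiseEvent] = []
    active = np.argwhere((labels != 0).any(axis=0))
    for y, x in active:
        col = labels[:, y, x]
        t = 0
        while t < n_frames:
            cls = col[t]
            if cls == 0:
                t += 1
                continue
            t0 = t
            while t + 1 < n_frames and col[t + 1] == cls:
                t += 1
            k = t - t0 + 1
            run_folds = folds[t0 : t + 1, y, x]
            peak = float(np.max(run_folds) if cls == HIGH else np.min(run_folds))
            ev = NoiseEvent(
                x=int(x),
                y=int(y),
                event_class="High" if cls == HIGH else "Low",
                start_frame=int(t0),
                end_frame=int(t),
                peak_fold=peak,
            )
            if k >= params.min_frames and k * frame_interval_min > params.min_duration_min:
                events.append(ev)
            elif k == 1:
                transients[t0] += 1
            else:
                dropped.append(ev)
            t += 1
    events.sort(key=lambda e: (e.start_frame, e.y, e.x))
    return events, transients, dropped


def time_course_frame(
    events: list[NoiseEvent], transients: np.ndarray, n_frames: int
) -> pd.DataFrame:
    """Per-frame counts of active High/Low event pixels and new transients."""
    high = np.zeros(n_frames, dtype=int)
    low = np.zeros(n_frames, dtype=int)
    for e in events:
        tgt = high if e.event_class == "High" else low
        tgt[e.start_frame : e.end_frame + 1] += 1
    return pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "high_px": high,
            "low_px": low,
            "transients": np.asarray(transients, dtype=int),
        }
    )


def detect(
    stack: ImageStack,
    params: NoiseParams = NoiseParams(),
    mask: np.ndarray | None = None,
) -> tuple[list[NoiseEvent], pd.DataFrame]:
    """Classify every frame, persistence-filter, and tally the time course.

    ``mask`` may be a single Y×X embryo mask or a per-frame T×Y×X mask; when
    omitted the automatic quantile mask is used.
    """
    if stack.n_frames < params.min_frames:
        raise ValueError(
            f"stack too short: {stack.n_frames} frames < min_frames={params.min_frames}"
        )
    if mask is None:
        masks = embryo_mask(stack, params)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            masks = np.broadcast_to(mask, stack.data.shape)
        elif mask.shape == stack.data.shape:
            masks = mask
        else:
            raise ValueError("mask must be Y×X or T×Y×X matching the stack")
    labels = np.zeros(stack.data.shape, dtype=np.int8)
    folds = np.ones(stack.data.shape, dtype=float)
    for t in range(stack.n_frames):
        labels[t], folds[t] = classify_frame(stack.data[t], masks[t], params)
    events, transients, _ = persistence_filter(
        labels, folds, params, stack.frame_interval_min
    )
    return events, time_course_frame(events, transients, stack.n_frames)


def events_to_frame(events: list[NoiseEvent]) -> pd.DataFrame:
    """Events as a tidy table (0-based pixel and frame indices)."""
    return pd.DataFrame(
        [
            {
                "x": e.x,
                "y": e.y,
                "event_class": e.event_class,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "peak_fold": e.peak_fold,
            }
            for e in events
        ],
        columns=["x", "y", "event_class", "start_frame", "end_frame", "peak_fold"],
    )
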