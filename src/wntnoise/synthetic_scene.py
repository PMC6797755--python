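"""Synthetic reporter time-lapse scenes with planted ground truth.

This module emulates the statistical structure of single-channel luminescence
time-lapse imaging of a morphogen-reporter gradient in an early embryo:

* a monotone anterior→posterior intensity gradient (the baseline field),
* sparsely appearing "unfit" cells whose reporter output deviates from the
  local field by a multiplicative fold (High: fold > threshold; Low: fold
  below its reciprocal) and that persist for a bounded, possibly apoptosis-
  terminated, number of frames,
* single-frame spikes standing in for cosmic rays and detector artefacts,
* optional Gaussian or Poisson (shot) detector noise.

Every planted feature is recorded in a :class:`GroundTruth` so downstream
detection can be scored against a known answer.  A companion generator builds
toy differential-expression tables with planted condition-specific hits.

At the default calibration (6.5 μm pixels, ~10 μm deep-cell diameter) one
unfit cell covers a single pixel, which is exactly the scale at which the
noise-pixel classifier operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import distance_from_posterior_px, validate_ap_axis

__all__ = [
    "SimConfig",
    "PlantedEvent",
    "GroundTruth",
    "SimScene",
    "make_gradient_field",
    "spawn_events",
    "plant_exact_events",
    "render_stack",
    "simulate_scene",
    "score_detection",
    "make_de_table",
    "make_cell_table",
    "MOSAIC",
    "UBIQUITOUS",
]

GradientKind = Literal["exponential", "linear", "constant"]
NoiseModel = Literal["none", "gaussian", "poisson"]

# contrast names used throughout the DE-table machinery
MOSAIC = "mosaic_vs_uninjected"
UBIQUITOUS = "ubiquitous_vs_uninjected"


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic scene.

    Intensity units are arbitrary; spatial calibration is μm per pixel and
    temporal calibration minutes per frame.  ``ap_axis`` names the image axis
    along which posterior position increases.  The frame interval default of
    3.5 min makes a two-frame run span 7 min, i.e. strictly more than the
    6-minute persistence cut used by the detector.
    """

    width_px: int = 100
    height_px: int = 100
    pixel_size_um: float = 6.5
    frame_interval_min: float = 3.5
    n_frames: int = 40
    gradient_kind: GradientKind = "exponential"
    posterior_level: float = 200.0
    anterior_level: float = 20.0
    decay_length_um: float = 150.0
    ap_axis: str = "x+"
    cell_diameter_um: float = 10.0
    unfit_rate: float = 0.5
    unfit_fold_min: float = 2.5
    unfit_fold_max: float = 4.0
    unfit_class_prob_high: float = 0.5
    elimination_rate: float = 0.1
    max_lifetime_frames: int = 12
    spike_rate: float = 1.0
    noise_model: NoiseModel = "gaussian"
    noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1 or self.n_frames < 1:
            raise ValueError("image dimensions and n_frames must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")
        validate_ap_axis(self.ap_axis)
        if self.gradient_kind not in ("exponential", "linear", "constant"):
            raise ValueError(f"unknown gradient_kind {self.gradient_kind!r}")
        if self.gradient_kind == "exponential" and self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be positive for an exponential gradient")
        if not (self.posterior_level >= self.anterior_level > 0):
            raise ValueError("require posterior_level >= anterior_level > 0")
        for name in ("unfit_rate", "spike_rate", "elimination_rate", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.unfit_fold_min > 1:
            raise ValueError("unfit_fold_min must exceed 1")
        if self.unfit_fold_max < self.unfit_fold_min:
            raise ValueError("unfit_fold_max must be >= unfit_fold_min")
        for name in ("unfit_class_prob_high", "elimination_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_lifetime_frames < 1:
            raise ValueError("max_lifetime_frames must be >= 1")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "poisson" and self.noise_scale <= 0:
            raise ValueError("poisson noise requires a positive photon scaling")

    @property
    def cell_radius_px(self) -> float:
        """Physical cell radius in pixels (diameter/2 ÷ pixel size)."""
        return self.cell_diameter_um / (2.0 * self.pixel_size_um)


@dataclass(frozen=True)
class PlantedEvent:
    """One planted multiplicative deviation: an unfit cell or a spike."""

    x: int
    y: int
    event_class: str  # "High", "Low" or "Transient"
    fold: float
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        if self.event_class == "Transient" and self.start_frame != self.end_frame:
            raise ValueError("Transient events are single-frame")
        if self.event_class not in ("High", "Low", "Transient"):
            raise ValueError(f"unknown event_class {self.event_class!r}")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class GroundTruth:
    """Planted events plus the configuration that produced them."""

    events: tuple[PlantedEvent, ...]
    config: SimConfig

    @property
    def persistent(self) -> tuple[PlantedEvent, ...]:
        return tuple(e for e in self.events if e.event_class != "Transient")

    @property
    def transients(self) -> tuple[PlantedEvent, ...]:
        return tuple(e for e in self.events if e.event_class == "Transient")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x": e.x,
                    "y": e.y,
                    "event_class": e.event_class,
                    "fold": e.fold,
                    "start_frame": e.start_frame,
                    "end_frame": e.end_frame,
                }
                for e in self.events
            ],
            columns=["x", "y", "event_class", "fold", "start_frame", "end_frame"],
        )


def make_gradient_field(config: SimConfig) -> np.ndarray:
    """Baseline 2-D intensity field, monotone from posterior to anterior.

    Exponential: I(d) = posterior_level·exp(−d/decay_length_um) floored at
    anterior_level, with d the distance (μm) from the posterior edge.  Linear:
    a ramp from posterior_level at the posterior edge reaching anterior_level
    over the full axis span.  Constant: posterior_level everywhere.
    """
    shape = (config.height_px, config.width_px)
    if config.gradient_kind == "constant":
        return np.full(shape, float(config.posterior_level))
    d_um = distance_from_posterior_px(shape, config.ap_axis) * config.pixel_size_um
    if config.gradient_kind == "exponential":
        out = config.posterior_level * np.exp(-d_um / config.decay_length_um)
        return np.maximum(out, config.anterior_level)
    # linear ramp over the full span (one pixel beyond the last column), so a
    # 50-px ramp from 200 to 100 reads 150 exactly at column 25 from posterior
    span_um = (
        max(config.width_px, 1) if config.ap_axis[0] == "x" else max(config.height_px, 1)
    ) * config.pixel_size_um
    frac = d_um / span_um
    return config.posterior_level + (config.anterior_level - config.posterior_level) * frac


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one master seed; sub-streams keyed by purpose (0 = events, 1 = detector noise)
    return np.random.default_rng([int(config.seed), stream])


def _geometric_lifetime(u: float, rate: float, max_lifetime: int) -> int:
    """Lifetime in frames: 1 + min(G, max−1), G ~ Geometric(rate) failures.

    The geometric draw comes from a single uniform through the inverse CDF so
    that every elimination rate consumes exactly one stream value; rate 0 maps
    to an unbounded G (capped by max_lifetime).
    """
    if rate <= 0:
        g = max_lifetime - 1
    elif rate >= 1:
        g = 0
    else:
        g = int(math.floor(math.log(max(u, 1e-300)) / math.log1p(-rate)))
    return 1 + min(g, max_lifetime - 1)


def spawn_events(config: SimConfig) -> GroundTruth:
    """Draw the planted events of a scene; deterministic given the seed.

    Persistent (unfit-cell) event count ~ Poisson(unfit_rate·n_frames); spike
    count ~ Poisson(spike_rate·n_frames).  Positions are uniform with the cell
    disc kept inside the frame; folds are uniform in [unfit_fold_min,
    unfit_fold_max] (reciprocal for Low).
    """
    rng = _rng(config, 0)
    margin = int(math.ceil(config.cell_radius_px))
    xlo, xhi = margin, config.width_px - 1 - margin
    ylo, yhi = margin, config.height_px - 1 - margin
    if xhi < xlo or yhi < ylo:
        raise ValueError("image too small for the configured cell size")

    events: list[PlantedEvent] = []
    n_persistent = rng.poisson(config.unfit_rate * config.n_frames)
    for _ in range(n_persistent):
        x = int(rng.integers(xlo, xhi + 1))
        y = int(rng.integers(ylo, yhi + 1))
        start = int(rng.integers(0, config.n_frames))
        is_high = rng.random() < config.unfit_class_prob_high
        fold = float(rng.uniform(config.unfit_fold_min, config.unfit_fold_max))
        if not is_high:
            fold = 1.0 / fold
        life = _geometric_lifetime(
            rng.random(), config.elimination_rate, config.max_lifetime_frames
        )
        end = min(start + life - 1, config.n_frames - 1)
        events.append(
            PlantedEvent(x, y, "High" if is_high else "Low", fold, start, end)
        )

    n_spikes = rng.poisson(config.spike_rate * config.n_frames)
    for _ in range(n_spikes):
        x = int(rng.integers(xlo, xhi + 1))
        y = int(rng.integers(ylo, yhi + 1))
        t = int(rng.integers(0, config.n_frames))
        is_high = rng.random() < config.unfit_class_prob_high
        fold = float(rng.uniform(config.unfit_fold_min, config.unfit_fold_max))
        if not is_high:
            fold = 1.0 / fold
        events.append(PlantedEvent(x, y, "Transient", fold, t, t))

    return GroundTruth(tuple(events), config)


def plant_exact_events(
    config: SimConfig,
    n_persistent: int,
    persistent_frames: int,
    persistent_fold: float,
    n_spikes: int,
    spike_fold: float = 3.0,
    min_separation_px: int = 5,
    seed: int | None = None,
) -> GroundTruth:
    """Plant exact numbers of well-separated events (benchmark scenes).

    Events are placed on distinct pixels at least ``min_separation_px`` apart
    (Chebyshev), so their classifier neighbourhoods never interact and each
    planted feature maps to exactly one detectable pixel run.  Low events are
    requested by passing a fold < 1.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    margin = int(math.ceil(config.cell_radius_px)) + 1
    taken: list[tuple[int, int]] = []

    def place() -> tuple[int, int]:
        for _ in range(100_000):
            x = int(rng.integers(margin, config.width_px - margin))
            y = int(rng.integers(margin, config.height_px - margin))
            if all(
                max(abs(x - tx), abs(y - ty)) >= min_separation_px for tx, ty in taken
            ):
                taken.append((x, y))
                return x, y
        raise ValueError("could not place events with the requested separation")

    if persistent_frames > config.n_frames:
        raise ValueError("persistent_frames exceeds the movie length")
    events: list[PlantedEvent] = []
    cls = "High" if persistent_fold > 1 else "Low"
    for _ in range(n_persistent):
        x, y = place()
        start = int(rng.integers(0, config.n_frames - persistent_frames + 1))
        events.append(
            PlantedEvent(x, y, cls, persistent_fold, start, start + persistent_frames - 1)
        )
    for _ in range(n_spikes):
        x, y = place()
        t = int(rng.integers(0, config.n_frames))
        events.append(PlantedEvent(x, y, "Transient", spike_fold, t, t))
    return GroundTruth(tuple(events), config)


def _disc_indices(
    x: int, y: int, radius_px: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    r = max(radius_px, 0.0)
    ri = int(math.floor(r))
    ys, xs = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    inside = ys**2 + xs**2 <= r**2
    yy = ys[inside] + y
    xx = xs[inside] + x
    ok = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    return yy[ok], xx[ok]


def render_stack(field: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Forward model: field per frame, event discs multiplied by their fold,
    then detector noise.

    Overlapping discs are resolved in favour of the most recently started
    event (later starts are applied last, deterministically).
    """
    config = truth.config
    if field.shape != (config.height_px, config.width_px):
        raise ValueError("field and ground truth disagree on geometry")
    stack = np.repeat(field[None, :, :].astype(float), config.n_frames, axis=0)
    radius = config.cell_radius_px
    order = sorted(range(len(truth.events)), key=lambda i: (truth.events[i].start_frame, i))
    for i in order:
        e = truth.events[i]
        yy, xx = _disc_indices(e.x, e.y, radius, field.shape)
        for t in range(e.start_frame, min(e.end_frame, config.n_frames - 1) + 1):
            stack[t, yy, xx] = field[yy, xx] * e.fold

    if config.noise_model == "gaussian":
        rng = _rng(config, 1)
        stack = stack + rng.normal(0.0, 1.0, stack.shape) * (config.noise_scale * stack)
        stack = np.clip(stack, 0.0, None)
    elif config.noise_model == "poisson":
        rng = _rng(config, 1)
        stack = rng.poisson(stack * config.noise_scale).astype(float) / config.noise_scale
    return stack


@dataclass(frozen=True)
class SimScene:
    """A rendered scene bundle: stack, baseline field, truth and embryo mask."""

    stack: np.ndarray  # T×Y×X
    field: np.ndarray  # Y×X
    truth: GroundTruth
    embryo_mask: np.ndarray  # Y×X bool (synthetic embryos fill the frame)

    @property
    def config(self) -> SimConfig:
        return self.truth.config


def simulate_scene(config: SimConfig, truth: GroundTruth | None = None) -> SimScene:
    """Generate field + events + rendered stack in one call."""
    field = make_gradient_field(config)
    if truth is None:
        truth = spawn_events(config)
    stack = render_stack(field, truth)
    mask = np.ones(field.shape, dtype=bool)
    return SimScene(stack=stack, field=field, truth=truth, embryo_mask=mask)


def score_detection(
    truth: GroundTruth,
    events: Sequence,
    fold_threshold: float = 2.0,
    min_frames: int = 2,
    min_duration_min: float = 6.0,
    match_radius_px: float | None = None,
) -> dict:
    """Recall/precision of detected pixel runs against planted events.

    A planted persistent event is *detectable* when |log fold| exceeds
    log fold_threshold and its lifetime satisfies both persistence criteria.
    A detected event matches a planted one when it lies within the planted
    disc dilated by one pixel and the frame spans overlap.  Precision counts
    detected events lying within any planted (persistent or transient)
    footprint.
    """
    config = truth.config
    if match_radius_px is None:
        match_radius_px = config.cell_radius_px + 1.0

    def detectable(e: PlantedEvent) -> bool:
        if abs(math.log(e.fold)) <= math.log(fold_threshold):
            return False
        k = e.duration_frames
        return k >= min_frames and k * config.frame_interval_min > min_duration_min

    targets = [e for e in truth.persistent if detectable(e)]
    matched_targets: set[int] = set()
    matched_detected = 0
    for det in events:
        hit = False
        for i, tgt in enumerate(targets):
            if (
                math.hypot(det.x - tgt.x, det.y - tgt.y) <= match_radius_px
                and det.start_frame <= tgt.end_frame
                and det.end_frame >= tgt.start_frame
            ):
                matched_targets.add(i)
                hit = True
        if not hit:
            # near any planted footprint at all (incl. non-detectable / spikes)?
            for tgt in truth.events:
                if math.hypot(det.x - tgt.x, det.y - tgt.y) <= match_radius_px:
                    hit = True
                    break
        matched_detected += hit
    recall = len(matched_targets) / len(targets) if targets else 1.0
    precision = matched_detected / len(events) if events else 1.0
    return {
        "n_detectable": len(targets),
        "n_detected": len(events),
        "recall": recall,
        "precision": precision,
    }


# ---------------------------------------------------------------------------
# toy differential-expression tables


def make_de_table(
    n_genes: int,
    n_mosaic_specific: int,
    n_shared: int,
    seed: int,
    fdr_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy two-contrast DE table with planted condition-specific hits.

    Returns ``(records, truth)``: ``records`` is tidy with one row per
    (gene, contrast) and columns gene_id / contrast / log2_fold_change / fdr;
    ``truth`` labels each gene mosaic_specific, shared or null with its
    planted direction.  FDR values are drawn well clear of the threshold on
    either side, so a gate at ``fdr_threshold`` recovers the planted sets
    exactly.
    """
    if n_mosaic_specific + n_shared > n_genes:
        raise ValueError("planted hits exceed the number of genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    mosaic_ids = set(order[:n_mosaic_specific])
    shared_ids = set(order[n_mosaic_specific : n_mosaic_specific + n_shared])

    sig_lo, sig_hi = 1e-4, fdr_threshold * 0.5
    null_lo, null_hi = min(fdr_threshold + 0.05, 0.98), 0.99

    rec_rows, truth_rows = [], []
    for i, g in enumerate(genes):
        direction = int(rng.choice([-1, 1]))
        lfc = direction * float(rng.uniform(0.5, 3.0))
        if i in mosaic_ids:
            label = "mosaic_specific"
            fdr_m = float(rng.uniform(sig_lo, sig_hi))
            fdr_u = float(rng.uniform(null_lo, null_hi))
            lfc_m, lfc_u = lfc, float(rng.normal(0.0, 0.1))
        elif i in shared_ids:
            label = "shared"
            fdr_m = float(rng.uniform(sig_lo, sig_hi))
            fdr_u = float(rng.uniform(sig_lo, sig_hi))
            lfc_m = lfc_u = lfc
        else:
            label = "null"
            direction = 0
            fdr_m = float(rng.uniform(null_lo, null_hi))
            fdr_u = float(rng.uniform(null_lo, null_hi))
            lfc_m = float(rng.normal(0.0, 0.1))
            lfc_u = float(rng.normal(0.0, 0.1))
        rec_rows.append((g, MOSAIC, lfc_m, fdr_m))
        rec_rows.append((g, UBIQUITOUS, lfc_u, fdr_u))
        truth_rows.append((g, label, direction))

    records = pd.DataFrame(
        rec_rows, columns=["gene_id", "contrast", "log2_fold_change", "fdr"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "label", "direction"])
    return records, truth


# ---------------------------------------------------------------------------
# toy cell tables (AP-binned marker frequencies)


def make_cell_table(
    n_embryos: int,
    cells_per_embryo: int,
    bin_marker_probs: Sequence[float],
    seed: int,
    ap_extent_um: float = 650.0,
) -> pd.DataFrame:
    """Point-annotated cells with a planted AP-bin-dependent marker rate.

    Cells are scattered uniformly along an AP span split into
    ``len(bin_marker_probs)`` equal bins; each cell is marker-positive with
    the probability of its bin.  All cells belong to the labelled population.
    """
    probs = np.asarray(bin_marker_probs, dtype=float)
    if probs.ndim != 1 or len(probs) < 1 or np.any((probs < 0) | (probs > 1)):
        raise ValueError("bin_marker_probs must be probabilities")
    rng = np.random.default_rng(seed)
    rows = []
    n_bins = len(probs)
    for emb in range(n_embryos):
        x = rng.uniform(0.0, ap_extent_um, size=cells_per_embryo)
        y = rng.uniform(0.0, ap_extent_um / 2, size=cells_per_embryo)
        b = np.minimum((x / ap_extent_um * n_bins).astype(int), n_bins - 1)
        marker = rng.random(cells_per_embryo) < probs[b]
        for xi, yi, mi in zip(x, y, marker):
            rows.append((f"embryo_{emb:03d}", float(xi), float(yi), True, bool(mi)))
    return pd.DataFrame(
        rows, columns=["embryo_id", "x", "y", "is_population", "is_marker"]
    )


def config_with(config: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced (re-validated)."""
    return replace(config, **overrides)
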