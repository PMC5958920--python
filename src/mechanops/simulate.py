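"""Forward model: synthetic current traces with per-cell ground truth.

The simulator renders the canonical pulse anatomy of a cell transiting the
device: in each pre-contraction pore the normalized current drops from the
unit baseline by the Coulter blockade fraction of the cell's free diameter;
in each node it returns to baseline; in the contraction channel it drops by
the occluded-volume fraction (cell volume over contraction-channel volume),
which is always deeper than the pore drop; and in the post-contraction
pores the drop follows a recovery trajectory toward the pre-contraction
amplitude.

Recovery trajectories
---------------------
* ``instant`` — post-pore amplitudes equal the pre-contraction amplitude
  immediately (the overall pulse is symmetric).
* ``transient`` — the amplitude deficit decays as a single exponential
  A·exp(−t/τ) of the time since contraction exit; the ground-truth recovery
  time ΔT_r is the first time the deficit falls to the analysis pipeline's
  equality tolerance, and τ is chosen to place that crossing at the drawn
  ΔT_r.
* ``prolonged`` — the deficit is held constant above the tolerance through
  the last post-contraction pore, so the record censors at the observation
  window.

Cell speed is constant within the node/pore sections and separately
constant within the contraction channel; transitions are instantaneous
steps (realistic edge shapes come from the analysis low-pass filter).
Noise is additive Gaussian white noise plus an optional linear drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .device import AcquisitionConfig, DeviceGeometry, RawTrace
from .errors import DurationError, InfeasibleCellError, ValidationError
from .physics import blockade_fraction

#: Deficit fraction of ΔI_np immediately after the contraction exit for a
#: transiently recovering cell.
TRANSIENT_INITIAL_DEFICIT = 0.30

#: Constant deficit fraction for a cell that does not recover in-window.
PROLONGED_DEFICIT = 0.15


@dataclass(frozen=True)
class GroundTruthEvent:
    """Per-cell ground truth paired with a simulated event."""

    cell_id: int
    D_cell_true: float  # μm
    dT_cont_true: float  # ms
    dT_r_true: float  # ms (0 for instant; > window for prolonged)
    dT_r_censored: bool
    recovery_class_true: str
    event_start: float  # s
    boundaries: tuple[float, ...]  # s, sub-pulse boundary times (absolute)
    dI_np_true: float  # normalized
    dI_c_true: float  # normalized
    window_ms: float  # observable recovery window (to last post-pore midpoint)
    speed_node: float  # μm ms⁻¹

    def __post_init__(self) -> None:
        if self.dT_r_true < 0:
            raise ValidationError("dT_r_true must be ≥ 0")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValidationError("sub-pulse boundaries must be strictly increasing")
        cls = self.recovery_class_true
        if cls == "instant" and self.dT_r_true != 0:
            raise ValidationError("instant recovery requires dT_r_true = 0")
        if cls == "transient" and not (0 < self.dT_r_true <= self.window_ms):
            raise ValidationError("transient recovery requires 0 < dT_r_true ≤ window")
        if cls == "prolonged" and not (self.dT_r_censored or self.dT_r_true > self.window_ms):
            raise ValidationError("prolonged recovery requires censoring or dT_r_true > window")


@dataclass(frozen=True)
class SimulationConfig:
    """Seeded description of a synthetic cell population and acquisition run.

    Defaults describe the canonical screening conditions: ~16 μm epithelial
    cells (sd 2 μm) in a calibrated channel, node-section speed
    50 μm ms⁻¹, contraction transit times centred near 30 ms for a 16 μm
    cell, a 50/30/20 instant/transient/prolonged recovery mix, and
    amplitude SNR ≈ 20 for the default cell size.
    """

    geometry: DeviceGeometry
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    n_cells: int = 200
    diameter_mean: float = 16.0  # μm
    diameter_sd: float = 2.0  # μm
    diameters: Sequence[float] | None = None  # explicit list overrides the distribution
    speed_node: float = 50.0  # μm ms⁻¹ (proxy for U_flow)
    slowdown_median: float = 0.73  # median of ΔT_cont/(L_c/speed_node) at the reference diameter
    slowdown_sigma: float = 0.20  # log-sd of the slowdown multiplier (stiffness proxy)
    diameter_ref: float = 16.0  # μm; ΔT_cont scales linearly with D/diameter_ref
    recovery_mix: dict = field(
        default_factory=lambda: {"instant": 0.5, "transient": 0.3, "prolonged": 0.2}
    )
    transient_recovery_range: tuple[float, float] = (6.0, 20.0)  # ms
    recovery_tolerance: float = 0.05  # relative equality tolerance mirrored by the pipeline
    noise_sd: float = 6.5e-5  # normalized-current units
    drift_slope: float = 0.0  # normalized units s⁻¹
    gap_mean_s: float = 0.10  # exponential inter-event gap (on top of gap_min_s)
    gap_min_s: float = 0.05
    lead_s: float = 0.05  # quiet baseline before the first / after the last event
    duration_s: float | None = None  # fixed total duration; derived when None
    coincidence_pairs: int = 0  # number of deliberately overlapping event pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry.D_e is None:
            raise ValidationError("simulation requires a geometry with calibrated D_e")
        total = sum(self.recovery_mix.get(k, 0.0) for k in ("instant", "transient", "prolonged"))
        if abs(total - 1.0) > 1e-12 or set(self.recovery_mix) - {
            "instant",
            "transient",
            "prolonged",
        }:
            raise ValidationError("recovery_mix probabilities must cover the three classes and sum to 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be ≥ 0")
        if not self.speed_node > 0:
            raise ValidationError("speed_node must be > 0")
        if self.diameters is not None:
            arr = np.asarray(self.diameters, dtype=float)
            if np.any(arr >= self.geometry.D_e) or np.any(arr <= 0):
                raise ValidationError("explicit diameters must satisfy 0 < d < D_e")
        lo, hi = self.transient_recovery_range
        if not (0 < lo < hi):
            raise ValidationError("transient_recovery_range must satisfy 0 < lo < hi")


# --------------------------------------------------------------------------
# single-event forward model


def contraction_fraction(D_cell: float, geometry: DeviceGeometry) -> float:
    """ΔI_c/I forward value: sphere volume over contraction-channel volume."""
    return (math.pi * D_cell**3 / 6.0) / geometry.contraction_volume


def _post_pore_layout(geometry: DeviceGeometry, speed_node: float) -> tuple[np.ndarray, float]:
    """Midpoint times (ms, from contraction exit) of the post pores, and the
    observable recovery window (time to the last midpoint)."""
    node_ms = geometry.node_length / speed_node
    pore_ms = geometry.pore_length / speed_node
    mids = []
    t = 0.0
    for _ in range(geometry.n_post_pairs):
        t += node_ms
        mids.append(t + pore_ms / 2.0)
        t += pore_ms
    mids_arr = np.asarray(mids)
    return mids_arr, float(mids_arr[-1])


def simulate_event_pulse(
    D_cell: float,
    geometry: DeviceGeometry,
    acquisition: AcquisitionConfig,
    *,
    speed_node: float = 50.0,
    dT_cont_ms: float = 30.0,
    recovery_class: str = "instant",
    dT_r_ms: float = 0.0,
    tolerance: float = 0.05,
    start_time: float = 0.0,
    cell_id: int = 0,
) -> tuple[np.ndarray, GroundTruthEvent]:
    """Render the sample segment of one cell's transit and its ground truth.

    Returns the noise-free normalized-current samples covering the event
    (baseline = 1) and the matching :class:`GroundTruthEvent`; the caller
    places the segment on a longer trace and adds noise.
    """
    D_e = geometry.D_e
    if D_e is None:
        raise ValidationError("geometry has no calibrated D_e")
    if D_cell >= D_e:
        raise InfeasibleCellError(f"cell diameter {D_cell} μm ≥ effective diameter {D_e} μm")
    if recovery_class not in ("instant", "transient", "prolonged"):
        raise ValidationError(f"unknown recovery class {recovery_class!r}")

    dI_np = blockade_fraction(D_cell, D_e, geometry.L_total)
    dI_c = contraction_fraction(D_cell, geometry)
    mids_ms, window_ms = _post_pore_layout(geometry, speed_node)

    # Deficit trajectory (fraction of dI_np still missing) vs time since exit.
    if recovery_class == "instant":
        deficit = lambda t_ms: 0.0  # noqa: E731
        dT_r_true, censored = 0.0, False
    elif recovery_class == "transient":
        if not 0 < dT_r_ms <= window_ms:
            raise ValidationError(
                f"transient dT_r must lie in (0, {window_ms:.2f}] ms for this geometry/speed"
            )
        tau = dT_r_ms / math.log(TRANSIENT_INITIAL_DEFICIT / tolerance)
        deficit = lambda t_ms: TRANSIENT_INITIAL_DEFICIT * math.exp(-t_ms / tau)  # noqa: E731
        dT_r_true, censored = dT_r_ms, False
    else:  # prolonged
        deficit = lambda t_ms: PROLONGED_DEFICIT  # noqa: E731
        dT_r_true, censored = 1.5 * window_ms, True

    node_s = geometry.node_length / speed_node / 1e3
    pore_s = geometry.pore_length / speed_node / 1e3

    # Piecewise-constant levels and boundary times (relative, seconds).
    pieces: list[tuple[float, float]] = []  # (duration_s, level)
    for _ in range(geometry.n_pre_pairs):
        pieces.append((pore_s, 1.0 - dI_np))
        pieces.append((node_s, 1.0))
    pieces.append((dT_cont_ms / 1e3, 1.0 - dI_c))
    for k in range(geometry.n_post_pairs):
        pieces.append((node_s, 1.0))
        dI_r = dI_np * (1.0 - deficit(mids_ms[k]))
        pieces.append((pore_s, 1.0 - dI_r))

    boundaries_rel = np.concatenate([[0.0], np.cumsum([d for d, _ in pieces])])
    levels = np.asarray([lv for _, lv in pieces])

    # Area sampling: each sample carries the mean level over its own sample
    # interval, so step edges at fractional sample positions are rendered
    # with sub-sample accuracy (a symmetric one-sample box average that the
    # zero-phase analysis filter preserves).
    fs = acquisition.sampling_rate
    h = 1.0 / fs
    n = int(math.ceil(boundaries_rel[-1] * fs))
    # Cumulative integral of the level function, padded with baseline outside.
    pad_b = np.concatenate([[-h], boundaries_rel, [boundaries_rel[-1] + h]])
    pad_lv = np.concatenate([[1.0], levels, [1.0]])
    areas = np.concatenate([[0.0], np.cumsum(pad_lv * np.diff(pad_b))])
    t_k = np.arange(n) / fs
    F = lambda t: np.interp(t, pad_b, areas)  # noqa: E731
    samples = (F(t_k + h / 2) - F(t_k - h / 2)) / h

    truth = GroundTruthEvent(
        cell_id=cell_id,
        D_cell_true=D_cell,
        dT_cont_true=dT_cont_ms,
        dT_r_true=dT_r_true,
        dT_r_censored=censored,
        recovery_class_true=recovery_class,
        event_start=start_time,
        boundaries=tuple(start_time + boundaries_rel),
        dI_np_true=dI_np,
        dI_c_true=dI_c,
        window_ms=window_ms,
        speed_node=speed_node,
    )
    return samples, truth


# --------------------------------------------------------------------------
# full-trace simulation


def simulate_trace(config: SimulationConfig) -> tuple[RawTrace, list[GroundTruthEvent]]:
    """Generate a full seeded trace plus the per-cell ground-truth list.

    Deterministic under a fixed seed.  When ``coincidence_pairs`` > 0 the
    last pairs of events are forced to overlap in time, producing composite
    pulses for coincidence-rejection tests.
    """
    geometry, acq = config.geometry, config.acquisition
    rng = np.random.default_rng(config.seed)
    fs = acq.sampling_rate
    n_cells = config.n_cells

    # Transient recovery must be resolvable by the post-pore comb: the first
    # midpoint precedes the earliest draw and one pair spacing of headroom is
    # left before the observable window so quantized estimates stay in-class.
    mids_ms, window_ms = _post_pore_layout(geometry, config.speed_node)
    pair_ms = (geometry.node_length + geometry.pore_length) / config.speed_node
    lo, hi = config.transient_recovery_range
    if n_cells and config.recovery_mix.get("transient", 0.0) > 0:
        if lo <= mids_ms[0] or hi + pair_ms > window_ms:
            raise ValidationError(
                "transient_recovery_range must lie within "
                f"({mids_ms[0]:.2f}, {window_ms - pair_ms:.2f}) ms for this geometry/speed"
            )

    # Per-cell draws.
    if config.diameters is not None:
        diameters = np.asarray(config.diameters, dtype=float)
        if len(diameters) != n_cells:
            raise ValidationError("explicit diameter list length must equal n_cells")
    else:
        diameters = np.empty(n_cells)
        upper = 0.98 * geometry.D_e
        for k in range(n_cells):
            d = rng.normal(config.diameter_mean, config.diameter_sd)
            while not (1.0 < d < upper):
                d = rng.normal(config.diameter_mean, config.diameter_sd)
            diameters[k] = d
    slowdowns = rng.lognormal(math.log(config.slowdown_median), config.slowdown_sigma, n_cells)
    classes = rng.choice(
        ["instant", "transient", "prolonged"],
        size=n_cells,
        p=[config.recovery_mix.get(k, 0.0) for k in ("instant", "transient", "prolonged")],
    )
    transient_times = rng.uniform(lo, hi, n_cells)
    gaps = config.gap_min_s + rng.exponential(config.gap_mean_s, n_cells)

    base_cont_ms = geometry.L_c / config.speed_node
    events: list[tuple[np.ndarray, GroundTruthEvent]] = []
    t_cursor = config.lead_s
    starts = np.empty(n_cells)
    for k in range(n_cells):
        dT_cont = slowdowns[k] * base_cont_ms * (diameters[k] / config.diameter_ref)
        # Snap event starts to the sample grid; edge positions inside the
        # event remain sub-sample accurate through area sampling.
        t_cursor = round(t_cursor * fs) / fs
        samples, truth = simulate_event_pulse(
            diameters[k],
            geometry,
            acq,
            speed_node=config.speed_node,
            dT_cont_ms=dT_cont,
            recovery_class=str(classes[k]),
            dT_r_ms=float(transient_times[k]),
            tolerance=config.recovery_tolerance,
            start_time=t_cursor,
            cell_id=k,
        )
        starts[k] = t_cursor
        events.append((samples, truth))
        t_cursor = truth.boundaries[-1] + gaps[k]

    # Force the requested number of overlapping pairs at the end of the run.
    n_coinc = min(config.coincidence_pairs, n_cells // 2)
    for j in range(n_coinc):
        a, b = n_cells - 2 * (j + 1), n_cells - 2 * (j + 1) + 1
        dur_a = events[a][1].boundaries[-1] - events[a][1].event_start
        new_start = round((starts[a] + 0.4 * dur_a) * fs) / fs
        shift = starts[b] - new_start
        starts[b] = new_start
        samples, truth = events[b]
        events[b] = (
            samples,
            GroundTruthEvent(
                **{
                    **truth.__dict__,
                    "event_start": new_start,
                    "boundaries": tuple(np.asarray(truth.boundaries) - shift),
                }
            ),
        )

    end_time = (
        max((ev[1].boundaries[-1] for ev in events), default=config.lead_s) + config.lead_s
    )
    if config.duration_s is not None:
        if end_time > config.duration_s:
            raise DurationError(
                f"events extend to {end_time:.3f} s; increase duration_s beyond that"
            )
        end_time = config.duration_s
    n = max(int(math.ceil(end_time * fs)), 2)

    i = np.ones(n)
    for samples, truth in events:
        i0 = int(round(truth.event_start * fs))
        i1 = min(i0 + len(samples), n)
        i[i0:i1] += samples[: i1 - i0] - 1.0  # additive occlusion; overlaps superpose
    t = np.arange(n) / fs
    if config.drift_slope:
        i = i + config.drift_slope * t
    if config.noise_sd:
        i = i + rng.normal(0.0, config.noise_sd, n)

    trace = RawTrace(
        t=t,
        i=i,
        meta={"sampling_rate_hz": fs, "normalized": True, "seed": config.seed},
    )
    return trace, [ev[1] for ev in events]
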