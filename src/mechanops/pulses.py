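"""Pulse extraction: filtering, event detection, sub-pulse segmentation and
per-cell measurement.

The analysis chain mirrors standard resistive-pulse processing:

1. zero-phase low-pass filtering (4th-order Butterworth, forward-backward);
2. baseline tracking by a rolling median of coarse block medians, which
   interpolates smoothly under events and follows slow drift;
3. event detection by hysteresis thresholding of the baseline-subtracted
   signal (enter at k·σ, extend to k·σ/2, with σ a robust MAD estimate of
   the residual noise), merging sub-pulse runs separated by node returns
   into one event window;
4. segmentation of each window into pore/contraction/pore sub-pulses by
   matching the run pattern against the device geometry, with plateau
   amplitudes taken as baseline minus the trimmed-interior median and
   edges refined to half-amplitude crossings;
5. measurement of ΔI_np (mean pre-contraction pore amplitude), ΔI_c,
   ΔT_cont, and the recovery time ΔT_r.

ΔT_r is quantized by the post-pore comb: it is the elapsed time from the
contraction exit to the midpoint of the first post-contraction pore whose
amplitude is within the equality tolerance of ΔI_np, linearly interpolated
between successive midpoints when the crossing falls between them.  A cell
whose first post pore already satisfies the criterion recovered instantly
(ΔT_r = 0); one that never satisfies it in-window is censored (prolonged).

Windows containing more sub-pulses than the geometry predicts are flagged
as coincidence events (more than one cell in the channel) and excluded;
windows with fewer are flagged truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import bessel, sosfiltfilt

from .device import AcquisitionConfig, DeviceGeometry, RawTrace
from .errors import (
    BaselineError,
    InconsistentEventError,
    ParameterError,
    SegmentationError,
)

#: Default detection threshold in units of the robust noise sd.
DETECTION_K = 5.0

#: Default relative tolerance for "post-pore amplitude equals ΔI_np".
EQUALITY_TOLERANCE = 0.05

#: Absolute floor on the noise-sd estimate (normalized units), so that
#: noise-free traces still threshold sensibly.
SIGMA_FLOOR = 1e-9

#: Smallest resolvable blockade depth (normalized units).  The detection
#: threshold never drops below this, so residual filter transients on
#: noise-free traces are not mistaken for sub-pulses.
MIN_DEPTH = 1e-4


@dataclass(frozen=True)
class SubPulse:
    """One sub-pulse: a pore or contraction plateau below baseline."""

    segment_kind: str  # pore_pre | contraction | pore_post
    index: int  # transit order within its kind
    t_start: float  # s
    t_end: float  # s
    dI: float  # normalized amplitude (baseline − plateau)

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise SegmentationError("sub-pulse must have t_end > t_start")
        if not self.dI > 0:
            raise SegmentationError("sub-pulse amplitude must be > 0")

    @property
    def dT(self) -> float:
        """Duration in ms."""
        return (self.t_end - self.t_start) * 1e3

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class PulseRecord:
    """One accepted cell event, fully measured."""

    cell_id: int
    baseline_I: float
    dI_np: float  # mean pre-contraction pore amplitude
    dI_c: float  # contraction amplitude
    dT_cont: float  # ms
    dT_r: float  # ms (reported at the window when censored)
    dT_r_censored: bool
    window_ms: float
    pre_pulses: tuple[SubPulse, ...]
    contraction: SubPulse
    post_pulses: tuple[SubPulse, ...]
    t_start: float  # s
    t_end: float  # s

    def __post_init__(self) -> None:
        if not self.dI_c > self.dI_np:
            raise InconsistentEventError("contraction amplitude must exceed the pore amplitude")
        if not self.dT_cont > 0:
            raise InconsistentEventError("dT_cont must be > 0")
        if not self.post_pulses:
            raise InconsistentEventError("accepted records require post-contraction sub-pulses")


@dataclass(frozen=True)
class EventWindow:
    """A candidate event located by :func:`detect_events`."""

    i0: int
    i1: int
    t_start: float
    t_end: float
    baseline: float
    sigma: float
    threshold_hi: float
    threshold_lo: float
    n_subpulses: int
    coincidence: bool = False
    truncated: bool = False
    sub_runs: tuple[tuple[int, int], ...] = ()  # absolute sample-index runs


@dataclass(frozen=True)
class RejectedEvent:
    window: EventWindow
    reason: str


# --------------------------------------------------------------------------
# filtering


def lowpass_filter(trace: RawTrace, cutoff: float) -> RawTrace:
    """Zero-phase 4th-order Bessel low-pass; DC gain 1, same time base.

    A Bessel response is used because plateau amplitudes are the measurand:
    its step response has negligible overshoot, so pore and contraction
    plateaus are not distorted by ringing, at the cost of a gentler roll-off
    than a Butterworth of the same order.
    """
    nyq = trace.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"cutoff must lie in (0, Nyquist={nyq:g} Hz), got {cutoff}")
    sos = bessel(4, cutoff, btype="low", fs=trace.fs, output="sos", norm="mag")
    return RawTrace(t=trace.t, i=sosfiltfilt(sos, trace.i), meta=dict(trace.meta))


# --------------------------------------------------------------------------
# baseline and detection


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def rolling_baseline(
    i: np.ndarray, fs: float, block_s: float = 0.01, span_s: float = 1.0
) -> np.ndarray:
    """Baseline estimate: rolling median of coarse block medians.

    Blocks of ``block_s`` seconds are reduced to their medians, a centred
    rolling median over ``span_s`` rejects blocks occupied by events, and
    the result is linearly interpolated back to the full time base.  The
    span must greatly exceed an event's duration for the rejection to work.
    """
    nb = max(int(round(block_s * fs)), 1)
    n_blocks = len(i) // nb
    if n_blocks < 2:
        return np.full_like(i, np.median(i))
    trimmed = i[: n_blocks * nb].reshape(n_blocks, nb)
    block_med = np.median(trimmed, axis=1)
    win = max(int(round(span_s / block_s)) | 1, 3)
    smoothed = (
        pd.Series(block_med).rolling(window=win, center=True, min_periods=1).median().to_numpy()
    )
    centers = (np.arange(n_blocks) + 0.5) * nb
    return np.interp(np.arange(len(i)), centers, smoothed)


def detect_events(
    trace: RawTrace,
    geometry: DeviceGeometry,
    acquisition: AcquisitionConfig,
    *,
    k: float = DETECTION_K,
    min_depth: float = MIN_DEPTH,
    merge_gap_s: float = 0.010,
    baseline_span_s: float = 1.0,
    min_baseline_samples: int = 100,
) -> list[EventWindow]:
    """Locate candidate cell-transit windows on a (filtered) trace.

    Returns disjoint, time-sorted windows.  Windows whose sub-pulse count
    exceeds the geometry's prediction are flagged ``coincidence``; those
    with fewer are flagged ``truncated``.  Both are excluded from phenotype
    output downstream.
    """
    if len(trace) < min_baseline_samples:
        raise BaselineError(
            f"trace too short to estimate a baseline (< {min_baseline_samples} samples)"
        )
    fs = trace.fs
    baseline = rolling_baseline(trace.i, fs, span_s=baseline_span_s)
    resid = baseline - trace.i
    med = np.median(resid)
    sigma = max(1.4826 * float(np.median(np.abs(resid - med))), SIGMA_FLOOR)

    thr_hi = max(k * sigma, min_depth)
    thr_lo = 0.5 * thr_hi
    hi_runs = _runs_of(resid > thr_hi)
    if not hi_runs:
        return []
    # Hysteresis: keep the low-threshold runs that contain a high-threshold run.
    lo_runs = _runs_of(resid > thr_lo)
    lo_starts = np.asarray([r[0] for r in lo_runs])
    kept_idx = sorted(
        {int(np.searchsorted(lo_starts, h0, side="right") - 1) for h0, _ in hi_runs}
    )
    kept = [lo_runs[j] for j in kept_idx]

    # Merge runs separated by less than the node-return gap into one event.
    merge_gap = int(round(merge_gap_s * fs))
    groups: list[list[tuple[int, int]]] = [[kept[0]]]
    for run in kept[1:]:
        if run[0] - groups[-1][-1][1] <= merge_gap:
            groups[-1].append(run)
        else:
            groups.append([run])

    expected = geometry.n_pre_pairs + 1 + geometry.n_post_pairs
    pad = merge_gap // 2
    windows: list[EventWindow] = []
    prev_end = 0
    for g, group in enumerate(groups):
        raw0, raw1 = group[0][0], group[-1][1]
        nxt_start = groups[g + 1][0][0] if g + 1 < len(groups) else len(trace.i)
        i0 = max(raw0 - pad, prev_end)
        i1 = min(raw1 + pad, (raw1 + nxt_start) // 2, len(trace.i))
        prev_end = i1
        n_sub = len(group)
        # A single cell produces exactly one run much longer than the pore
        # runs (the contraction).  Overlapping cells can merge runs into a
        # pattern with the expected count but more than one long run.
        durations = np.asarray([r1 - r0 for r0, r1 in group], dtype=float)
        n_long = int(np.sum(durations > 3.0 * np.median(durations))) if n_sub >= 3 else 0
        local_base = float(np.median(baseline[i0:i1]))
        windows.append(
            EventWindow(
                i0=i0,
                i1=i1,
                t_start=float(trace.t[i0]),
                t_end=float(trace.t[i1 - 1]),
                baseline=local_base,
                sigma=sigma,
                threshold_hi=thr_hi,
                threshold_lo=thr_lo,
                n_subpulses=n_sub,
                coincidence=n_sub > expected or n_long > 1,
                truncated=n_sub < expected,
                sub_runs=tuple(group),
            )
        )
    return windows


# --------------------------------------------------------------------------
# segmentation


def _refine_run(
    resid: np.ndarray, t: np.ndarray, run: tuple[int, int], n_trim: int
) -> tuple[float, float, float]:
    """Amplitude and half-amplitude edge times for one below-baseline run.

    The plateau amplitude is the median of the run interior (``n_trim``
    samples trimmed each side to discard filter transients); edges are the
    half-amplitude crossings, linearly interpolated between samples.
    """
    s0, s1 = run
    if s1 - s0 > 3 * n_trim:
        interior = resid[s0 + n_trim : s1 - n_trim]
    else:
        third = max((s1 - s0) // 3, 1)
        interior = resid[s0 + third : s1 - third] if s1 - s0 > 2 else resid[s0:s1]
    amp = float(np.median(interior))
    half = amp / 2.0

    above = np.flatnonzero(resid[s0:s1] >= half)
    if above.size == 0:
        raise SegmentationError("plateau never reaches half of its own amplitude")
    jl = s0 + int(above[0])
    jr = s0 + int(above[-1])

    # Leading half-amplitude crossing, interpolated between samples.
    if jl > 0 and resid[jl] != resid[jl - 1]:
        frac = (half - resid[jl - 1]) / (resid[jl] - resid[jl - 1])
        t_start = t[jl - 1] + frac * (t[jl] - t[jl - 1])
    else:
        t_start = t[jl]
    # Trailing crossing.
    if jr < len(resid) - 1 and resid[jr] != resid[jr + 1]:
        frac = (resid[jr] - half) / (resid[jr] - resid[jr + 1])
        t_end = t[jr] + frac * (t[jr + 1] - t[jr])
    else:
        t_end = t[jr]
    return amp, float(t_start), float(t_end)


def segment_event(
    trace: RawTrace,
    window: EventWindow,
    geometry: DeviceGeometry,
    acquisition: AcquisitionConfig,
    *,
    trim_factor: float = 2.0,
) -> list[SubPulse]:
    """Segment an event window into labelled sub-pulses.

    The unique longest run is labelled ``contraction`` (and must also be the
    deepest); runs before it become ``pore_pre`` and after it ``pore_post``,
    indexed in transit order.  A run pattern incompatible with the geometry
    raises :class:`SegmentationError`.
    """
    if window.coincidence:
        raise SegmentationError("refusing to segment a coincidence-flagged window")
    runs = list(window.sub_runs)
    if len(runs) < 3:
        raise SegmentationError(
            f"window has {len(runs)} plateau(s); need at least pore + contraction + pore"
        )
    resid = window.baseline - trace.i
    n_trim = max(int(round(trim_factor * trace.fs / acquisition.lowpass_cutoff)), 1)

    refined = [_refine_run(resid, trace.t, run, n_trim) for run in runs]

    # Plateau-flatness guard: a single cell's sub-pulse is a flat plateau.
    # Superposed cells (coincidence with nested overlap) leave internal steps
    # of the order of the pore/contraction amplitudes.
    for (amp, _, _), (s0, s1) in zip(refined, runs):
        if s1 - s0 > 4 * n_trim:
            interior = resid[s0 + n_trim : s1 - n_trim]
            spread = float(np.percentile(interior, 95) - np.percentile(interior, 5))
            if spread > 0.3 * amp + 6.0 * window.sigma:
                raise SegmentationError(
                    "non-flat plateau inside a sub-pulse; likely coincidence overlap"
                )
    durations = [te - ts for _, ts, te in refined]
    ci = int(np.argmax(durations))
    amps = [a for a, _, _ in refined]
    if ci != int(np.argmax(amps)):
        raise SegmentationError("longest plateau is not the deepest; not a contraction pulse")

    n_pre, n_post = ci, len(runs) - ci - 1
    if n_pre != geometry.n_pre_pairs or n_post != geometry.n_post_pairs:
        raise SegmentationError(
            f"plateau count incompatible with geometry: {n_pre} pre / {n_post} post "
            f"(expected {geometry.n_pre_pairs} / {geometry.n_post_pairs})"
        )

    out: list[SubPulse] = []
    for j, (amp, ts, te) in enumerate(refined):
        if j < ci:
            kind, idx = "pore_pre", j
        elif j == ci:
            kind, idx = "contraction", 0
        else:
            kind, idx = "pore_post", j - ci - 1
        out.append(SubPulse(segment_kind=kind, index=idx, t_start=ts, t_end=te, dI=amp))
    return out


# --------------------------------------------------------------------------
# measurement


def measure_event(
    subpulses: list[SubPulse],
    *,
    baseline_I: float = 1.0,
    window_ms: float | None = None,
    tolerance: float = EQUALITY_TOLERANCE,
    cell_id: int = 0,
) -> PulseRecord:
    """Measure ΔI_np, ΔI_c, ΔT_cont and ΔT_r from segmented sub-pulses.

    ``window_ms`` defaults to the observable window — the elapsed time from
    the contraction exit to the midpoint of the last post-contraction pore.
    """
    pre = tuple(s for s in subpulses if s.segment_kind == "pore_pre")
    post = tuple(s for s in subpulses if s.segment_kind == "pore_post")
    cont = [s for s in subpulses if s.segment_kind == "contraction"]
    if not (pre and post and len(cont) == 1):
        raise SegmentationError("measurement requires ≥1 pre pore, 1 contraction, ≥1 post pore")
    cont = cont[0]

    dI_np = float(np.mean([s.dI for s in pre]))
    dI_c = cont.dI
    dT_cont = cont.dT
    exit_t = cont.t_end

    mids_ms = np.asarray([(s.midpoint - exit_t) * 1e3 for s in post])
    amps = np.asarray([s.dI for s in post])
    observable = float(mids_ms[-1])
    if window_ms is None:
        window_ms = observable

    within = np.abs(amps - dI_np) <= tolerance * dI_np
    if within[0]:
        dT_r, censored = 0.0, False
    elif within.any():
        kstar = int(np.argmax(within))
        target = (1.0 - tolerance) * dI_np
        a0, a1 = amps[kstar - 1], amps[kstar]
        if a1 != a0:
            frac = (target - a0) / (a1 - a0)
            frac = min(max(frac, 0.0), 1.0)
        else:
            frac = 1.0
        dT_r = float(mids_ms[kstar - 1] + frac * (mids_ms[kstar] - mids_ms[kstar - 1]))
        censored = False
        if dT_r > window_ms:
            dT_r, censored = window_ms, True
    else:
        dT_r, censored = window_ms, True

    return PulseRecord(
        cell_id=cell_id,
        baseline_I=baseline_I,
        dI_np=dI_np,
        dI_c=dI_c,
        dT_cont=dT_cont,
        dT_r=dT_r,
        dT_r_censored=censored,
        window_ms=float(window_ms),
        pre_pulses=pre,
        contraction=cont,
        post_pulses=post,
        t_start=pre[0].t_start,
        t_end=post[-1].t_end,
    )


# --------------------------------------------------------------------------
# pipeline


def extract_pulses(
    trace: RawTrace,
    geometry: DeviceGeometry,
    acquisition: AcquisitionConfig,
    *,
    k: float = DETECTION_K,
    min_depth: float = MIN_DEPTH,
    tolerance: float = EQUALITY_TOLERANCE,
    window_ms: float | None = None,
    merge_gap_s: float = 0.010,
    baseline_span_s: float = 1.0,
    prefilter: bool = True,
) -> tuple[list[PulseRecord], list[RejectedEvent]]:
    """Full extraction chain: filter → detect → segment → measure.

    Returns accepted records (cell_id assigned in transit order) and the
    rejected windows with reasons; every detected window is accounted for in
    exactly one of the two lists.
    """
    work = lowpass_filter(trace, acquisition.lowpass_cutoff) if prefilter else trace
    windows = detect_events(
        work,
        geometry,
        acquisition,
        k=k,
        min_depth=min_depth,
        merge_gap_s=merge_gap_s,
        baseline_span_s=baseline_span_s,
    )
    records: list[PulseRecord] = []
    rejects: list[RejectedEvent] = []
    for w in windows:
        if w.coincidence:
            rejects.append(RejectedEvent(w, "coincidence"))
            continue
        if w.truncated:
            rejects.append(RejectedEvent(w, "truncated"))
            continue
        try:
            subs = segment_event(work, w, geometry, acquisition)
            rec = measure_event(
                subs,
                baseline_I=w.baseline,
                window_ms=window_ms,
                tolerance=tolerance,
                cell_id=len(records),
            )
        except (SegmentationError, InconsistentEventError) as exc:
            rejects.append(RejectedEvent(w, str(exc)))
            continue
        records.append(rec)
    return records, rejects


# --------------------------------------------------------------------------
# tabular round-trip for the CLI


PULSE_COLUMNS = (
    "cell_id",
    "baseline_I",
    "dI_np",
    "dI_c",
    "dT_cont_ms",
    "dT_r_ms",
    "dT_r_censored",
    "window_ms",
    "U_flow_ummps",
    "t_start_s",
)


def pulses_to_frame(records: list[PulseRecord], geometry: DeviceGeometry) -> pd.DataFrame:
    """Flatten records to a table (one row per cell) for CSV output.

    ``U_flow_ummps`` is the node-section speed proxy (μm ms⁻¹) from the last
    pre-contraction pore, carried so the phenotype stage can run from CSV.
    """
    rows = []
    for r in records:
        u_flow = geometry.pore_length / r.pre_pulses[-1].dT
        rows.append(
            {
                "cell_id": r.cell_id,
                "baseline_I": r.baseline_I,
                "dI_np": r.dI_np,
                "dI_c": r.dI_c,
                "dT_cont_ms": r.dT_cont,
                "dT_r_ms": r.dT_r,
                "dT_r_censored": r.dT_r_censored,
                "window_ms": r.window_ms,
                "U_flow_ummps": u_flow,
                "t_start_s": r.t_start,
            }
        )
    return pd.DataFrame(rows, columns=list(PULSE_COLUMNS))
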