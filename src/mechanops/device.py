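"""Device geometry, acquisition settings, and plain-text trace/table I/O.

Unit conventions used throughout the package: lengths in micrometres (μm),
sub-pulse durations in milliseconds (ms), trace time axes in seconds (s),
speeds in μm ms⁻¹, pressures in kPa, and currents normalized to a unit
baseline (I = 1).  File readers convert to these conventions at the
boundary; config files may attach unit strings (``"2.055 mm"``) which are
normalized on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, TraceFormatError, ValidationError

SEGMENT_KINDS = ("pore", "node", "contraction")

#: Relative jitter tolerated on the time base of a trace before it is
#: rejected as non-uniform.
TIME_JITTER_TOL = 1e-6

#: Fixed column order of the per-cell phenotype table.
PHENOTYPE_COLUMNS = (
    "cell_id",
    "D_cell_um",
    "L_deform_um",
    "delta_deform",
    "strain",
    "dT_cont_ms",
    "dT_r_ms",
    "dT_r_censored",
    "wCDI",
    "recovery_class",
)


# --------------------------------------------------------------------------
# unit parsing

_LENGTH_UM = {"um": 1.0, "µm": 1.0, "μm": 1.0, "nm": 1e-3, "mm": 1e3, "cm": 1e4, "m": 1e6}
_FREQ_HZ = {"hz": 1.0, "khz": 1e3, "mhz": 1e6}
_VOLT_V = {"v": 1.0, "mv": 1e-3}
_PRESS_KPA = {"kpa": 1.0, "pa": 1e-3, "mpa": 1e3}

_UNIT_TABLES = {"um": _LENGTH_UM, "Hz": _FREQ_HZ, "V": _VOLT_V, "kPa": _PRESS_KPA}


def _parse_quantity(value, canonical: str, key: str) -> float:
    """Coerce a config value to a float in the canonical unit.

    Bare numbers are taken to already be in the canonical unit; strings may
    carry a unit suffix (``"2.055 mm"``, ``"100 kHz"``).
    """
    if isinstance(value, bool):
        raise ConfigError(f"key '{key}': expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.replace("_", " ").split()
        try:
            mag = float(parts[0])
        except (ValueError, IndexError):
            raise ConfigError(f"key '{key}': cannot parse quantity {value!r}") from None
        if len(parts) == 1:
            return mag
        table = _UNIT_TABLES[canonical]
        unit = parts[1].lower()
        if unit not in table:
            raise ConfigError(
                f"key '{key}': unknown unit {parts[1]!r} (expected one of {sorted(table)})"
            )
        return mag * table[unit]
    raise ConfigError(f"key '{key}': expected a number or quantity string, got {type(value).__name__}")


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Segment:
    """One channel segment: a pore, a node, or the contraction channel."""

    kind: str
    length: float  # μm
    width: float  # μm

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValidationError(f"segment kind must be one of {SEGMENT_KINDS}, got {self.kind!r}")
        if not (self.length > 0 and self.width > 0):
            raise ValidationError(
                f"segment lengths/widths must be > 0 (got length={self.length}, width={self.width})"
            )


@dataclass(frozen=True)
class DeviceGeometry:
    """Physical description of the node-pore / contraction channel.

    ``segment_sequence`` lists the segments a cell traverses in order:
    alternating pores and nodes, exactly one contraction channel, then the
    post-contraction node-pore pairs.  ``D_e`` is the channel's effective
    electrical diameter, usually set by microsphere calibration and left
    unset until then.
    """

    segment_sequence: tuple[Segment, ...]
    w_pore: float = 25.0  # μm
    w_node: float = 85.0  # μm
    w_c: float = 12.0  # μm, contraction-channel width
    h_channel: float = 30.0  # μm
    L_c: float = 2055.0  # μm, contraction-channel length
    D_e: float | None = None  # μm, effective diameter (set by calibration)

    def __post_init__(self) -> None:
        for name in ("w_pore", "w_node", "w_c", "h_channel", "L_c"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"invariant violated: {name} must be > 0")
        if not (self.w_c < self.w_pore < self.w_node):
            raise ValidationError(
                "invariant violated: w_c < w_pore < w_node "
                f"(got w_c={self.w_c}, w_pore={self.w_pore}, w_node={self.w_node})"
            )
        if not self.segment_sequence:
            raise ValidationError("invariant violated: segment_sequence is empty")
        contractions = [s for s in self.segment_sequence if s.kind == "contraction"]
        if len(contractions) != 1:
            raise ValidationError(
                f"invariant violated: exactly one contraction segment required, got {len(contractions)}"
            )
        c = contractions[0]
        if not math.isclose(c.length, self.L_c, rel_tol=1e-9):
            raise ValidationError("invariant violated: contraction segment length must equal L_c")
        if not math.isclose(c.width, self.w_c, rel_tol=1e-9):
            raise ValidationError("invariant violated: contraction segment width must equal w_c")
        if self.D_e is not None and not self.D_e > self.w_c:
            raise ValidationError(
                f"invariant violated: D_e must exceed w_c (got D_e={self.D_e}, w_c={self.w_c})"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def L_total(self) -> float:
        """Sensed channel length (μm): sum of all segment lengths."""
        return float(sum(s.length for s in self.segment_sequence))

    @property
    def contraction_index(self) -> int:
        return next(i for i, s in enumerate(self.segment_sequence) if s.kind == "contraction")

    @property
    def n_pre_pairs(self) -> int:
        """Number of pore segments ahead of the contraction channel."""
        ci = self.contraction_index
        return sum(1 for s in self.segment_sequence[:ci] if s.kind == "pore")

    @property
    def n_post_pairs(self) -> int:
        """Number of pore segments after the contraction channel."""
        ci = self.contraction_index
        return sum(1 for s in self.segment_sequence[ci + 1 :] if s.kind == "pore")

    @property
    def pore_length(self) -> float:
        return next(s.length for s in self.segment_sequence if s.kind == "pore")

    @property
    def node_length(self) -> float:
        return next(s.length for s in self.segment_sequence if s.kind == "node")

    @property
    def contraction_volume(self) -> float:
        """Volume of the contraction channel, L_c · w_c · h_channel (μm³)."""
        return self.L_c * self.w_c * self.h_channel

    def with_effective_diameter(self, D_e: float) -> "DeviceGeometry":
        return replace(self, D_e=D_e)

    # -- construction -------------------------------------------------------

    @classmethod
    def standard(
        cls,
        *,
        w_pore: float = 25.0,
        w_node: float = 85.0,
        w_c: float = 12.0,
        h_channel: float = 30.0,
        L_c: float = 2055.0,
        pore_length: float = 100.0,
        node_length: float = 85.0,
        n_pre_pairs: int = 3,
        n_post_pairs: int = 7,
        D_e: float | None = None,
    ) -> "DeviceGeometry":
        """Build the canonical layout: n_pre pore/node pairs, one contraction
        channel, n_post node/pore pairs."""
        if n_pre_pairs < 1 or n_post_pairs < 1:
            raise ValidationError("at least one node-pore pair is required on each side")
        pre: list[Segment] = []
        for _ in range(n_pre_pairs):
            pre.append(Segment("pore", pore_length, w_pore))
            pre.append(Segment("node", node_length, w_node))
        post: list[Segment] = []
        for _ in range(n_post_pairs):
            post.append(Segment("node", node_length, w_node))
            post.append(Segment("pore", pore_length, w_pore))
        seq = tuple(pre + [Segment("contraction", L_c, w_c)] + post)
        return cls(
            segment_sequence=seq,
            w_pore=w_pore,
            w_node=w_node,
            w_c=w_c,
            h_channel=h_channel,
            L_c=L_c,
            D_e=D_e,
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Data-acquisition settings for one run."""

    sampling_rate: float = 50_000.0  # Hz
    applied_voltage: float = 1.0  # V
    inlet_pressure: float = 21.0  # kPa
    lowpass_cutoff: float = 5_000.0  # Hz
    baseline_current_hint: float | None = None  # normalized units

    def __post_init__(self) -> None:
        if not self.applied_voltage > 0:
            raise ValidationError("invariant violated: applied_voltage must be > 0")
        if not self.sampling_rate > 2 * self.lowpass_cutoff:
            raise ValidationError(
                "invariant violated: sampling_rate must exceed 2 × lowpass_cutoff "
                f"(got {self.sampling_rate} Hz vs cutoff {self.lowpass_cutoff} Hz)"
            )


@dataclass(frozen=True)
class RawTrace:
    """A uniformly sampled current-vs-time trace, current normalized to I=1."""

    t: np.ndarray  # seconds
    i: np.ndarray  # normalized current
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        i = np.asarray(self.i, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "i", i)
        if t.ndim != 1 or i.ndim != 1 or t.shape != i.shape:
            raise ValidationError("trace arrays must be 1-D and of equal length")
        if len(t) < 2:
            raise ValidationError("trace must have at least 2 samples")
        if not np.all(np.isfinite(i)):
            idx = int(np.flatnonzero(~np.isfinite(i))[0])
            raise TraceFormatError(f"non-finite current sample at row {idx}")
        if not np.all(np.isfinite(t)):
            idx = int(np.flatnonzero(~np.isfinite(t))[0])
            raise TraceFormatError(f"non-finite time sample at row {idx}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            idx = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise TraceFormatError(f"time base not strictly increasing at row {idx}")
        mean_dt = float(dt.mean())
        if np.max(np.abs(dt - mean_dt)) > TIME_JITTER_TOL * mean_dt:
            raise TraceFormatError(
                f"non-uniform time base (relative jitter exceeds {TIME_JITTER_TOL:g})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz, derived from the time base."""
        return 1.0 / self.dt


# --------------------------------------------------------------------------
# config I/O

_DEVICE_MANDATORY = ("w_pore", "w_node", "w_c", "h_channel", "L_c")
_DEVICE_OPTIONAL = ("pore_length", "node_length", "n_pre_pairs", "n_post_pairs", "D_e")
_ACQ_KEYS = {
    "sampling_rate": "Hz",
    "applied_voltage": "V",
    "inlet_pressure": "kPa",
    "lowpass_cutoff": "Hz",
    "baseline_current_hint": None,
}


def load_device_config(path) -> tuple[DeviceGeometry, AcquisitionConfig]:
    """Read a device/acquisition config (YAML or JSON) and validate it.

    The file has a mandatory ``device`` section (keys ``w_pore``, ``w_node``,
    ``w_c``, ``h_channel``, ``L_c``; optional segment-layout keys and
    ``D_e``) and an optional ``acquisition`` section.  Lengths default to μm,
    frequencies to Hz; values may be unit-suffixed strings.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "device" not in raw:
        raise ConfigError("config must be a mapping with a 'device' section")
    dev = raw["device"]
    if not isinstance(dev, dict):
        raise ConfigError("'device' section must be a mapping")
    for key in _DEVICE_MANDATORY:
        if key not in dev:
            raise ConfigError(f"missing mandatory device key '{key}'")
    unknown = set(dev) - set(_DEVICE_MANDATORY) - set(_DEVICE_OPTIONAL)
    if unknown:
        raise ConfigError(f"unknown device key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key in _DEVICE_MANDATORY:
        kwargs[key] = _parse_quantity(dev[key], "um", key)
    for key in ("pore_length", "node_length"):
        if key in dev:
            kwargs[key] = _parse_quantity(dev[key], "um", key)
    for key in ("n_pre_pairs", "n_post_pairs"):
        if key in dev:
            kwargs[key] = int(dev[key])
    if "D_e" in dev and dev["D_e"] is not None:
        kwargs["D_e"] = _parse_quantity(dev["D_e"], "um", "D_e")
    geometry = DeviceGeometry.standard(**kwargs)

    acq_raw = raw.get("acquisition", {}) or {}
    if not isinstance(acq_raw, dict):
        raise ConfigError("'acquisition' section must be a mapping")
    unknown = set(acq_raw) - set(_ACQ_KEYS)
    if unknown:
        raise ConfigError(f"unknown acquisition key(s): {sorted(unknown)}")
    acq_kwargs = {}
    for key, unit in _ACQ_KEYS.items():
        if key in acq_raw and acq_raw[key] is not None:
            acq_kwargs[key] = (
                _parse_quantity(acq_raw[key], unit, key) if unit else float(acq_raw[key])
            )
    acquisition = AcquisitionConfig(**acq_kwargs)
    return geometry, acquisition


# --------------------------------------------------------------------------
# trace I/O


def write_trace(trace: RawTrace, path) -> None:
    """Write a trace as two-column delimited text with '#' metadata headers.

    Floats are written with 17 significant digits so that a read-back is
    bit-identical.
    """
    path = Path(path)
    lines = ["# mechanops trace"]
    meta = dict(trace.meta)
    meta.setdefault("sampling_rate_hz", trace.fs)
    meta.setdefault("units", "normalized")
    for key, value in meta.items():
        lines.append(f"# {key} = {value}")
    for tk, ik in zip(trace.t, trace.i):
        lines.append(f"{tk:.17g},{ik:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> RawTrace:
    """Read a two-column delimited trace file written by :func:`write_trace`
    (or any compatible '#'-commented CSV/whitespace table)."""
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                for sep in ("=", ":"):
                    if sep in body:
                        key, _, value = body.partition(sep)
                        meta[key.strip()] = value.strip()
                        break
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) != 2:
                raise TraceFormatError(f"expected 2 columns at row {len(rows)} (line {lineno + 1})")
            try:
                tv, iv = float(parts[0]), float(parts[1])
            except ValueError:
                raise TraceFormatError(f"unparsable number at row {len(rows)}") from None
            if math.isnan(tv) or math.isnan(iv):
                raise TraceFormatError(f"NaN sample at row {len(rows)}")
            rows.append((tv, iv))
    if len(rows) < 2:
        raise TraceFormatError("trace file has fewer than 2 samples")
    arr = np.asarray(rows, dtype=float)
    if "units" in meta:
        meta["normalized"] = meta["units"] == "normalized"
    if "sampling_rate_hz" in meta:
        meta["sampling_rate_hz"] = float(meta["sampling_rate_hz"])
    return RawTrace(t=arr[:, 0], i=arr[:, 1], meta=meta)


# --------------------------------------------------------------------------
# phenotype table I/O


def write_phenotypes(records: Sequence, path) -> None:
    """Write per-cell phenotypes as a CSV with fixed column order.

    ``records`` may be CellPhenotype objects or anything exposing the same
    attributes.  A censored recovery time is written as an empty ``dT_r_ms``
    cell with ``dT_r_censored=True``.
    """
    if len(records) == 0:
        raise ValidationError("cannot write an empty phenotype table")
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "D_cell_um": r.D_cell,
                "L_deform_um": r.L_deform,
                "delta_deform": r.delta_deform,
                "strain": r.strain,
                "dT_cont_ms": r.dT_cont,
                "dT_r_ms": np.nan if r.dT_r_censored else r.dT_r,
                "dT_r_censored": bool(r.dT_r_censored),
                "wCDI": r.wCDI,
                "recovery_class": r.recovery_class,
            }
        )
    frame = pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table back into a DataFrame with the canonical columns."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(PHENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise TraceFormatError(f"phenotype table missing column(s): {sorted(missing)}")
    frame["dT_r_censored"] = frame["dT_r_censored"].astype(bool)
    return frame[list(PHENOTYPE_COLUMNS)]
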