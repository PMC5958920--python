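"""Biophysics layer: Coulter blockade sizing, deformation geometry, the
whole-cell deformability index (wCDI), recovery classification, and cortical
tension.

The sizing model is the classical resistive-pulse (Coulter) relation for a
sphere of diameter ``d`` in a channel of effective electrical diameter
``D_e`` and sensed length ``L``::

    ΔI/I = d³ / (D_e² L) · 1 / (1 − 0.8 (d/D_e)³)

which is strictly increasing in ``d`` up to the pole of the correction
factor at d = D_e · 0.8^(−1/3).  ``D_e`` is calibrated from microspheres of
known diameter, after which the relation is inverted numerically for each
cell.

Inside the contraction channel the compressed cell is modelled as an oblate
spheroid squeezed to the channel width ``w_c``; its occluded volume
satisfies V_deform = π w_c L_deform² / 6 and relates to the contraction
blockade by ΔI_c/I ≈ V_deform / V_contraction.

The wCDI is the dimensionless product assembled by the Buckingham-π
procedure from the contraction length L_c, the node-section flow speed
U_flow, the channel height h_channel, the free diameter D_cell and the
contraction transit time ΔT_cont::

    wCDI = [L_c / (U_flow · h_channel)] · [D_cell / ΔT_cont]

Higher wCDI means a more deformable cell; the index divides out the
first-order effect of cell size on transit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .device import DeviceGeometry
from .errors import (
    CalibrationError,
    DegenerateEventError,
    DomainError,
    ParameterError,
    ValidationError,
)

#: d/D_e ratio at which the blockade correction factor diverges.
BLOCKADE_POLE = 0.8 ** (-1.0 / 3.0)

#: Relative tolerance of the numerical inversions of the blockade relation.
ROOT_RTOL = 1e-9

RECOVERY_CLASSES = ("instant", "transient", "prolonged")


# --------------------------------------------------------------------------
# Coulter blockade relation and its inversions


def blockade_fraction(d: float, D_e: float, L_total: float) -> float:
    """Fractional current drop ΔI/I for a sphere of diameter ``d`` (μm).

    Valid for 0 ≤ d < D_e·0.8^(−1/3); strictly increasing in ``d`` there.
    """
    if D_e <= 0 or L_total <= 0:
        raise DomainError("D_e and L_total must be positive")
    if d < 0:
        raise DomainError("diameter must be non-negative")
    ratio3 = (d / D_e) ** 3
    denom = 1.0 - 0.8 * ratio3
    if denom <= 0:
        raise DomainError(
            f"d/D_e = {d / D_e:.4f} at or past the pole 0.8^(-1/3) ≈ {BLOCKADE_POLE:.4f}"
        )
    return d**3 / (D_e**2 * L_total) / denom


def invert_cell_diameter(fraction: float, D_e: float, L_total: float) -> float:
    """Solve the blockade relation for the particle diameter (μm).

    Bracketed root-finding on [0, 0.999·D_e·0.8^(−1/3)]; the returned
    diameter reproduces ``fraction`` to better than 1e-9 relative.
    """
    if not fraction > 0:
        raise DomainError("blockade fraction must be > 0")
    d_hi = 0.999 * D_e * BLOCKADE_POLE
    f_hi = blockade_fraction(d_hi, D_e, L_total)
    if fraction > f_hi:
        raise DomainError(
            f"fraction {fraction:.3e} exceeds the attainable range (max {f_hi:.3e}) for D_e={D_e}"
        )
    d = brentq(
        lambda x: blockade_fraction(x, D_e, L_total) - fraction,
        0.0,
        d_hi,
        xtol=1e-13,
        rtol=8.9e-16,
    )
    if abs(blockade_fraction(d, D_e, L_total) - fraction) > ROOT_RTOL * fraction:
        raise DomainError("diameter inversion failed to converge")  # pragma: no cover
    return float(d)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the microsphere calibration of the effective diameter."""

    D_e: float  # μm
    residuals: np.ndarray  # per-sphere relative residuals
    n_spheres: int
    sphere_d: float  # μm
    L_total: float  # μm

    @property
    def residual_rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.residuals))))


def calibrate_effective_diameter(
    observed_fractions: Sequence[float], d_sphere: float, L_total: float
) -> CalibrationResult:
    """Solve the blockade relation for D_e from microsphere blockades.

    The mean observed ΔI/I is matched by bracketed root-finding, subject to
    the physical constraint D_e > d_sphere; per-sphere relative residuals
    against the fitted relation are reported.
    """
    fractions = np.asarray(observed_fractions, dtype=float)
    if fractions.size == 0:
        raise CalibrationError("at least one observed blockade fraction is required")
    if np.any(fractions <= 0):
        raise CalibrationError("observed blockade fractions must all be positive")
    if d_sphere <= 0 or L_total <= 0:
        raise CalibrationError("sphere diameter and channel length must be positive")
    target = float(fractions.mean())

    lo = d_sphere * (1.0 + 1e-12)
    g = lambda De: blockade_fraction(d_sphere, De, L_total) - target  # noqa: E731
    if g(lo) < 0:
        # Even the smallest admissible channel (D_e → d_sphere) blockades less
        # than observed: no solution with D_e > d_sphere.
        raise CalibrationError(
            f"mean fraction {target:.3e} too large for any D_e > sphere diameter {d_sphere} μm"
        )
    hi = 10.0 * d_sphere
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise CalibrationError("no admissible effective diameter below 1e9 μm")
    D_e = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    fitted = blockade_fraction(d_sphere, D_e, L_total)
    residuals = (fractions - fitted) / fitted
    return CalibrationResult(
        D_e=float(D_e),
        residuals=residuals,
        n_spheres=int(fractions.size),
        sphere_d=float(d_sphere),
        L_total=float(L_total),
    )


# --------------------------------------------------------------------------
# deformation geometry


def deformed_geometry(
    fraction_c: float, geometry: DeviceGeometry, occlusion_scale: float = 1.0
) -> tuple[float, float]:
    """Convert the contraction blockade ΔI_c/I into (V_deform, L_deform).

    The occluded volume is V_deform = (ΔI_c/I) · V_contraction /
    ``occlusion_scale`` (the proportionality constant defaults to 1 and is
    exposed for empirical calibration), and the oblate-spheroid model
    V_deform = π w_c L_deform²/6 yields the elongation length.
    """
    if not fraction_c > 0:
        raise DomainError("contraction blockade fraction must be > 0")
    if fraction_c >= 1:
        raise DomainError(
            f"contraction blockade fraction {fraction_c} ≥ 1 is physically implausible"
        )
    if not occlusion_scale > 0:
        raise ParameterError("occlusion_scale must be > 0")
    V_deform = fraction_c * geometry.contraction_volume / occlusion_scale
    L_deform = math.sqrt(6.0 * V_deform / (math.pi * geometry.w_c))
    return V_deform, L_deform


def transverse_deformation(L_deform: float, D_cell: float) -> float:
    """Transverse deformation δ_deform = L_deform / D_cell (> 1 when the
    cell elongates beyond its free diameter)."""
    if not (L_deform > 0 and D_cell > 0):
        raise DomainError("L_deform and D_cell must be positive")
    return L_deform / D_cell


def strain(D_cell: float, w_c: float) -> float:
    """Imposed compressive strain ε = (D_cell − w_c)/D_cell.

    Negative values (cell smaller than the contraction channel) are allowed;
    such cells transit un-deformed.
    """
    if not D_cell > 0:
        raise DomainError("D_cell must be positive")
    return (D_cell - w_c) / D_cell


# --------------------------------------------------------------------------
# flow context, wCDI and π-terms


@dataclass(frozen=True)
class FlowContext:
    """Per-cell (or per-run) flow velocities plus optional fluid metadata."""

    U_flow: float  # μm ms⁻¹, node-section velocity leading into the contraction
    U_c: float | None = None  # μm ms⁻¹, contraction transit velocity L_c/ΔT_cont
    mu: float | None = None  # Pa·s, fluid viscosity (metadata)
    E: float | None = None  # Pa, elastic modulus (metadata only)

    def __post_init__(self) -> None:
        if not self.U_flow > 0:
            raise ValidationError("U_flow must be > 0")
        if self.U_c is not None and not self.U_c > 0:
            raise ValidationError("U_c must be > 0 when set")


def estimate_flow_velocity(record, geometry: DeviceGeometry) -> FlowContext:
    """Estimate U_flow from the last pre-contraction pore sub-pulse.

    The cell's speed through a pore of known length is used as a proxy for
    the fluid velocity in the node section leading into the contraction;
    U_c = L_c/ΔT_cont is reported alongside.
    """
    if not record.pre_pulses:
        raise DegenerateEventError("record has no pre-contraction pore sub-pulses")
    last_pre = record.pre_pulses[-1]
    if not last_pre.dT > 0:
        raise DegenerateEventError("zero-duration pre-contraction pore sub-pulse")
    U_flow = geometry.pore_length / last_pre.dT
    U_c = geometry.L_c / record.dT_cont if record.dT_cont > 0 else None
    return FlowContext(U_flow=U_flow, U_c=U_c)


def compute_wcdi(
    D_cell: float, dT_cont: float, flow: FlowContext, geometry: DeviceGeometry
) -> float:
    """Whole-cell deformability index, [L_c/(U_flow·h_channel)]·[D_cell/ΔT_cont].

    Dimensionless; strictly increasing in D_cell and strictly decreasing in
    ΔT_cont.
    """
    if not (D_cell > 0 and dT_cont > 0):
        raise DomainError("D_cell and dT_cont must be positive")
    return (geometry.L_c / (flow.U_flow * geometry.h_channel)) * (D_cell / dT_cont)


@dataclass(frozen=True)
class PiTerms:
    """The four dimensionless groups of the Buckingham-π analysis.

    ``pi1`` involves the elastic modulus and is only set when E and μ are
    provided; the binding algebraic contract is pi2·pi3·pi4 = wCDI.
    """

    pi2: float
    pi3: float
    pi4: float
    pi1: float | None = None

    def __post_init__(self) -> None:
        for name in ("pi2", "pi3", "pi4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0")
        if self.pi1 is not None and not (math.isfinite(self.pi1) and self.pi1 > 0):
            raise ValidationError("pi1 must be finite and > 0 when set")

    @property
    def product(self) -> float:
        return self.pi2 * self.pi3 * self.pi4


def compute_pi_terms(
    D_cell: float, dT_cont: float, flow: FlowContext, geometry: DeviceGeometry
) -> PiTerms:
    """π-terms: pi2 = h/(ΔT_cont·U_flow), pi3 = D_cell/h, pi4 = L_c/h.

    pi1 = h·E/(U_flow·μ) is computed only when both E and μ are given on the
    flow context (U_flow converted from μm ms⁻¹ to μm s⁻¹ so the group is
    dimensionless).
    """
    if not (D_cell > 0 and dT_cont > 0):
        raise DomainError("D_cell and dT_cont must be positive")
    h = geometry.h_channel
    pi2 = h / (dT_cont * flow.U_flow)
    pi3 = D_cell / h
    pi4 = geometry.L_c / h
    pi1 = None
    if flow.E is not None and flow.mu is not None:
        pi1 = h * flow.E / ((flow.U_flow * 1e3) * flow.mu)
    return PiTerms(pi2=pi2, pi3=pi3, pi4=pi4, pi1=pi1)


# --------------------------------------------------------------------------
# recovery classification


def classify_recovery(dT_r: float, window: float, censored: bool = False) -> str:
    """Classify recovery: instant (ΔT_r = 0), transient (0 < ΔT_r ≤ window),
    prolonged (censored, or ΔT_r > window)."""
    if not window > 0:
        raise ParameterError("recovery window must be > 0")
    if censored:
        return "prolonged"
    if dT_r < 0:
        raise ParameterError("recovery time cannot be negative")
    if dT_r == 0:
        return "instant"
    if dT_r <= window:
        return "transient"
    return "prolonged"


# --------------------------------------------------------------------------
# cortical tension (micropipette aspiration)


@dataclass(frozen=True)
class AspirationMeasurement:
    """One micropipette-aspiration measurement at the critical pressure,
    where the aspirated length equals the pipette radius (L_p = R_p)."""

    R_p: float  # μm, pipette radius
    R_c: float  # μm, cell radius
    dP_crit: float  # kPa
    L_p: float  # μm
    T_eff: float  # mN m⁻¹

    def __post_init__(self) -> None:
        if not (self.R_c > self.R_p > 0):
            raise ValidationError("require R_c > R_p > 0")
        if not self.dP_crit > 0:
            raise ValidationError("dP_crit must be > 0")
        if not self.T_eff > 0:
            raise ValidationError("T_eff must be > 0")


def cortical_tension(dP_crit: float, R_p: float, R_c: float) -> float:
    """Cortical tension from the Law of Laplace at the critical aspiration
    pressure: T_eff = ΔP_crit / (2 (1/R_p − 1/R_c)).

    With ΔP_crit in kPa and radii in μm the result is in mN m⁻¹ directly
    (1 kPa·μm = 1 mN m⁻¹).
    """
    if not (R_c > R_p > 0):
        raise DomainError("require R_c > R_p > 0 (Laplace inversion undefined otherwise)")
    if not dP_crit > 0:
        raise DomainError("dP_crit must be > 0")
    return dP_crit / (2.0 * (1.0 / R_p - 1.0 / R_c))


# --------------------------------------------------------------------------
# per-cell phenotype assembly


@dataclass(frozen=True)
class CellPhenotype:
    """The four biophysical readouts plus wCDI and recovery class for one cell."""

    cell_id: int
    D_cell: float  # μm
    V_deform: float  # μm³
    L_deform: float  # μm
    delta_deform: float
    strain: float
    dT_cont: float  # ms
    dT_r: float  # ms (equal to the window when censored)
    dT_r_censored: bool
    wCDI: float
    recovery_class: str
    U_flow: float | None = None  # μm ms⁻¹
    deformed: bool = True  # False when strain ≤ 0 (cell narrower than w_c)

    def __post_init__(self) -> None:
        if self.recovery_class not in RECOVERY_CLASSES:
            raise ValidationError(f"recovery_class must be one of {RECOVERY_CLASSES}")
        if not self.wCDI > 0:
            raise ValidationError("wCDI must be > 0")
        if not math.isclose(self.delta_deform, self.L_deform / self.D_cell, rel_tol=1e-9):
            raise ValidationError("delta_deform must equal L_deform / D_cell")


def phenotype_from_measurements(
    *,
    cell_id: int,
    dI_np: float,
    dI_c: float,
    dT_cont: float,
    dT_r: float,
    dT_r_censored: bool,
    U_flow: float,
    window: float,
    geometry: DeviceGeometry,
    occlusion_scale: float = 1.0,
) -> CellPhenotype:
    """Assemble a CellPhenotype from scalar pulse measurements.

    Requires a calibrated geometry (D_e set).  ``dT_r`` is in ms measured
    from the contraction exit; when censored it is reported at the window.
    """
    if geometry.D_e is None:
        raise ValidationError("geometry has no effective diameter; run calibration first")
    D_cell = invert_cell_diameter(dI_np, geometry.D_e, geometry.L_total)
    V_deform, L_deform = deformed_geometry(dI_c, geometry, occlusion_scale)
    delta = transverse_deformation(L_deform, D_cell)
    eps = strain(D_cell, geometry.w_c)
    flow = FlowContext(U_flow=U_flow, U_c=geometry.L_c / dT_cont)
    wcdi = compute_wcdi(D_cell, dT_cont, flow, geometry)
    rc = classify_recovery(0.0 if dT_r_censored else dT_r, window, censored=dT_r_censored)
    return CellPhenotype(
        cell_id=cell_id,
        D_cell=D_cell,
        V_deform=V_deform,
        L_deform=L_deform,
        delta_deform=delta,
        strain=eps,
        dT_cont=dT_cont,
        dT_r=window if dT_r_censored else dT_r,
        dT_r_censored=dT_r_censored,
        wCDI=wcdi,
        recovery_class=rc,
        U_flow=U_flow,
        deformed=eps > 0,
    )


def phenotype_from_record(
    record, geometry: DeviceGeometry, occlusion_scale: float = 1.0
) -> CellPhenotype:
    """Assemble a CellPhenotype from a PulseRecord (see pulses module)."""
    flow = estimate_flow_velocity(record, geometry)
    return phenotype_from_measurements(
        cell_id=record.cell_id,
        dI_np=record.dI_np,
        dI_c=record.dI_c,
        dT_cont=record.dT_cont,
        dT_r=record.dT_r,
        dT_r_censored=record.dT_r_censored,
        U_flow=flow.U_flow,
        window=record.window_ms,
        geometry=geometry,
        occlusion_scale=occlusion_scale,
    )
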