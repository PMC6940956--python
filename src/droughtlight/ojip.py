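"""JIP-test analysis of OJIP chlorophyll-a fluorescence transients.

The fast fluorescence rise of a dark-adapted leaf under saturating light
passes through the landmarks O (~50 us), K (300 us), J (2 ms), I (30 ms)
and P (the maximum, FM). The JIP-test (Strasser framework) converts these
landmarks into PSII quantum yields, specific energy fluxes per reaction
center (RC) and per illuminated cross-section (CS), and the performance
index PI_ABS.

Implemented quantities, writing phiP0 = 1 - F0/FM, VJ = (FJ-F0)/(FM-F0),
VI = (FI-F0)/(FM-F0), M0 = 4 (F300-F0)/(FM-F0):

    phiD0  = F0/FM                  psiE0  = 1 - VJ
    phiE0  = phiP0 (1 - VJ)         phiR0  = phiP0 (1 - VI)
    deltaR0 = (1 - VI)/(1 - VJ)
    TR0/RC = M0 / VJ                ABS/RC = (M0/VJ) / phiP0
    DI0/RC = ABS/RC - TR0/RC        ET0/RC = (M0/VJ) psiE0
    RC/CS0 = F0 phiP0 VJ / M0       gammaRC = 1/(1 + ABS/RC)
    PI_ABS = (phiP0 VJ / M0) * [phiP0/(1-phiP0)] * [(1-VJ)/VJ]

Per-cross-section fluxes use the F0 proxy for ABS/CS (switchable to FM), so
that RC/CS0 * ABS/RC = ABS/CS holds as an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    CoverageError,
    DegenerateTransientError,
    UndefinedParameterError,
    ValidationError,
)

#: Landmark times in seconds: O (F0), K (F300), J (FJ), I (FI).
LANDMARK_TIMES = {"O": 5e-5, "K": 3e-4, "J": 2e-3, "I": 3e-2}


@dataclass
class FluorescenceTransient:
    """One OJIP trace: strictly increasing times (s), positive fluorescence."""

    time: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.fluorescence.shape:
            raise ValidationError("time and fluorescence must be equal-length 1-D arrays")
        if self.time.size < 2:
            raise ValidationError("a transient needs at least two points")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)) or np.any(self.fluorescence <= 0):
            raise ValidationError("fluorescence values must be finite and positive")
        if self.time[0] <= 0:
            raise ValidationError("times must be positive (log-time analysis)")


@dataclass(frozen=True)
class JipLandmarks:
    """Landmark fluorescence values and the derived VJ, VI, M0."""

    F0: float
    F300: float
    FJ: float
    FI: float
    FM: float
    VJ: float
    VI: float
    M0: float


@dataclass
class JipParameters:
    """Full JIP-test parameter vector derived from one landmark set."""

    phiP0: float
    phiE0: float
    phiR0: float
    phiD0: float
    deltaR0: float
    psiE0: float
    ABS_RC: float
    TR0_RC: float
    DI0_RC: float
    ET0_RC: float
    RC_CS0: float
    gammaRC: float
    PI_ABS: float
    ABS_CS: float | None = None
    TR0_CS: float | None = None
    ET0_CS: float | None = None
    DI0_CS: float | None = None


@dataclass
class VtCurve:
    """Relative variable fluorescence Vt = (Ft - F0)/(FM - F0)."""

    time: np.ndarray
    vt: np.ndarray
    label: str = ""


@dataclass
class DifferentialCurve:
    """Delta-Vt = Vt(treated) - Vt(control) on a shared log-time grid.

    Band amplitudes are delta-Vt read at the K (300 us), J (2 ms) and
    I (30 ms) times; under stress the K band is positive by this sign
    convention.
    """

    time: np.ndarray
    delta_vt: np.ndarray
    delta_k: float
    delta_j: float
    delta_i: float
    label: str = ""


def _interp_log_time(transient: FluorescenceTransient, t: float) -> float:
    """Fluorescence at time ``t``, linear in (ln t, F) if off-grid."""
    return float(np.interp(np.log(t), np.log(transient.time), transient.fluorescence))


def extract_landmarks(transient: FluorescenceTransient) -> JipLandmarks:
    """Read F0/F300/FJ/FI at 50 us/300 us/2 ms/30 ms and FM as the maximum.

    Off-grid landmark times are interpolated linearly in log-time. Raises
    :class:`CoverageError` if the trace does not span the landmark times and
    :class:`DegenerateTransientError` if FM <= F0.
    """
    t_lo, t_hi = min(LANDMARK_TIMES.values()), max(LANDMARK_TIMES.values())
    if transient.time[0] > t_lo or transient.time[-1] < t_hi:
        raise CoverageError(
            f"transient [{transient.time[0]:g}, {transient.time[-1]:g}] s does not "
            f"cover the landmark range [{t_lo:g}, {t_hi:g}] s"
        )
    f0 = _interp_log_time(transient, LANDMARK_TIMES["O"])
    f300 = _interp_log_time(transient, LANDMARK_TIMES["K"])
    fj = _interp_log_time(transient, LANDMARK_TIMES["J"])
    fi = _interp_log_time(transient, LANDMARK_TIMES["I"])
    fm = float(transient.fluorescence.max())
    if fm <= f0:
        raise DegenerateTransientError(
            f"FM={fm:g} <= F0={f0:g}: no variable fluorescence"
        )
    fv = fm - f0
    return JipLandmarks(
        F0=f0, F300=f300, FJ=fj, FI=fi, FM=fm,
        VJ=(fj - f0) / fv, VI=(fi - f0) / fv, M0=4.0 * (f300 - f0) / fv,
    )


def relative_variable_fluorescence(transient: FluorescenceTransient) -> VtCurve:
    """Vt(t) = (Ft - F0)/(FM - F0) on the input time grid."""
    lm = extract_landmarks(transient)
    vt = (transient.fluorescence - lm.F0) / (lm.FM - lm.F0)
    return VtCurve(time=transient.time.copy(), vt=vt, label=transient.label)


def differential_curve(treated: VtCurve, control: VtCurve) -> DifferentialCurve:
    """Delta-Vt = treated - control, resampled to a shared log-time grid.

    The shared grid is the treated grid restricted to the overlap of both
    curves, with the K/J/I landmark times inserted; the control curve is
    interpolated linearly in log-time onto it.
    """
    lo = max(treated.time[0], control.time[0])
    hi = min(treated.time[-1], control.time[-1])
    if lo >= hi:
        raise CoverageError("treated and control curves have disjoint time ranges")
    band_times = [LANDMARK_TIMES[k] for k in ("K", "J", "I")]
    if lo > min(band_times) or hi < max(band_times):
        raise CoverageError("shared time range does not cover the K/J/I band times")
    grid = treated.time[(treated.time >= lo) & (treated.time <= hi)]
    grid = np.unique(np.concatenate([grid, band_times]))
    log_grid = np.log(grid)
    vt_t = np.interp(log_grid, np.log(treated.time), treated.vt)
    vt_c = np.interp(log_grid, np.log(control.time), control.vt)
    delta = vt_t - vt_c
    bands = {
        k: float(np.interp(np.log(LANDMARK_TIMES[k]), log_grid, delta))
        for k in ("K", "J", "I")
    }
    label = f"{treated.label} - {control.label}".strip(" -")
    return DifferentialCurve(
        time=grid, delta_vt=delta,
        delta_k=bands["K"], delta_j=bands["J"], delta_i=bands["I"], label=label,
    )


def jip_parameters(landmarks: JipLandmarks) -> JipParameters:
    """Derive the full JIP-test parameter set from one landmark set.

    Raises :class:`UndefinedParameterError` when VJ or VI is outside (0, 1)
    or M0 <= 0, naming the offending landmark.
    """
    if landmarks.FM <= landmarks.F0:
        raise UndefinedParameterError("FM <= F0: degenerate landmark set")
    for name, v in (("VJ", landmarks.VJ), ("VI", landmarks.VI)):
        if not 0.0 < v < 1.0:
            raise UndefinedParameterError(
                f"{name}={v:g} outside (0, 1): JIP parameters undefined"
            )
    if landmarks.M0 <= 0:
        raise UndefinedParameterError(f"M0={landmarks.M0:g} <= 0: slope undefined")

    vj, vi, m0 = landmarks.VJ, landmarks.VI, landmarks.M0
    phi_p0 = 1.0 - landmarks.F0 / landmarks.FM
    phi_d0 = landmarks.F0 / landmarks.FM
    psi_e0 = 1.0 - vj
    phi_e0 = phi_p0 * psi_e0
    delta_r0 = (1.0 - vi) / (1.0 - vj)
    phi_r0 = phi_p0 * (1.0 - vi)
    tr0_rc = m0 / vj
    abs_rc = tr0_rc / phi_p0
    di0_rc = abs_rc - tr0_rc
    et0_rc = tr0_rc * psi_e0
    rc_cs0 = landmarks.F0 * phi_p0 * vj / m0
    gamma_rc = 1.0 / (1.0 + abs_rc)
    pi_abs = (phi_p0 * vj / m0) * (phi_p0 / (1.0 - phi_p0)) * ((1.0 - vj) / vj)
    return JipParameters(
        phiP0=phi_p0, phiE0=phi_e0, phiR0=phi_r0, phiD0=phi_d0,
        deltaR0=delta_r0, psiE0=psi_e0,
        ABS_RC=abs_rc, TR0_RC=tr0_rc, DI0_RC=di0_rc, ET0_RC=et0_rc,
        RC_CS0=rc_cs0, gammaRC=gamma_rc, PI_ABS=pi_abs,
    )


def cross_section_fluxes(
    params: JipParameters,
    landmarks: JipLandmarks,
    basis: Literal["F0", "FM"] = "F0",
) -> JipParameters:
    """Fill per-cross-section fluxes in place (and return ``params``).

    ABS/CS is approximated by F0 (convention; ``basis="FM"`` switches to the
    FM proxy). TR0/CS = phiP0 * ABS/CS, ET0/CS = phiE0 * ABS/CS and
    DI0/CS = ABS/CS - TR0/CS. With the F0 basis, RC/CS0 * ABS/RC = ABS/CS
    holds exactly.
    """
    abs_cs = landmarks.F0 if basis == "F0" else landmarks.FM
    params.ABS_CS = abs_cs
    params.TR0_CS = params.phiP0 * abs_cs
    params.ET0_CS = params.phiE0 * abs_cs
    params.DI0_CS = abs_cs - params.TR0_CS
    return params


def analyze_transient(transient: FluorescenceTransient) -> tuple[JipLandmarks, JipParameters]:
    """Landmarks plus the full parameter vector (per-RC and per-CS) for one trace."""
    lm = extract_landmarks(transient)
    params = cross_section_fluxes(jip_parameters(lm), lm)
    return lm, params
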