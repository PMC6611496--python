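"""Thin-lens pseudophakic vergence optics and the SRK/T formula chain.

This module holds the optical core of the package: the SRK/T effective lens
position (ELP) and emmetropic-power formulas, and the "reversed" vergence
model that maps an eye's biometry, its implanted IOL power and the lens
position to the residual refraction at the spectacle plane.  From that model
three derived quantities are built:

``rx_theor_post``
    theoretical post-operative spherical-equivalent refraction (D),
``rx_05iol``
    refraction change at the spectacle plane per 0.5 D of IOL power,
``iol_ideal`` / ``rx_predicted``
    the lens power that would have produced zero residual refraction for a
    given eye, and the back-calculated residual for an arbitrary predicted
    power.

Sign conventions: refractions are spherical equivalents in diopters with
positive = hyperopic residual; IOL powers are positive (converging); all
axial distances in millimeters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "OpticsConstants",
    "SrktIntermediates",
    "TargetRecord",
    "OpticsDomainError",
    "srkt_elp",
    "srkt_power_emmetropia",
    "clinical_iol_choice",
    "rx_theor_post",
    "rx_05iol",
    "iol_ideal",
    "rx_predicted",
    "iol_for_emmetropia",
]

#: Corneal refractive index used by SRK/T for the (nc - 1) keratometric term.
CORNEAL_INDEX = 1.333

#: Axial length (mm) above which SRK/T applies the long-eye LCOR correction.
LCOR_BREAKPOINT_MM = 24.2


class OpticsDomainError(ValueError):
    """An optical computation was attempted outside its physical domain."""


@dataclass(frozen=True)
class OpticsConstants:
    """Optical and lens constants shared by the vergence and SRK/T formulas.

    Parameters
    ----------
    vertex_distance_mm
        Spectacle-plane to cornea distance.  Standard phoropter convention
        is 12 mm.
    n_aqueous
        Reduced refractive index of the intraocular media, scaled by 1000
        (1336 corresponds to n = 1.336).
    keratometric_index_numerator
        Constant converting mean keratometry to corneal radius,
        r = 337.5 / K (mm).
    a_constant
        Lens-specific A-constant on the SRK D-scale (e.g. 119.1).
    iol_step_d, iol_min_d, iol_max_d
        Commercial availability of the lens: power increment and range.
    """

    vertex_distance_mm: float = 12.0
    n_aqueous: float = 1336.0
    keratometric_index_numerator: float = 337.5
    a_constant: float = 119.1
    iol_step_d: float = 0.5
    iol_min_d: float = 6.0
    iol_max_d: float = 35.0

    def __post_init__(self) -> None:
        if self.vertex_distance_mm < 0:
            raise ValueError("vertex_distance_mm must be >= 0")
        if self.n_aqueous <= 1000:
            raise ValueError("n_aqueous is on the x1000 scale and must exceed 1000")
        if self.iol_step_d <= 0:
            raise ValueError("iol_step_d must be positive")
        if self.iol_min_d >= self.iol_max_d:
            raise ValueError("iol_min_d must be below iol_max_d")


@dataclass(frozen=True)
class SrktIntermediates:
    """All intermediate quantities of the SRK/T ELP chain (mm)."""

    r_mm: float
    lcor_mm: float
    cw_mm: float
    h_mm: float
    acd_const_mm: float
    offset_mm: float
    elp_mm: float
    rethick_mm: float
    lopt_mm: float


@dataclass
class TargetRecord:
    """Per-eye derived optical quantities used in target engineering."""

    elp_mm: float
    rx_theor_post_d: float
    rx_05iol_d: float
    iol_ideal_d: float
    iol_predicted_d: Optional[float] = None
    rx_predicted_d: Optional[float] = None


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not math.isfinite(value):
        raise OpticsDomainError(f"{name} is not finite: {value!r}")
    if not (lo <= value <= hi):
        raise OpticsDomainError(f"{name}={value} outside physiological range [{lo}, {hi}]")


def srkt_elp(k_d: float, al_mm: float, consts: OpticsConstants = OpticsConstants()) -> SrktIntermediates:
    """SRK/T effective lens position from mean keratometry and axial length.

    Follows the published SRK/T chain: corneal radius from K, corrected
    axial length (LCOR, long-eye polynomial above 24.2 mm), computed corneal
    width, corneal height (square-root argument clamped at zero for the
    steep-cornea degeneracy), ACD constant from the A-constant, and the
    fixed ELP offset.  Returns every intermediate for audit.
    """
    _check_range("k_d", k_d, 30.0, 60.0)
    _check_range("al_mm", al_mm, 15.0, 40.0)

    r = consts.keratometric_index_numerator / k_d
    if al_mm <= LCOR_BREAKPOINT_MM:
        lcor = al_mm
    else:
        lcor = -3.446 + 1.716 * al_mm - 0.0237 * al_mm**2
    cw = -5.41 + 0.58412 * lcor + 0.098 * k_d
    # steep cornea / wide cornea degeneracy: clamp the radicand at zero
    h = r - math.sqrt(max(r * r - cw * cw / 4.0, 0.0))
    acd_const = 0.62467 * consts.a_constant - 68.747
    offset = acd_const - 3.336
    elp = h + offset
    rethick = 0.65696 - 0.02029 * al_mm
    lopt = al_mm + rethick
    return SrktIntermediates(
        r_mm=r, lcor_mm=lcor, cw_mm=cw, h_mm=h,
        acd_const_mm=acd_const, offset_mm=offset, elp_mm=elp,
        rethick_mm=rethick, lopt_mm=lopt,
    )


def srkt_power_emmetropia(k_d: float, al_mm: float, consts: OpticsConstants = OpticsConstants()) -> float:
    """Unrounded SRK/T IOL power targeting emmetropia.

    P = 1000·na·(na·r − (nc−1)·LOPT) / ((LOPT−ELP)·(na·r − (nc−1)·ELP))
    with na the aqueous index, nc the corneal index, r the corneal radius
    and LOPT the retina-corrected optical axial length.
    """
    inter = srkt_elp(k_d, al_mm, consts)
    na = consts.n_aqueous / 1000.0
    ncm1 = CORNEAL_INDEX - 1.0
    if inter.lopt_mm <= inter.elp_mm:
        raise OpticsDomainError(
            f"degenerate geometry: optical axial length {inter.lopt_mm:.3f} mm "
            f"not beyond ELP {inter.elp_mm:.3f} mm"
        )
    num = 1000.0 * na * (na * inter.r_mm - ncm1 * inter.lopt_mm)
    den = (inter.lopt_mm - inter.elp_mm) * (na * inter.r_mm - ncm1 * inter.elp_mm)
    return num / den


def clinical_iol_choice(k_d: float, al_mm: float, consts: OpticsConstants = OpticsConstants()) -> float:
    """Commercially available IOL power a clinic would implant for emmetropia.

    The unrounded SRK/T emmetropic power is rounded to the nearest
    ``iol_step_d`` (ties toward the lower power — the myopic-safe
    convention) and clamped to the available range.
    """
    p = srkt_power_emmetropia(k_d, al_mm, consts)
    step = consts.iol_step_d
    rounded = math.ceil(p / step - 0.5) * step
    return min(max(rounded, consts.iol_min_d), consts.iol_max_d)


def rx_theor_post(
    k_d: float,
    al_mm: float,
    elp_mm: float,
    iol_d: float,
    consts: OpticsConstants = OpticsConstants(),
) -> float:
    """Residual spectacle-plane refraction of a pseudophakic eye.

    Propagates vergence back from the retina through the IOL and cornea to
    the spectacle plane:

        V3 = 1336 / (AL − ELP)                 (vergence at the IOL, D)
        1/V1 = ELP/1336 + 1/(V3 − IOL)         (vergence demand at cornea)
        Rx = (K − V1) / ((V/1000)·(K − V1) − 1)

    The last line is the algebraically regular form of
    Rx = 1/(V/1000 − 1/(K − V1)); it is continuous through the emmetropic
    point K = V1 where Rx = 0.  Positive Rx = hyperopic residual.
    """
    for name, v in (("k_d", k_d), ("al_mm", al_mm), ("elp_mm", elp_mm), ("iol_d", iol_d)):
        if not math.isfinite(v):
            raise OpticsDomainError(f"{name} is not finite: {v!r}")
    if al_mm <= elp_mm:
        raise OpticsDomainError(f"axial length {al_mm} mm must exceed ELP {elp_mm} mm")
    na1000 = consts.n_aqueous
    v3 = na1000 / (al_mm - elp_mm)
    if abs(v3 - iol_d) < 1e-12:
        raise OpticsDomainError("singular vergence: IOL power equals retinal vergence V3")
    inv_v1 = elp_mm / na1000 + 1.0 / (v3 - iol_d)
    if abs(inv_v1) < 1e-15:
        raise OpticsDomainError("singular vergence: corneal-plane vergence demand is zero")
    v1 = 1.0 / inv_v1
    diff = k_d - v1
    den = (consts.vertex_distance_mm / 1000.0) * diff - 1.0
    if abs(den) < 1e-12:
        raise OpticsDomainError("singular vergence: spectacle-plane denominator vanishes")
    return diff / den


def rx_05iol(
    k_d: float,
    al_mm: float,
    elp_mm: float,
    iol_d: float,
    consts: OpticsConstants = OpticsConstants(),
    delta_d: float = 0.5,
) -> float:
    """Refraction change at the spectacle plane per ``delta_d`` of IOL power.

    Rx(IOL) − Rx(IOL + delta); positive for physiological eyes because a
    stronger lens shifts the refraction myopically.
    """
    return (
        rx_theor_post(k_d, al_mm, elp_mm, iol_d, consts)
        - rx_theor_post(k_d, al_mm, elp_mm, iol_d + delta_d, consts)
    )


def iol_ideal(iol_implanted_d: float, rx_post_d: float, rx_05iol_d: float) -> float:
    """Lens power that would have left the eye with zero residual refraction.

    IOL_ideal = IOL_implanted + (Rx_post / Rx_05IOL) · 0.5.  A hyperopic
    residual (Rx_post > 0) demands a stronger lens.
    """
    if not rx_05iol_d > 0:
        raise OpticsDomainError(f"rx_05iol_d must be positive, got {rx_05iol_d}")
    return iol_implanted_d + (rx_post_d / rx_05iol_d) * 0.5


def rx_predicted(
    iol_implanted_d: float,
    iol_predicted_d: float,
    rx_05iol_d: float,
    rx_post_d: float,
) -> float:
    """Back-calculated residual refraction had ``iol_predicted_d`` been implanted.

    Rx_predicted = ((IOL_implanted − IOL_predicted)/0.5)·Rx_05IOL + Rx_post.
    Substituting the ideal power cancels Rx_post exactly, so a perfect
    prediction scores a zero error.
    """
    if not rx_05iol_d > 0:
        raise OpticsDomainError(f"rx_05iol_d must be positive, got {rx_05iol_d}")
    return ((iol_implanted_d - iol_predicted_d) / 0.5) * rx_05iol_d + rx_post_d


def iol_for_emmetropia(
    k_d: float,
    al_mm: float,
    elp_mm: float,
    consts: OpticsConstants = OpticsConstants(),
) -> float:
    """Exact IOL power zeroing the vergence-model refraction at a given ELP.

    Closed form of rx_theor_post(...) = 0: the emmetropic condition is
    V1 = K, hence IOL = V3 − 1/(1/K − ELP/1336).  Independent of vertex
    distance (a zero refraction is zero at any plane).
    """
    if al_mm <= elp_mm:
        raise OpticsDomainError(f"axial length {al_mm} mm must exceed ELP {elp_mm} mm")
    na1000 = consts.n_aqueous
    v3 = na1000 / (al_mm - elp_mm)
    inv = 1.0 / k_d - elp_mm / na1000
    if abs(inv) < 1e-15:
        raise OpticsDomainError("degenerate cornea/ELP combination")
    return v3 - 1.0 / inv
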