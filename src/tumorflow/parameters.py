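"""Physiological parameters and derived flow/transport coefficients.

The tumor is modeled as three concentric regions — an avascular necrotic
core, a vascularized viable rim without lymphatics, and surrounding healthy
tissue with both blood vessels and functional lymphatics.  This module
houses the per-region physiology (hydraulic conductivities, vascular
density, oncotic/hydrostatic pressures, permeability, void fraction), the
solute/carrier description, and every derived coefficient both solvers
consume:

* effective pressure  ``P_EF = P_V - sigma_s * (pi_V - pi_IS)``
* steady-state pressure ``P_SS`` (conductance-weighted average of ``P_EF``
  and the lymphatic pressure ``P_L``)
* the dimensionless fluid-flow resistance
  ``alpha = R * sqrt((Lp*S/V + L_PL*S_L/V) / K)``
* Starling transvascular source ``phi_VS`` and lymphatic sink ``phi_LS``
* Stokes–Einstein and hindered (void-fraction-corrected) diffusivities
* the Patlak transvascular extraction coefficient with its Peclet factor

Internal unit system: cm – s – mmHg.  Stokes–Einstein is evaluated in SI
and converted; 1 mmHg = 133.322 Pa is used for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "MMHG_PA",
    "RegionParameters",
    "LymphaticParameters",
    "SoluteSpec",
    "TumorGeometry",
    "RegionCoefficients",
    "effective_pressure",
    "steady_state_pressure",
    "alpha",
    "vascular_source_phiVS",
    "lymphatic_sink_phiLS",
    "stokes_einstein_diffusivity",
    "effective_diffusivity",
    "peclet_factor",
    "transvascular_extraction",
    "region_coefficients",
    "baseline_regions",
    "baseline_lymphatics",
    "vn_regions",
    "carrier_spec",
    "solute_from_size",
    "CARRIERS",
    "REGION_NAMES",
]

#: Pa per mmHg, used only when reporting pressures in SI.
MMHG_PA = 133.322

REGION_NAMES = ("necrotic", "viable", "healthy")

RegionName = Literal["necrotic", "viable", "healthy"]


class ConfigurationError(ValueError):
    """Raised when a parameter set is physically inconsistent."""


@dataclass(frozen=True)
class RegionParameters:
    """Physiology of one tissue region.

    Parameters
    ----------
    name : {"necrotic", "viable", "healthy"}
    Lp : float
        Microvascular wall hydraulic conductivity [cm/(mmHg·s)].
    K : float
        Interstitial tissue hydraulic conductivity [cm²/(mmHg·s)].
    SV : float
        Vascular density S/V [1/cm]; zero in the necrotic core.
    sigma_s : float
        Osmotic reflection coefficient [-].
    piV, piIS : float
        Capillary and interstitial oncotic pressures [mmHg].
    PV : float
        Microvascular hydrostatic pressure [mmHg].
    Pperm : float
        Vascular permeability to the solute [cm/s].
    xi : float
        Interstitium void fraction [-], in (0, 1].
    """

    name: RegionName
    Lp: float
    K: float
    SV: float
    sigma_s: float
    piV: float
    piIS: float
    PV: float
    Pperm: float
    xi: float

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ConfigurationError(f"unknown region name {self.name!r}")
        if not (0.0 <= self.sigma_s <= 1.0):
            raise ConfigurationError("sigma_s must lie in [0, 1]")
        if not (0.0 < self.xi <= 1.0):
            raise ConfigurationError("void fraction xi must lie in (0, 1]")
        if self.Lp < 0 or self.K < 0 or self.SV < 0:
            raise ConfigurationError("Lp, K and S/V must be non-negative")
        if self.name == "necrotic" and self.SV != 0.0:
            raise ConfigurationError("necrotic core is avascular: S/V must be 0")


@dataclass(frozen=True)
class LymphaticParameters:
    """Lymphatic drainage of the healthy region.

    ``LPL_SLV`` is the lymphatic filtration coefficient L_PL·S_L/V
    [1/(mmHg·s)].  ``PL`` is the lymphatic hydrostatic pressure [mmHg];
    it is applied only when ``functional`` is True, otherwise the sink
    operates with P_L = 0 (the "absent lymphatic dynamics" case).
    """

    LPL_SLV: float = 1.1e-5
    PL: float = 0.0
    functional: bool = False

    def __post_init__(self) -> None:
        if self.LPL_SLV < 0:
            raise ConfigurationError("LPL_SLV must be non-negative")

    @property
    def PL_effective(self) -> float:
        return self.PL if self.functional else 0.0


@dataclass(frozen=True)
class SoluteSpec:
    """Nanoparticle / drug description for the transport model.

    Either a particle radius ``nr`` [m] (from which free and hindered
    diffusivities follow via Stokes–Einstein) or explicit per-region
    effective diffusivities ``D_override`` [cm²/s] must be supplied.
    Overrides carry keys ``"tumor"`` (necrotic + viable) and ``"normal"``
    (healthy), matching how carrier parameters are tabulated.
    """

    nr: Optional[float] = None
    tau_deg: float = 5.8e-6
    sigma_rc: float = 0.5
    CPL: float = 0.0
    kB: float = 1.38e-23
    T: float = 310.0
    mu: float = 1.0e-3
    D_override: Optional[dict] = None
    tau_override: Optional[dict] = None
    label: str = "generic"

    def __post_init__(self) -> None:
        if self.nr is None and self.D_override is None:
            raise ConfigurationError("either nr or D_override must be given")
        if self.nr is not None and self.nr <= 0:
            raise ConfigurationError("particle radius nr must be positive")
        if self.tau_deg < 0:
            raise ConfigurationError("tau_deg must be non-negative")
        if not (0.0 <= self.sigma_rc <= 1.0):
            raise ConfigurationError("sigma_rc must lie in [0, 1]")

    def diffusivity(self, region: RegionParameters) -> float:
        """Effective interstitial diffusivity in ``region`` [cm²/s]."""
        if self.D_override is not None:
            key = "normal" if region.name == "healthy" else "tumor"
            return float(self.D_override[key])
        return effective_diffusivity(stokes_einstein_diffusivity(self), region.xi)

    def degradation(self, region: RegionParameters) -> float:
        """First-order degradation rate in ``region`` [1/s]."""
        if self.tau_override is not None:
            key = "normal" if region.name == "healthy" else "tumor"
            return float(self.tau_override[key])
        return self.tau_deg


@dataclass(frozen=True)
class TumorGeometry:
    """Radii of the necrotic, viable and healthy outer boundaries [cm]."""

    Rnt: float = 0.5
    Rvt: float = 1.0
    Rht: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.Rnt < self.Rvt < self.Rht):
            raise ConfigurationError("radii must satisfy 0 < Rnt < Rvt < Rht")

    def region_of(self, r: float) -> RegionName:
        """Classify a radius using half-open bins [0,Rnt), [Rnt,Rvt), [Rvt,Rht]."""
        if r < self.Rnt:
            return "necrotic"
        if r < self.Rvt:
            return "viable"
        return "healthy"


@dataclass(frozen=True)
class RegionCoefficients:
    """Derived coefficients of one region, as consumed by the solvers.

    ``beta2`` [1/cm²] is the reaction coefficient of the pressure equation
    (alpha²/R² in dimensionless form); ``phiVS_linear = (a, b)`` exposes the
    Starling source as ``phi_VS = a − b·P_IS`` and ``phiLS_linear = (a, b)``
    the lymphatic sink as ``phi_LS = a + b·P_IS`` for linear assembly.
    """

    name: RegionName
    beta2: float
    PSS: float
    PEF: float
    K: float
    alpha: float
    phiVS_linear: tuple
    phiLS_linear: tuple
    LpSV: float
    LPL_SLV: float

    def phiVS(self, P_IS):
        a, b = self.phiVS_linear
        return a - b * np.asarray(P_IS, dtype=float)

    def phiLS(self, P_IS):
        a, b = self.phiLS_linear
        return a + b * np.asarray(P_IS, dtype=float)


# ---------------------------------------------------------------------------
# scalar operations


def effective_pressure(rp: RegionParameters) -> float:
    """Effective pressure P_EF = P_V − σ_s·(π_V − π_IS) [mmHg].

    The interstitial pressure at which transvascular filtration stops.
    """
    return rp.PV - rp.sigma_s * (rp.piV - rp.piIS)


def steady_state_pressure(
    rp: RegionParameters, lym: Optional[LymphaticParameters] = None
) -> float:
    """Steady-state (far-field equilibrium) pressure of a region [mmHg].

    Conductance-weighted average of the effective pressure and the
    lymphatic hydrostatic pressure.  The necrotic core, having neither
    vessels nor lymphatics, is assigned P_SS = 0.
    """
    if rp.name == "necrotic":
        return 0.0
    lpsv = rp.Lp * rp.SV
    lpl = lym.LPL_SLV if (lym is not None and rp.name == "healthy") else 0.0
    denom = lpsv + lpl
    if denom <= 0.0:
        raise ConfigurationError(
            f"zero vascular+lymphatic conductance in {rp.name} region"
        )
    PL = lym.PL_effective if lym is not None else 0.0
    return (lpsv * effective_pressure(rp) + lpl * PL) / denom


def alpha(
    rp: RegionParameters,
    lym: Optional[LymphaticParameters] = None,
    R: float = 1.0,
) -> float:
    """Dimensionless fluid-flow resistance α = R·sqrt((Lp·S/V + L_PL·S_L/V)/K).

    Ratio of interstitial to vascular flow resistance; zero in the
    avascular necrotic core, and the lymphatic term contributes only in
    the healthy region.
    """
    if rp.name == "necrotic":
        return 0.0
    if rp.K <= 0:
        raise ConfigurationError("hydraulic conductivity K must be positive")
    lpl = lym.LPL_SLV if (lym is not None and rp.name == "healthy") else 0.0
    return R * math.sqrt((rp.Lp * rp.SV + lpl) / rp.K)


def vascular_source_phiVS(rp: RegionParameters, P_IS) -> float:
    """Starling transvascular fluid source φ_VS [1/s]; zero in the necrotic core."""
    if rp.name == "necrotic":
        return np.zeros_like(np.asarray(P_IS, dtype=float)) + 0.0
    return rp.Lp * rp.SV * (effective_pressure(rp) - np.asarray(P_IS, dtype=float))


def lymphatic_sink_phiLS(
    lym: LymphaticParameters, P_IS, region: RegionName = "healthy"
) -> float:
    """Lymphatic drainage sink φ_LS = L_PL·S_L/V·(P_IS − P_L) [1/s].

    Only the healthy region drains; elsewhere the sink is identically zero.
    """
    if region != "healthy":
        return np.zeros_like(np.asarray(P_IS, dtype=float)) + 0.0
    return lym.LPL_SLV * (np.asarray(P_IS, dtype=float) - lym.PL_effective)


def stokes_einstein_diffusivity(ss: SoluteSpec) -> float:
    """Free-solution diffusivity D = k_B·T/(6π·μ·n_r), returned in cm²/s."""
    if ss.nr is None or ss.nr <= 0:
        raise ConfigurationError("Stokes–Einstein needs a positive particle radius")
    d_si = ss.kB * ss.T / (6.0 * math.pi * ss.mu * ss.nr)  # m²/s
    return d_si * 1.0e4


def effective_diffusivity(D_DIS: float, xi: float) -> float:
    """Hindered diffusivity in porous tissue: D_EF = (2ξ/(3−ξ))·D_DIS."""
    if not (0.0 < xi <= 1.0):
        raise ConfigurationError("void fraction xi must lie in (0, 1]")
    return (2.0 * xi / (3.0 - xi)) * D_DIS


#: below this |Pe| the Patlak factor uses a 3-term Bernoulli expansion,
#: avoiding 0/0 where the filtration flux vanishes.
_PE_SERIES_THRESHOLD = 1.0e-6


def peclet_factor(Pe):
    """Patlak factor Pe/(e^Pe − 1), positive and continuous at Pe = 0.

    Evaluated with a small-argument series for |Pe| < 1e-6 and the
    asymptote Pe·e^(−Pe) for large positive Pe to avoid overflow.
    """
    Pe = np.asarray(Pe, dtype=float)
    out = np.empty_like(Pe)
    small = np.abs(Pe) < _PE_SERIES_THRESHOLD
    big = Pe > 45.0
    mid = ~(small | big)
    out[small] = 1.0 - Pe[small] / 2.0 + Pe[small] ** 2 / 12.0
    out[big] = Pe[big] * np.exp(-Pe[big])
    out[mid] = Pe[mid] / np.expm1(Pe[mid])
    return out if out.ndim else float(out)


def transvascular_extraction(rp: RegionParameters, ss: SoluteSpec, phiVS):
    """Transvascular solute-extraction rate coefficient [1/s].

    With negligible plasma concentration the transvascular exchange
    reduces to a first-order sink Φ_BV = −c·C_IS with
    ``c = P·(S/V)·Pe/(e^Pe − 1)`` and ``Pe = φ_VS·(1−σ_rc)/(P·S/V)``.
    Returns 0 in the necrotic core.
    """
    phiVS = np.asarray(phiVS, dtype=float)
    if rp.name == "necrotic":
        return np.zeros_like(phiVS) + 0.0
    psv = rp.Pperm * rp.SV
    if psv <= 0.0:
        raise ConfigurationError(
            f"P·S/V must be positive outside the necrotic core ({rp.name})"
        )
    Pe = phiVS * (1.0 - ss.sigma_rc) / psv
    return psv * peclet_factor(Pe)


# ---------------------------------------------------------------------------
# region-wise coefficient builder


def region_coefficients(
    rp: RegionParameters,
    lym: Optional[LymphaticParameters] = None,
    R_ref: float = 1.0,
) -> RegionCoefficients:
    """Bundle the derived flow coefficients of one region.

    ``beta2 = (Lp·S/V + L_PL·S_L/V)/K`` vanishes exactly in the necrotic
    core; the reported ``alpha`` uses the reference length ``R_ref``
    (default 1 cm, the viable-tumor radius) so that
    ``alpha² = beta2·R_ref²``.
    """
    if rp.name == "necrotic":
        return RegionCoefficients(
            name="necrotic", beta2=0.0, PSS=0.0, PEF=0.0, K=rp.K, alpha=0.0,
            phiVS_linear=(0.0, 0.0), phiLS_linear=(0.0, 0.0),
            LpSV=0.0, LPL_SLV=0.0,
        )
    lpsv = rp.Lp * rp.SV
    lpl = lym.LPL_SLV if (lym is not None and rp.name == "healthy") else 0.0
    PL = lym.PL_effective if lym is not None else 0.0
    if rp.K <= 0:
        raise ConfigurationError("hydraulic conductivity K must be positive")
    beta2 = (lpsv + lpl) / rp.K
    pef = effective_pressure(rp)
    pss = steady_state_pressure(rp, lym)
    return RegionCoefficients(
        name=rp.name,
        beta2=beta2,
        PSS=pss,
        PEF=pef,
        K=rp.K,
        alpha=R_ref * math.sqrt(beta2),
        phiVS_linear=(lpsv * pef, lpsv),
        phiLS_linear=(-lpl * PL, lpl) if lpl > 0 else (0.0, 0.0),
        LpSV=lpsv,
        LPL_SLV=lpl,
    )


# ---------------------------------------------------------------------------
# bundled presets

_BASELINE = dict(
    necrotic=dict(Lp=2.8e-7, K=4.13e-8, SV=0.0, sigma_s=0.0, piV=0.0,
                  piIS=0.0, PV=0.0, Pperm=0.0, xi=0.6),
    viable=dict(Lp=2.8e-7, K=4.13e-8, SV=200.0, sigma_s=0.82, piV=20.0,
                piIS=15.0, PV=15.6, Pperm=5.73e-9, xi=0.4),
    healthy=dict(Lp=3.6e-8, K=8.53e-9, SV=70.0, sigma_s=0.91, piV=20.0,
                 piIS=10.0, PV=15.6, Pperm=0.73e-9, xi=0.26),
)

#: viable-region replacements at 50% / 100% vascular normalization
_VN_LEVELS = {
    0: dict(K=4.13e-8, Lp=2.8e-7, SV=200.0, sigma_s=0.82),
    50: dict(K=2.49e-8, Lp=1.585e-7, SV=135.0, sigma_s=0.865),
    100: dict(K=8.53e-9, Lp=3.6e-8, SV=70.0, sigma_s=0.91),
}

#: effective diffusivity [cm²/s] and degradation rate [1/s] of the carriers,
#: keyed tumor/normal
CARRIERS = {
    "doxorubicin": dict(D=dict(tumor=3.4e-6, normal=1.58e-6),
                        tau=dict(tumor=2.69e-3, normal=2.689e-3)),
    "dextran": dict(D=dict(tumor=1.4e-7, normal=5.0e-9),
                    tau=dict(tumor=4.17e-4, normal=2.085e-4)),
    "liposomal": dict(D=dict(tumor=3.35e-7, normal=2.4e-9),
                      tau=dict(tumor=1.16e-5, normal=1.157e-5)),
    "peg_gold": dict(D=dict(tumor=4.40e-8, normal=1.2e-8),
                     tau=dict(tumor=2.08e-5, normal=2.083e-5)),
    "magnetic": dict(D=dict(tumor=8.89e-8, normal=4.17e-8),
                     tau=dict(tumor=3.0e-16, normal=3.0e-16)),
}


def baseline_regions() -> dict:
    """Baseline physiology of the three regions, keyed by region name."""
    return {name: RegionParameters(name=name, **vals)
            for name, vals in _BASELINE.items()}


def baseline_lymphatics(functional: bool = False, PL: float = -4.0) -> LymphaticParameters:
    """Healthy-region lymphatics; ``functional=True`` applies P_L (default −4 mmHg)."""
    return LymphaticParameters(LPL_SLV=1.1e-5, PL=PL, functional=functional)


def vn_regions(level: int) -> dict:
    """Region set with the viable rim normalized to 0, 50 or 100 percent.

    Vascular normalization interpolates the viable region's K, Lp, S/V and
    σ_s toward healthy-tissue values; 0% reproduces the baseline exactly.
    """
    if level not in _VN_LEVELS:
        raise ConfigurationError(f"VN level must be one of {sorted(_VN_LEVELS)}")
    regions = baseline_regions()
    regions["viable"] = replace(regions["viable"], **_VN_LEVELS[level])
    return regions


def carrier_spec(name: str) -> SoluteSpec:
    """SoluteSpec for a named carrier (Table-driven diffusivity/degradation)."""
    if name not in CARRIERS:
        raise ConfigurationError(
            f"unknown carrier {name!r}; choose from {sorted(CARRIERS)}")
    c = CARRIERS[name]
    return SoluteSpec(D_override=c["D"], tau_override=c["tau"], label=name)


def solute_from_size(size_nm: float, **kwargs) -> SoluteSpec:
    """SoluteSpec for a nanoparticle of the given *diameter* in nm.

    The sweep labels particles by size (10–100 nm); the Stokes–Einstein
    radius is size/2.
    """
    return SoluteSpec(nr=size_nm * 0.5e-9, label=f"np_{size_nm:g}nm", **kwargs)
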