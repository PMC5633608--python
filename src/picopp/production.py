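"""Light field and the production equations.

Depth-integrated primary production per group follows the carbon-based
productivity model

    PP = C * mu * Zeu * h(I0)        [mg C m^-2 d^-1]

where C is surface carbon biomass (mg C m^-3), mu the growth rate
(d^-1), Zeu the euphotic-zone depth (m) and h(I0) a dimensionless
saturating function of surface PAR that captures how irradiance shapes
the depth profile of carbon fixation:

    h(I0) = 0.66125 * I0 / (I0 + 4.1),      I0 in mol photons m^-2 d^-1
    Zeu   = -ln(0.01) / k490                (1% light depth)

The volumetric form PP = C * mu (mg C m^-3 d^-1) is used when no light
field is available, e.g. when comparing against volumetric 14C
incubations. Surface biomass is taken to drive the whole column — field
profiles of picophytoplankton abundance show no significant depth
structure over these shallow euphotic zones.

The k490 formulation of Zeu was developed for clear open-ocean water
and overestimates the euphotic depth in turbid coastal water, so an
externally supplied Zeu (e.g. a satellite IOP product) takes precedence
by default when present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .biomass import BiomassEstimate, CCFTable, biomass_station
from .growth import GrowthModelParams, GrowthResult, _default_params, \
    growth_picoeukaryotes, growth_prochlorococcus, growth_synechococcus
from .stations import GROUPS, StationRecord

__all__ = [
    "LightParams",
    "ProductionEstimate",
    "euphotic_depth",
    "light_limitation",
    "volumetric_pp",
    "integrated_pp",
    "estimate_station",
]


@dataclass(frozen=True)
class LightParams:
    """Constants of the light terms."""

    h_scale: float = 0.66125  # dimensionless asymptote scale
    h_half_sat: float = 4.1  # mol photons m^-2 d^-1
    zeu_log_level: float = math.log(0.01)  # 1% light level

    def __post_init__(self):
        if self.h_scale <= 0 or self.h_half_sat <= 0:
            raise ValueError("h_scale and h_half_sat must be positive")


_DEFAULT_LIGHT = LightParams()


def euphotic_depth(k490_m1: float, params: LightParams = _DEFAULT_LIGHT) -> float:
    """Euphotic-zone depth (m, positive) from the 490-nm attenuation."""
    if not (k490_m1 > 0):
        raise ValueError(f"k490 must be > 0, got {k490_m1!r}")
    return -params.zeu_log_level / k490_m1


def light_limitation(i0: float, params: LightParams = _DEFAULT_LIGHT) -> float:
    """Saturating irradiance term h(I0) in [0, h_scale)."""
    if i0 < 0:
        raise ValueError(f"I0 must be >= 0, got {i0!r}")
    return params.h_scale * i0 / (i0 + params.h_half_sat)


def volumetric_pp(biomass_mgm3: float, mu_per_day: float) -> float:
    """Volumetric production C * mu (mg C m^-3 d^-1)."""
    if biomass_mgm3 < 0 or mu_per_day < 0:
        raise ValueError("biomass and mu must be >= 0")
    return biomass_mgm3 * mu_per_day


def integrated_pp(
    biomass_mgm3: float, mu_per_day: float, zeu_m: float, h: float
) -> float:
    """Depth-integrated production C * mu * Zeu * h(I0) (mg C m^-2 d^-1)."""
    if min(biomass_mgm3, mu_per_day, zeu_m, h) < 0:
        raise ValueError("all factors must be >= 0")
    return biomass_mgm3 * mu_per_day * zeu_m * h


@dataclass(frozen=True)
class ProductionEstimate:
    """Per-group and total production at one station, with provenance.

    ``volumetric`` holds C * mu per group (mg C m^-3 d^-1),
    ``integrated`` the depth-integrated values (mg C m^-2 d^-1).
    ``growth`` keeps the per-group GrowthResult so clamping,
    low-chlorophyll and extrapolation flags stay visible downstream.
    """

    volumetric: dict[str, float]
    integrated: dict[str, float]
    volumetric_total: float
    integrated_total: float
    biomass: BiomassEstimate
    growth: dict[str, GrowthResult]
    zeu_source: str  # "k490_formula" | "external_iop"
    zeu_m: float
    h_i0: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def _resolve_zeu(record: StationRecord, zeu_source: str, light: LightParams):
    if zeu_source not in ("auto", "formula", "external"):
        raise ValueError(f"zeu_source must be auto/formula/external, got {zeu_source!r}")
    has_ext = record.zeu_m is not None
    has_k = record.k490_m1 is not None
    if zeu_source == "external" or (zeu_source == "auto" and has_ext):
        if not has_ext:
            raise ValueError("external Zeu requested but record has no zeu_m")
        return record.zeu_m, "external_iop"
    if not has_k:
        raise ValueError("record has neither k490_m1 nor zeu_m; cannot set Zeu")
    return euphotic_depth(record.k490_m1, light), "k490_formula"


def estimate_station(
    record: StationRecord,
    ccf_table: Optional[CCFTable] = None,
    which: str = "average",
    ecotype: str = "mean",
    zeu_source: str = "auto",
    growth_params: Optional[GrowthModelParams] = None,
    light_params: LightParams = _DEFAULT_LIGHT,
    correct_low_chl_bias: bool = False,
) -> ProductionEstimate:
    """Full pipeline for one station: growth -> biomass -> light -> PP.

    Requires a temperature, at least the abundance columns (missing
    groups contribute zero), surface PAR, and either k490 or an
    external euphotic depth (``zeu_source="auto"`` prefers the external
    value, the coastal-water choice).
    """
    ccf_table = ccf_table or CCFTable.direct()
    growth_params = growth_params or _default_params()
    if record.sst_c is None:
        raise ValueError("record has no temperature (sst_c); cannot estimate growth")
    if record.par_mol_m2_d is None:
        raise ValueError("record has no surface PAR (par_mol_m2_d)")

    zeu, zsource = _resolve_zeu(record, zeu_source, light_params)
    h = light_limitation(record.par_mol_m2_d, light_params)

    chl = record.chl_mgm3
    growth = {
        "prochlorococcus": growth_prochlorococcus(record.sst_c, ecotype, growth_params),
        "synechococcus": growth_synechococcus(record.sst_c, growth_params),
        "picoeukaryotes": growth_picoeukaryotes(
            record.sst_c,
            chl if chl is not None else growth_params.low_chl_threshold,
            growth_params,
            correct_low_chl_bias=correct_low_chl_bias,
        ),
    }
    bio = biomass_station(record, ccf_table, which)
    vol = {g: volumetric_pp(bio.per_group[g], growth[g].mu) for g in GROUPS}
    integ = {g: integrated_pp(bio.per_group[g], growth[g].mu, zeu, h) for g in GROUPS}

    flags = []
    if growth["prochlorococcus"].clamped:
        flags.append("clamped")
    if growth["picoeukaryotes"].low_chl_warning:
        flags.append("low_chl_warning")
    if growth["synechococcus"].out_of_range:
        flags.append("extrapolated")
    if bio.missing_groups:
        flags.append("missing_abundance")

    return ProductionEstimate(
        volumetric=vol,
        integrated=integ,
        volumetric_total=sum(vol.values()),
        integrated_total=sum(integ.values()),
        biomass=bio,
        growth=growth,
        zeu_source=zsource,
        zeu_m=zeu,
        h_i0=h,
        flags=tuple(flags),
    )
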