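"""Temperature-dependent growth rates of picophytoplankton groups.

Two functional forms are used. *Prochlorococcus* growth is described by
concave-down quadratics in temperature, one per high-light-adapted
ecotype (eMIT9312 for low latitudes, eMED4 for high latitudes), because
its thermal response is strongly unimodal. *Synechococcus* and
picoeukaryote growth follow the Arrhenius form of metabolic theory,

    mu(T) = mu_c * exp(-E / (k * T)),

with activation energy ``E`` (eV), Boltzmann's constant
``k = 8.62e-5 eV K^-1`` and absolute temperature ``T`` (K). The
picoeukaryote relationship was fitted to field data at total chlorophyll
above 0.5 mg m^-3; below that threshold it is not significant and tends
to overestimate growth (by ~58% on average), so evaluations there carry
a warning flag and an optional bias correction.

Coefficients ship in ``data/growth_coefficients.yaml`` and can be
overridden with a user file of the same layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "PhysicalConstants",
    "PolynomialGrowthParams",
    "ArrheniusGrowthParams",
    "GrowthModelParams",
    "GrowthResult",
    "load_growth_params",
    "growth_prochlorococcus",
    "growth_synechococcus",
    "growth_picoeukaryotes",
]

PRO_ECOTYPES = ("eMIT9312", "eMED4", "mean")


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used by the Arrhenius growth form."""

    boltzmann_k: float = 8.62e-5  # eV K^-1
    celsius_to_kelvin_offset: float = 273.15

    def __post_init__(self):
        if self.boltzmann_k <= 0:
            raise ValueError("boltzmann_k must be positive")


@dataclass(frozen=True)
class PolynomialGrowthParams:
    """Quadratic growth-temperature curve mu = a0 + a1*T + a2*T^2 (T in degC)."""

    a0: float
    a1: float
    a2: float
    ecotype_label: str = ""

    @property
    def optimum_temperature(self) -> float:
        """Vertex of the parabola, degC (requires a2 != 0)."""
        return -self.a1 / (2.0 * self.a2)

    def evaluate(self, temperature_c: float) -> float:
        return self.a0 + self.a1 * temperature_c + self.a2 * temperature_c**2


@dataclass(frozen=True)
class ArrheniusGrowthParams:
    """Arrhenius growth curve ln mu = -E/(k*T) + ln(mu_c), T in kelvin."""

    activation_energy_e: float  # eV
    intercept_ln_mu_c: float  # ln of the normalisation constant
    ci_e: tuple[float, float] = (float("nan"), float("nan"))
    ci_intercept: tuple[float, float] = (float("nan"), float("nan"))
    fitted_range_c: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.activation_energy_e <= 0:
            raise ValueError("activation energy must be positive")

    def evaluate(self, temperature_c: float, constants: PhysicalConstants) -> float:
        kelvin = temperature_c + constants.celsius_to_kelvin_offset
        return math.exp(
            -self.activation_energy_e / (constants.boltzmann_k * kelvin)
            + self.intercept_ln_mu_c
        )


@dataclass(frozen=True)
class GrowthResult:
    """A growth rate with provenance flags.

    ``mu`` is never negative. ``clamped`` reports that the raw quadratic
    value was negative and was set to zero. ``low_chl_warning`` marks a
    picoeukaryote evaluation below the model's chlorophyll validity
    threshold. ``out_of_range`` marks extrapolation beyond the fitted
    temperature range (values are still computed).
    """

    mu: float
    clamped: bool = False
    low_chl_warning: bool = False
    out_of_range: bool = False


@dataclass(frozen=True)
class GrowthModelParams:
    """The full coefficient set for the four growth-temperature curves."""

    constants: PhysicalConstants
    emit9312: PolynomialGrowthParams
    emed4: PolynomialGrowthParams
    synechococcus: ArrheniusGrowthParams
    picoeukaryotes: ArrheniusGrowthParams
    low_chl_threshold: float = 0.5  # mg m^-3
    low_chl_overestimate_factor: float = 1.58


def _params_from_dict(cfg: dict) -> GrowthModelParams:
    const = cfg.get("constants", {})
    constants = PhysicalConstants(
        boltzmann_k=float(const.get("boltzmann_k_ev_per_k", 8.62e-5)),
        celsius_to_kelvin_offset=float(const.get("celsius_to_kelvin_offset", 273.15)),
    )
    pro = cfg["prochlorococcus"]
    syn = cfg["synechococcus"]
    euk = cfg["picoeukaryotes"]
    return GrowthModelParams(
        constants=constants,
        emit9312=PolynomialGrowthParams(
            ecotype_label="eMIT9312", **{k: float(v) for k, v in pro["eMIT9312"].items()}
        ),
        emed4=PolynomialGrowthParams(
            ecotype_label="eMED4", **{k: float(v) for k, v in pro["eMED4"].items()}
        ),
        synechococcus=ArrheniusGrowthParams(
            activation_energy_e=float(syn["activation_energy_ev"]),
            intercept_ln_mu_c=float(syn["intercept_ln_mu"]),
            ci_e=tuple(syn.get("ci_activation_energy_ev", (math.nan, math.nan))),
            ci_intercept=tuple(syn.get("ci_intercept_ln_mu", (math.nan, math.nan))),
            fitted_range_c=tuple(syn["fitted_range_c"]) if "fitted_range_c" in syn else None,
        ),
        picoeukaryotes=ArrheniusGrowthParams(
            activation_energy_e=float(euk["activation_energy_ev"]),
            intercept_ln_mu_c=float(euk["intercept_ln_mu"]),
            ci_e=tuple(euk.get("ci_activation_energy_ev", (math.nan, math.nan))),
            ci_intercept=tuple(euk.get("ci_intercept_ln_mu", (math.nan, math.nan))),
        ),
        low_chl_threshold=float(euk.get("low_chl_threshold_mg_m3", 0.5)),
        low_chl_overestimate_factor=float(euk.get("low_chl_overestimate_factor", 1.58)),
    )


@lru_cache(maxsize=None)
def _default_params() -> GrowthModelParams:
    text = resources.files("picopp.data").joinpath("growth_coefficients.yaml").read_text()
    return _params_from_dict(yaml.safe_load(text))


def load_growth_params(path=None) -> GrowthModelParams:
    """Load growth coefficients from the shipped config or a user file."""
    if path is None:
        return _default_params()
    with open(path) as fh:
        return _params_from_dict(yaml.safe_load(fh))


def _check_temperature(temperature_c: float, constants: PhysicalConstants) -> None:
    if not math.isfinite(temperature_c):
        raise ValueError(f"temperature must be finite, got {temperature_c!r}")
    if temperature_c <= -constants.celsius_to_kelvin_offset:
        raise ValueError(
            f"temperature {temperature_c} degC is at or below absolute zero"
        )


def growth_prochlorococcus(
    temperature_c: float,
    ecotype: str = "mean",
    params: Optional[GrowthModelParams] = None,
) -> GrowthResult:
    """*Prochlorococcus* growth rate (d^-1) from the ecotype quadratics.

    ``ecotype`` selects eMIT9312, eMED4, or their arithmetic mean
    (averaged before clamping). Negative raw values — the quadratics go
    negative in cold water — are clamped to zero with ``clamped=True``.
    """
    params = params or _default_params()
    _check_temperature(temperature_c, params.constants)
    if ecotype not in PRO_ECOTYPES:
        raise ValueError(f"ecotype must be one of {PRO_ECOTYPES}, got {ecotype!r}")
    if ecotype == "eMIT9312":
        raw = params.emit9312.evaluate(temperature_c)
    elif ecotype == "eMED4":
        raw = params.emed4.evaluate(temperature_c)
    else:
        raw = 0.5 * (
            params.emit9312.evaluate(temperature_c)
            + params.emed4.evaluate(temperature_c)
        )
    if raw < 0.0:
        return GrowthResult(mu=0.0, clamped=True)
    return GrowthResult(mu=raw)


def growth_synechococcus(
    temperature_c: float, params: Optional[GrowthModelParams] = None
) -> GrowthResult:
    """*Synechococcus* growth rate (d^-1) from the Arrhenius fit.

    Always positive; evaluations outside the 10-34 degC fitted range are
    flagged ``out_of_range`` but still computed (coastal winter
    applications sit below the range).
    """
    params = params or _default_params()
    _check_temperature(temperature_c, params.constants)
    mu = params.synechococcus.evaluate(temperature_c, params.constants)
    rng = params.synechococcus.fitted_range_c
    out = rng is not None and not (rng[0] <= temperature_c <= rng[1])
    return GrowthResult(mu=mu, out_of_range=out)


def growth_picoeukaryotes(
    temperature_c: float,
    chlorophyll_mgm3: float,
    params: Optional[GrowthModelParams] = None,
    correct_low_chl_bias: bool = False,
) -> GrowthResult:
    """Picoeukaryote community growth rate (d^-1) from the Arrhenius fit.

    The fit only holds at total chlorophyll >= 0.5 mg m^-3; below that,
    ``low_chl_warning`` is set and, if ``correct_low_chl_bias`` is on,
    mu is divided by 1.58 (the average overestimate in that regime).
    The growth value itself does not otherwise depend on chlorophyll.
    """
    params = params or _default_params()
    _check_temperature(temperature_c, params.constants)
    if chlorophyll_mgm3 is None or chlorophyll_mgm3 < 0:
        raise ValueError(f"chlorophyll must be >= 0, got {chlorophyll_mgm3!r}")
    mu = params.picoeukaryotes.evaluate(temperature_c, params.constants)
    low = chlorophyll_mgm3 < params.low_chl_threshold
    if low and correct_low_chl_bias:
        mu /= params.low_chl_overestimate_factor
    return GrowthResult(mu=mu, low_chl_warning=low)
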