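"""Model parameters, scenario descriptors and configuration I/O.

The parameter set describes a single patented-drug market (the defaults are
for an anti-multiple-myeloma drug in the Chinese hospital market): an
epidemiological eligibility funnel (incidence, affordability, diagnosis,
outpatient and treatment rates), adoption coefficients, survival and
treatment-suspension hazards, prices, tax rate, patent-decay constants and
the R&D investments that define patent intensity.

A :class:`Scenario` describes one simulated world: whether the originator
and government join the Medicines Patent Pool (MPP), the policy levers
(generic price ratio, royalty rate, pooling subsidy coefficient) and the
event timing (patent life, generic launch lag, horizon, step length).

Configuration files are flat YAML or JSON mappings whose keys name
:class:`ModelParameters` and/or :class:`Scenario` fields; unknown keys are
an error.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Any, Mapping, Union

import yaml

__all__ = [
    "ModelParameters",
    "Scenario",
    "ParameterError",
    "ConfigError",
    "DT_REFERENCE",
    "load_parameters",
    "load_config",
    "save_config",
    "default_scenario",
]

#: The two-month reference period the adoption coefficients alpha and beta
#: are quoted against (1/6 year).
DT_REFERENCE = 1.0 / 6.0


class ConfigError(ValueError):
    """Raised when a configuration source cannot be parsed or has unknown keys."""


class ParameterError(ValueError):
    """Raised when parameter values violate their bounds.

    The message enumerates *all* violations, one per line.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid parameter value(s):\n  " + "\n  ".join(self.violations)
        )


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """All market-model constants.

    Fractions are dimensionless in [0, 1]; times are in years; prices and
    R&D investments in dollars.  ``alpha`` and ``beta`` are per-two-month
    fractions (the model's native reporting period); the engine converts
    them to annual rates internally.
    """

    # eligibility funnel
    sigma: float = 0.32          # proportion of affordable population
    phi: float = 0.625           # diagnostic rate (midpoint of 0.5-0.75)
    rho_out: float = 0.85        # outpatient rate
    eps_treat: float = 0.85      # rate of treatment
    # adoption
    alpha: float = 0.05          # prescription decision coefficient (per 2 months)
    beta: float = 0.04           # patients-receiving-therapy coefficient (per 2 months)
    # survival / churn
    omega: float = 5.0           # median survival time, years
    z: float = 0.8               # lifetime probability of treatment suspension
    zz: float = 0.05             # retreatment probability of rejected patients, per year
    # prices and taxes
    p_orig: float = 80_000.0     # original drug price, $/patient-year
    psi: float = 0.15            # enterprise tax rate
    # patent decay
    tau: float = 10.0            # patent technology life cycle, years
    d: float = 0.05              # substitutability of patent technologies
    # market constants
    population: float = 1.37e9   # healthy-population basis
    morbidity: float = 3.0e-5    # disease incidence, per person per year (midpoint of 2-4/100,000)
    m_share: float = 0.25        # joint market share of originator + generic among treated
    v0_in: float = 5.0e7         # initial market-level R&D investment, in-pool originator
    v0_out: float = 5.0e7        # initial market-level R&D investment, out-of-pool competitors
    market_fraction: float = 0.05  # share of global R&D attributed to this market (1/20)
    # gap-filling calibration constants (see docs/methods.md)
    c_prod: float = 0.10         # originator production cost, fraction of revenue
    c_mkt: float = 0.753426      # originator marketing cost, fraction of revenue
    c_prod_gen: float = 0.10     # generic maker production cost share
    c_mkt_gen: float = 0.498791  # generic maker marketing cost share
    gamma_r: float = 6.032210    # attraction exponent on relative patent intensity
    gamma_p: float = 0.82        # attraction exponent on the reference/average price ratio
    # generic share ramp
    gen_share_frac: float = 0.7  # generic share of m reached after the ramp
    gen_ramp_years: float = 0.5  # ramp duration after generic launch (6 months)
    # toggles
    rejected_mortality: bool = True   # apply the death hazard to the rejected stock
    discount_rate: float = 0.0        # continuous discount rate on ledger flows, per year
    subsidy_timing: str = "lump"      # "lump" at t_join or "amortized" over patent life
    credit_tax_to_gov: bool = False   # credit enterprise tax against government expenditure

    _FRACTION_FIELDS = (
        "sigma", "phi", "rho_out", "eps_treat", "alpha", "beta", "z", "zz",
        "psi", "d", "m_share", "market_fraction", "c_prod", "c_mkt",
        "c_prod_gen", "c_mkt_gen", "gen_share_frac",
    )
    _POSITIVE_FIELDS = ("omega", "tau", "p_orig", "population")
    _NONNEG_FIELDS = (
        "morbidity", "v0_in", "v0_out", "gamma_r", "gamma_p",
        "gen_ramp_years", "discount_rate",
    )

    def __post_init__(self) -> None:
        violations = []
        for name in self._FRACTION_FIELDS:
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                violations.append(f"{name}={x!r}: must lie in [0, 1]")
        for name in self._POSITIVE_FIELDS:
            x = getattr(self, name)
            if not x > 0.0:
                violations.append(f"{name}={x!r}: must be > 0")
        for name in self._NONNEG_FIELDS:
            x = getattr(self, name)
            if not x >= 0.0:
                violations.append(f"{name}={x!r}: must be >= 0")
        if self.d == 0.0:
            violations.append(f"d={self.d!r}: must be > 0")
        if self.z >= 1.0:
            violations.append(f"z={self.z!r}: must be < 1 (suspension hazard finite)")
        if self.c_prod + self.c_mkt >= 1.0:
            violations.append(
                f"c_prod+c_mkt={self.c_prod + self.c_mkt!r}: must be < 1 "
                "(positive operating margin)"
            )
        if self.c_prod_gen + self.c_mkt_gen >= 1.0:
            violations.append(
                f"c_prod_gen+c_mkt_gen={self.c_prod_gen + self.c_mkt_gen!r}: "
                "must be < 1 (positive operating margin)"
            )
        if self.subsidy_timing not in ("lump", "amortized"):
            violations.append(
                f"subsidy_timing={self.subsidy_timing!r}: must be 'lump' or 'amortized'"
            )
        if violations:
            raise ParameterError(violations)

    @property
    def margin(self) -> float:
        """Originator operating margin 1 - c_prod - c_mkt."""
        return 1.0 - self.c_prod - self.c_mkt

    @property
    def margin_gen(self) -> float:
        """Generic maker operating margin 1 - c_prod_gen - c_mkt_gen."""
        return 1.0 - self.c_prod_gen - self.c_mkt_gen

    @property
    def death_hazard(self) -> float:
        """Annual death hazard ln(2)/omega (exponential survival, median omega)."""
        return math.log(2.0) / self.omega

    @property
    def suspension_hazard(self) -> float:
        """Annual treatment-suspension hazard -ln(1-z)/omega.

        z is read as the lifetime fraction of patients suspending within the
        median survival window (a literal per-step probability of 0.8 would
        empty the in-therapy stock within two steps).
        """
        return -math.log1p(-self.z) / self.omega

    def replace(self, **changes: Any) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One simulated world: pool membership, policy levers, event timing."""

    pooled: bool
    price_ratio: float = 0.40     # generic price / original price
    royalty_rate: float = 0.020875  # fraction of generic sales revenue (in-pool)
    subsidy_coef: float = 0.065   # pooling subsidy coefficient
    t_launch: float = 0.0         # originator launch, years (origin of time)
    t_join: float = 0.0           # MPP entry time, years (pooled worlds)
    patent_life: float = 12.0     # launch-to-expiry, years
    generic_lag: float = 2.0      # licensing/expiry to generic launch, years
    horizon: float = 16.0         # simulated span, years
    dt: float = DT_REFERENCE      # step length, years (2 months)

    def __post_init__(self) -> None:
        violations = []
        if not (0.0 < self.price_ratio <= 1.0):
            violations.append(f"price_ratio={self.price_ratio!r}: must lie in (0, 1]")
        if not (0.0 <= self.royalty_rate < 1.0):
            violations.append(f"royalty_rate={self.royalty_rate!r}: must lie in [0, 1)")
        if not self.subsidy_coef >= 0.0:
            violations.append(f"subsidy_coef={self.subsidy_coef!r}: must be >= 0")
        if not self.dt > 0.0:
            violations.append(f"dt={self.dt!r}: must be > 0")
        if not (0.0 <= self.t_join < self.patent_life):
            violations.append(
                f"t_join={self.t_join!r}: must satisfy 0 <= t_join < patent_life"
            )
        if not self.patent_life <= self.horizon:
            violations.append(
                f"patent_life={self.patent_life!r}: must not exceed horizon="
                f"{self.horizon!r}"
            )
        if not self.generic_lag >= 0.0:
            violations.append(f"generic_lag={self.generic_lag!r}: must be >= 0")
        if self.dt > 0.0 and self.horizon > 0.0:
            n = self.horizon / self.dt
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                violations.append(
                    f"dt={self.dt!r}: must divide horizon={self.horizon!r} evenly"
                )
        if violations:
            raise ParameterError(violations)

    @property
    def n_steps(self) -> int:
        """Number of integration steps (horizon / dt)."""
        return round(self.horizon / self.dt)

    @property
    def generic_launch_time(self) -> float:
        """Generic launch time for this world, years since originator launch.

        In-pool the licensed generic launches ``generic_lag`` years after the
        MPP entry; out-of-pool it launches ``generic_lag`` years after patent
        expiry.  May exceed the horizon (the event is then never reached).
        """
        if self.pooled:
            return self.t_join + self.generic_lag
        return self.patent_life + self.generic_lag

    def replace(self, **changes: Any) -> "Scenario":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(Scenario)}


def default_scenario(pooled: bool) -> Scenario:
    """The default world descriptor: 16-year horizon at a 2-month step,
    12-year patent life, 2-year generic lag, MPP entry at launch."""
    return Scenario(pooled=pooled)


def _parse_source(source: Union[str, pathlib.Path, Mapping[str, Any], None]) -> dict:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    path = pathlib.Path(source)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        # JSON first (YAML 1.1 misreads bare scientific notation like 3e-05
        # as a string), then YAML
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(
            f"config file {path} must contain a mapping, got {type(data).__name__}"
        )
    return data


def load_config(
    source: Union[str, pathlib.Path, Mapping[str, Any], None] = None,
    pooled: bool = True,
) -> tuple[ModelParameters, Scenario]:
    """Load model parameters and a scenario from one flat config mapping.

    Keys name :class:`ModelParameters` or :class:`Scenario` fields; absent
    keys take the shipped defaults; unknown keys raise :class:`ConfigError`.
    """
    data = _parse_source(source)
    unknown = sorted(set(data) - _PARAM_FIELDS - _SCENARIO_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    p_kwargs = {k: v for k, v in data.items() if k in _PARAM_FIELDS}
    s_kwargs = {k: v for k, v in data.items() if k in _SCENARIO_FIELDS}
    s_kwargs.setdefault("pooled", pooled)
    return ModelParameters(**p_kwargs), Scenario(**s_kwargs)


def load_parameters(
    source: Union[str, pathlib.Path, Mapping[str, Any], None] = None,
) -> ModelParameters:
    """Load :class:`ModelParameters` from a config source (defaults applied)."""
    params, _ = load_config(source)
    return params


def save_config(
    path: Union[str, pathlib.Path],
    params: ModelParameters,
    scenario: Scenario | None = None,
) -> None:
    """Write a config file (format chosen by extension: .json or .yaml/.yml)
    that round-trips through :func:`load_config`."""
    data: dict[str, Any] = params.to_dict()
    if scenario is not None:
        data.update(scenario.to_dict())
    path = pathlib.Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
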