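"""Patient-flow dynamics of the focal drug market.

Two stocks drive the market: diagnosed patients not (yet) on the focal drug
class, UP(t), and current patients in therapy, CP(t):

    dUP/dt = up(t) - cp(t)
    dCP/dt = cp(t) - ccp(t) - dp(t)

where up is the inflow of newly eligible plus retreating patients, cp the
adoption flow, ccp treatment suspension and dp death.  Adoption is limited
by the potential sales volume

    pp(t) = m * delta(t) * (alpha * UP + beta * CP)

(m: joint market share of originator + generic among treated patients;
delta: 1 while the drug class is marketed; alpha, beta: prescription
decision and word-of-mouth coefficients per two-month period), of which a
fraction A (the drug attraction, a function of relative patent intensity
and the average price level) actually starts therapy; the rest decline and
enter a rejected stock that retreats at rate zz per year.

All flows are advanced with explicit Euler steps on continuous stocks; the
engine never emits negative stocks (overshooting flows are truncated with a
logged warning).
"""

from __future__ import annotations

import dataclasses
import logging

from .params import DT_REFERENCE, ModelParameters

__all__ = [
    "PatientState",
    "FlowRecord",
    "incidence_inflow",
    "drug_attraction",
    "potential_sales",
    "generic_share_split",
    "step_patient_flow",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PatientState:
    """Patient stocks (continuous persons) plus cumulative exits."""

    up: float = 0.0              # diagnosed, not on the focal drug class
    cp: float = 0.0              # currently in therapy on the focal class
    rejected: float = 0.0        # declined therapy, may retreat
    cum_suspended: float = 0.0   # cumulative treatment suspensions (exits)
    cum_dead: float = 0.0        # cumulative deaths (exits)

    def __post_init__(self) -> None:
        for name in ("up", "cp", "rejected", "cum_suspended", "cum_dead"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"patient stock {name} must be non-negative")

    @property
    def total(self) -> float:
        """Sum of all stocks and cumulative exits (conserved up to inflows)."""
        return self.up + self.cp + self.rejected + self.cum_suspended + self.cum_dead


@dataclasses.dataclass(frozen=True)
class FlowRecord:
    """Per-step flows (persons over the step)."""

    inflow: float = 0.0
    retreat: float = 0.0
    pp: float = 0.0          # potential sales volume this step
    cp_flow: float = 0.0     # adoptions (attraction * pp)
    declined: float = 0.0    # (1 - attraction) * pp
    suspended: float = 0.0
    died: float = 0.0
    truncated: bool = False  # a flow was scaled down to avoid a negative stock


def incidence_inflow(params: ModelParameters, dt: float) -> float:
    """New treatment-eligible patients over a step of length ``dt`` years.

    The eligibility funnel multiplies incidence by the affordability,
    diagnosis, outpatient and treatment rates:
    population * morbidity * sigma * phi * rho_out * eps_treat * dt.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    return (
        params.population
        * params.morbidity
        * params.sigma
        * params.phi
        * params.rho_out
        * params.eps_treat
        * dt
    )


def drug_attraction(
    r_in: float,
    avg_price: float,
    ref_price: float,
    gamma_r: float,
    gamma_p: float,
) -> float:
    """Drug attraction A in [0, 1].

    A = clip(r_in^gamma_r * (ref_price / avg_price)^gamma_p, 0, 1):
    non-decreasing in the relative patent intensity ``r_in`` and
    non-increasing in the current average price of the drug class relative
    to the reference (launch) price, so generic entry — which lowers the
    average price — raises adoption.

    Raises
    ------
    ValueError
        On non-positive prices or ``r_in`` outside [0, 1].
    """
    if avg_price <= 0.0 or ref_price <= 0.0:
        raise ValueError("prices must be > 0")
    if not (0.0 <= r_in <= 1.0):
        raise ValueError(f"r_in must lie in [0, 1], got {r_in!r}")
    a = r_in**gamma_r * (ref_price / avg_price) ** gamma_p
    return min(1.0, max(0.0, a))


def potential_sales(
    m: float, delta: int, alpha: float, beta: float, up: float, cp: float
) -> float:
    """Potential sales volume per two-month period:
    ``m * delta * (alpha * up + beta * cp)``."""
    if delta not in (0, 1):
        raise ValueError(f"delta must be 0 or 1, got {delta!r}")
    if min(m, alpha, beta, up, cp) < 0.0:
        raise ValueError("inputs must be non-negative")
    return m * delta * (alpha * up + beta * cp)


def generic_share_split(
    t_since_generic_launch: float,
    m: float,
    gen_share_frac: float = 0.7,
    gen_ramp_years: float = 0.5,
) -> tuple[float, float]:
    """Split the joint market share m between originator and generic.

    Before the generic launch the originator holds all of m.  After launch
    the generic's share ramps linearly from 0 to ``gen_share_frac * m``
    (default 0.7 m, reached 6 months after launch) and stays constant
    thereafter; the originator keeps the remainder.  Shares always sum to m.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"m must lie in [0, 1], got {m!r}")
    if t_since_generic_launch <= 0.0:
        return m, 0.0
    if gen_ramp_years <= 0.0:
        frac = gen_share_frac
    else:
        frac = gen_share_frac * min(1.0, t_since_generic_launch / gen_ramp_years)
    gen = frac * m
    return m - gen, gen


def step_patient_flow(
    state: PatientState,
    inflow: float,
    attraction: float,
    delta: int,
    params: ModelParameters,
    dt: float,
) -> tuple[PatientState, FlowRecord]:
    """Advance the patient stocks by one Euler step of length ``dt`` years.

    Flows are computed from the start-of-step stocks: retreatment from the
    rejected stock (rate zz/year), potential sales split by attraction into
    adoptions and declines, suspension (hazard -ln(1-z)/omega per year) and
    death (hazard ln2/omega per year, also applied to the rejected stock
    when ``params.rejected_mortality``).  If an outflow would drive a stock
    negative it is scaled down pro rata and a warning is logged; stocks are
    never negative.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    if not (0.0 <= attraction <= 1.0):
        raise ValueError(f"attraction must lie in [0, 1], got {attraction!r}")

    retreat = params.zz * state.rejected * dt
    # alpha/beta are per-two-month fractions; rescale to this step length
    pp = potential_sales(
        params.m_share, delta, params.alpha, params.beta, state.up, state.cp
    ) * (dt / DT_REFERENCE)
    cp_flow = attraction * pp
    declined = pp - cp_flow
    died_cp = state.cp * params.death_hazard * dt
    suspended = state.cp * params.suspension_hazard * dt
    died_rej = (
        state.rejected * params.death_hazard * dt if params.rejected_mortality else 0.0
    )

    truncated = False

    # rejected first (retreat feeds up, so it must be final before up is
    # sized); conservatively ignore the incoming declined flow
    out_rej = retreat + died_rej
    if out_rej > state.rejected:
        scale = state.rejected / out_rej if out_rej > 0.0 else 0.0
        retreat, died_rej = retreat * scale, died_rej * scale
        truncated = True
    # up: in = inflow + retreat, out = pp
    avail_up = state.up + inflow + retreat
    if pp > avail_up:
        scale = avail_up / pp if pp > 0.0 else 0.0
        pp, cp_flow, declined = pp * scale, cp_flow * scale, declined * scale
        truncated = True
    # cp: in = cp_flow, out = died_cp + suspended
    out_cp = died_cp + suspended
    avail_cp = state.cp + cp_flow
    if out_cp > avail_cp:
        scale = avail_cp / out_cp if out_cp > 0.0 else 0.0
        died_cp, suspended = died_cp * scale, suspended * scale
        truncated = True
    if truncated:
        logger.warning("patient flow truncated to keep stocks non-negative")

    new = PatientState(
        up=max(0.0, state.up + inflow + retreat - pp),
        cp=max(0.0, state.cp + cp_flow - died_cp - suspended),
        rejected=max(0.0, state.rejected + declined - retreat - died_rej),
        cum_suspended=state.cum_suspended + suspended,
        cum_dead=state.cum_dead + died_cp + died_rej,
    )
    record = FlowRecord(
        inflow=inflow,
        retreat=retreat,
        pp=pp,
        cp_flow=cp_flow,
        declined=declined,
        suspended=suspended,
        died=died_cp + died_rej,
        truncated=truncated,
    )
    return new, record
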