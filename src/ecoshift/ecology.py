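"""Age-structured multispecies dynamics on the box geometry.

Functional groups are either age-structured (10 age bins, numbers per box,
one coastwide mean weight per bin), biomass pools (e.g. zooplankton), or
primary producers (logistic growth toward a per-box carrying capacity).

Each 12-h (or coarser) timestep resolves, in order:

1. proportional redistribution of every group to its (SDM-forced or pinned)
   spatial distribution, after knife-edge thermal masking;
2. the Q10 temperature scalar per box;
3. producer growth;
4. Holling type-II consumption for every consumer, filtered by the prey
   availability matrix and predator/prey gape windows;
5. mortality as simultaneous competing exponential rates (predation demand,
   fishing, Q10-scaled linear mortality), with predation capped by the prey
   actually available and predator intake rescaled to what was removed;
6. growth of the coastwide weight-at-age from assimilated intake minus
   Q10-scaled respiration.

Once per simulated year, Beverton-Holt recruitment (spawning output scaled
by body condition w/w_ref) is followed by fractional age-bin promotion with
a plus group.  A mortality/production ledger records every biomass flux so
that per-step mass balance is an exact bookkeeping identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .forcing import temperature_scalar
from .sdm import DistributionSeries, ToleranceWindow, apply_tolerance_mask, \
    interpolate_distribution

__all__ = [
    "AGE_BINS_VERTEBRATE",
    "FunctionalGroupDef",
    "AvailabilityMatrix",
    "GroupState",
    "MortalityLedger",
    "PreyItem",
    "EcologyError",
    "gape_filter",
    "consumption",
    "grow",
    "apply_mortality",
    "recruit",
    "add_recruits",
    "age_step",
    "producer_growth",
    "Ecosystem",
    "FishingField",
    "step_ecosystem",
]

#: Number of age bins for every age-structured (vertebrate-like) group.
AGE_BINS_VERTEBRATE = 10

G_PER_TONNE = 1.0e6
_TINY = 1e-300


class EcologyError(ValueError):
    pass


@dataclass
class FunctionalGroupDef:
    """Biological parameters of one functional group.

    Rates are per day; weights in grams wet weight per individual; biomass
    in tonnes.  ``clearance_rate`` and ``max_ingestion`` are mass-specific
    (per unit predator foraging biomass per day); foraging biomass of an
    age-structured group is evaluated on the reference weight-at-age, so
    ration scales with the age bin's characteristic size, while condition
    (w / w_ref) feeds back through spawning output.
    """

    group_id: str
    kind: str  # {age_structured, pool, producer}
    n_age_bins: int = AGE_BINS_VERTEBRATE
    years_per_bin: np.ndarray | int = 1
    maturity_at_bin: np.ndarray | None = None
    juvenile_adult_split_bin: int = 2
    clearance_rate: float = 0.0  # per day per unit prey biomass
    max_ingestion: float = 0.0  # tonnes prey / tonne predator / day
    assimilation_eff: float = 0.3
    respiration_coeff: float = 0.0  # per day
    linear_mortality: float = 0.0  # per day
    quadratic_mortality: float = 0.0  # per day per tonne (pool closure term)
    gape_window: tuple[float, float] = (1e-9, 1.0)
    recruit_alpha: float = 0.0  # asymptotic recruits (individuals / year)
    recruit_beta: float = 1.0  # spawning biomass (t) at half-maximum
    tolerance: ToleranceWindow = field(default_factory=ToleranceWindow)
    q10_sensitive: bool = True
    w_ref: np.ndarray | None = None  # reference weight-at-age (g)
    pool_individual_weight: float = 1e-3  # nominal prey size for pools (g)
    growth_rate: float = 0.0  # producer light-saturated growth (per day)
    carrying_capacity: np.ndarray | float = 0.0  # producer K per box (t)
    starvation_floor: float = 0.5  # min weight as fraction of w_ref

    def __post_init__(self):
        if self.kind not in ("age_structured", "pool", "producer"):
            raise EcologyError(f"{self.group_id}: unknown kind {self.kind!r}")
        if self.kind == "age_structured":
            if self.n_age_bins != AGE_BINS_VERTEBRATE:
                raise EcologyError(
                    f"{self.group_id}: age-structured groups use "
                    f"{AGE_BINS_VERTEBRATE} age bins"
                )
            self.years_per_bin = (
                np.full(self.n_age_bins, self.years_per_bin, dtype=int)
                if np.isscalar(self.years_per_bin)
                else np.asarray(self.years_per_bin, dtype=int)
            )
            if self.maturity_at_bin is None:
                self.maturity_at_bin = np.where(
                    np.arange(self.n_age_bins) >= self.juvenile_adult_split_bin,
                    1.0, 0.0,
                )
            self.maturity_at_bin = np.asarray(self.maturity_at_bin, dtype=float)
            if self.w_ref is None:
                raise EcologyError(f"{self.group_id}: w_ref required")
            self.w_ref = np.asarray(self.w_ref, dtype=float)
            if np.any(self.w_ref <= 0):
                raise EcologyError(f"{self.group_id}: w_ref must be positive")
        lo, hi = self.gape_window
        if not lo < hi:
            raise EcologyError(f"{self.group_id}: gape min_ratio must be < max_ratio")
        if not 0.0 < self.assimilation_eff <= 1.0:
            raise EcologyError(f"{self.group_id}: assimilation_eff in (0, 1]")
        for name in ("clearance_rate", "max_ingestion", "respiration_coeff",
                     "linear_mortality", "quadratic_mortality",
                     "recruit_alpha", "growth_rate"):
            if getattr(self, name) < 0:
                raise EcologyError(f"{self.group_id}: {name} must be >= 0")

    def stage_of_bin(self, a: int) -> str:
        return "juv" if a < self.juvenile_adult_split_bin else "adult"

    @property
    def is_consumer(self) -> bool:
        return self.kind != "producer" and self.max_ingestion > 0


class AvailabilityMatrix:
    """Stage-resolved prey availability, entries in [0, 1].

    Keys are (predator_id, predator_stage, prey_id, prey_stage) with stages
    in {"juv", "adult"}; pools and producers use stage "adult".  Missing
    entries mean the prey is unavailable (0).
    """

    def __init__(self, entries: dict[tuple[str, str, str, str], float] | None = None):
        self._entries: dict[tuple[str, str, str, str], float] = {}
        for key, val in (entries or {}).items():
            self.set(*key, val)

    def set(self, pred: str, pred_stage: str, prey: str, prey_stage: str,
            value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise EcologyError(f"availability {value} outside [0, 1]")
        self._entries[(pred, pred_stage, prey, prey_stage)] = float(value)

    def set_all_stages(self, pred: str, prey: str, value: float) -> None:
        for ps in ("juv", "adult"):
            for qs in ("juv", "adult"):
                self.set(pred, ps, prey, qs, value)

    def get(self, pred: str, pred_stage: str, prey: str, prey_stage: str) -> float:
        return self._entries.get((pred, pred_stage, prey, prey_stage), 0.0)

    def prey_of(self, pred: str) -> set[str]:
        return {k[2] for k, v in self._entries.items() if k[0] == pred and v > 0}

    def items(self):
        return self._entries.items()

    def __eq__(self, other):
        return isinstance(other, AvailabilityMatrix) and \
            self._entries == other._entries


@dataclass
class GroupState:
    """Spatial/age-resolved state of one group.

    Age-structured: ``numbers`` (n_boxes, n_age_bins) individuals and
    ``weight_at_age`` (n_age_bins,) grams (a single coastwide weight per age
    bin; redistribution homogenizes weights by construction).  Pools and
    producers: ``biomass`` (n_boxes,) tonnes.
    """

    group_id: str
    kind: str
    numbers: np.ndarray | None = None
    weight_at_age: np.ndarray | None = None
    biomass: np.ndarray | None = None

    def __post_init__(self):
        if self.kind == "age_structured":
            self.numbers = np.asarray(self.numbers, dtype=float)
            self.weight_at_age = np.asarray(self.weight_at_age, dtype=float)
            if np.any(self.numbers < 0):
                raise EcologyError(f"{self.group_id}: negative numbers")
            if np.any(self.weight_at_age <= 0):
                raise EcologyError(f"{self.group_id}: non-positive weights")
        else:
            self.biomass = np.asarray(self.biomass, dtype=float)
            if np.any(self.biomass < 0):
                raise EcologyError(f"{self.group_id}: negative biomass")

    # -- bookkeeping ---------------------------------------------------------
    def biomass_by_box(self) -> np.ndarray:
        """Tonnes per box."""
        if self.kind == "age_structured":
            return (self.numbers * self.weight_at_age[None, :]).sum(axis=1) \
                / G_PER_TONNE
        return self.biomass.copy()

    def total_biomass(self) -> float:
        return float(self.biomass_by_box().sum())

    def numbers_at_age(self) -> np.ndarray:
        """Coastwide totals per age bin."""
        return self.numbers.sum(axis=0)

    def distribution(self) -> np.ndarray:
        """Current per-box share of coastwide biomass (uniform if empty)."""
        b = self.biomass_by_box()
        tot = b.sum()
        if tot <= 0:
            return np.full(b.shape, 1.0 / b.shape[0])
        return b / tot

    def with_distribution(self, proportions: np.ndarray) -> "GroupState":
        """Totals-conserving proportional redistribution."""
        p = np.asarray(proportions, dtype=float)
        if self.kind == "age_structured":
            totals = self.numbers.sum(axis=0)
            return GroupState(
                group_id=self.group_id, kind=self.kind,
                numbers=p[:, None] * totals[None, :],
                weight_at_age=self.weight_at_age.copy(),
            )
        return GroupState(
            group_id=self.group_id, kind=self.kind,
            biomass=p * self.biomass.sum(),
        )

    def copy(self) -> "GroupState":
        return GroupState(
            group_id=self.group_id, kind=self.kind,
            numbers=None if self.numbers is None else self.numbers.copy(),
            weight_at_age=None if self.weight_at_age is None
            else self.weight_at_age.copy(),
            biomass=None if self.biomass is None else self.biomass.copy(),
        )


class MortalityLedger:
    """Per-timestep biomass fluxes (tonnes) for one group.

    ``predation``, ``fishing``, ``linear`` are (n_steps, n_components) where
    components are age bins for age-structured groups and a single column
    for pools/producers.  ``assimilated``, ``respiration``, ``production``
    (producer logistic increment) and ``recruitment`` are per-step totals.
    The bookkeeping identity

        dB = assimilated - respiration + production + recruitment
             - predation - fishing - linear

    holds exactly per step by construction.
    """

    def __init__(self, n_steps: int, n_components: int):
        shape = (n_steps, n_components)
        self.predation = np.zeros(shape)
        self.fishing = np.zeros(shape)
        self.linear = np.zeros(shape)
        self.assimilated = np.zeros(n_steps)
        self.respiration = np.zeros(n_steps)
        self.production = np.zeros(n_steps)
        self.recruitment = np.zeros(n_steps)

    def net_change(self) -> np.ndarray:
        """Per-step net biomass change implied by the ledger (tonnes)."""
        return (
            self.assimilated - self.respiration + self.production
            + self.recruitment
            - self.predation.sum(axis=1) - self.fishing.sum(axis=1)
            - self.linear.sum(axis=1)
        )


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def gape_filter(pred_weight: float, prey_weight: float,
                window: tuple[float, float]) -> float:
    """1 if prey/predator individual-weight ratio lies in the closed window."""
    if pred_weight <= 0 or prey_weight <= 0:
        raise EcologyError("weights must be positive")
    ratio = prey_weight / pred_weight
    return 1.0 if window[0] <= ratio <= window[1] else 0.0


@dataclass(frozen=True)
class PreyItem:
    """One prey component as seen by a predator in one box."""

    group_id: str
    stage: str
    biomass: float  # tonnes in the box
    indiv_weight: float  # g


def consumption(
    pred: FunctionalGroupDef,
    pred_indiv_weight: float,
    pred_stage: str,
    prey_items: list[PreyItem],
    avail: AvailabilityMatrix,
    t_scalar: float,
) -> np.ndarray:
    """Holling type-II intake of each prey, per unit predator biomass per day.

    ``intake_p = t_scalar * I_max * a * A_p * B_p / (I_max + a * sum_q A_q B_q)``
    with ``a`` the clearance rate and ``A`` the availability-matrix entry
    times the gape-window pass/fail.  The summed intake never exceeds
    ``t_scalar * I_max``.
    """
    if t_scalar <= 0:
        raise EcologyError("t_scalar must be positive")
    eff = np.array(
        [
            avail.get(pred.group_id, pred_stage, q.group_id, q.stage)
            * gape_filter(pred_indiv_weight, q.indiv_weight, pred.gape_window)
            * q.biomass
            for q in prey_items
        ]
    )
    enc = pred.clearance_rate * eff
    denom = pred.max_ingestion + enc.sum()
    if denom <= 0:
        return np.zeros(len(prey_items))
    return t_scalar * pred.max_ingestion * enc / denom


def grow(
    weight: float,
    assimilated_intake: float,
    respiration_coeff: float,
    t_scalar: float = 1.0,
    dt: float = 1.0,
    w_floor: float = 0.0,
) -> float:
    """One Euler step of individual weight (g).

    ``w' = w + dt * (assimilated_intake - t_scalar * respiration_coeff * w)``
    floored at ``w_floor`` (the starvation floor), never negative.

    The ecosystem stepper calls this with ``t_scalar = 1``: the Q10 scalar
    is applied to ingestion and clearance (so assimilated intake is already
    temperature-scaled), to linear mortality and to producer growth, but not
    to the respiration cost — warming therefore raises the energy surplus
    and weight-at-age when forage is sufficient.  The ``t_scalar`` argument
    is exposed for sensitivity experiments with temperature-scaled
    metabolic costs.
    """
    if dt <= 0:
        raise EcologyError("dt must be positive")
    w_new = weight + dt * (assimilated_intake - t_scalar * respiration_coeff * weight)
    return max(w_new, w_floor, 0.0)


def apply_mortality(
    biomass: np.ndarray,
    predation_demand: np.ndarray,
    f_rate: np.ndarray,
    linear_rate: np.ndarray,
    dt: float,
):
    """Competing-risks exponential decay of one group's components.

    All arrays are (n_boxes, n_components).  ``predation_demand`` is in
    tonnes/day; ``f_rate`` and ``linear_rate`` are per-day rates (the linear
    rate already includes its Q10 scalar).  Survival is
    ``exp(-(M_pred + F + m) * dt)`` with ``M_pred = demand / biomass``; the
    losses are attributed to components by their rate shares, so predation
    removals never exceed the biomass present, and the factor by which
    realized predation falls short of demand is returned so predator intake
    can be rescaled identically.

    Returns (survival, losses dict of tonnes, demand_scale).
    """
    if np.any(predation_demand < 0):
        raise EcologyError("predation demand must be non-negative")
    b = np.maximum(biomass, 0.0)
    m_pred = np.where(b > 0, predation_demand / np.maximum(b, _TINY), 0.0)
    z = m_pred + f_rate + linear_rate
    surv = np.exp(-z * dt)
    removed = b * (1.0 - surv)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_z = np.where(z > 0, 1.0 / np.maximum(z, _TINY), 0.0)
    losses = {
        "predation": removed * m_pred * inv_z,
        "fishing": removed * f_rate * inv_z,
        "linear": removed * linear_rate * inv_z,
    }
    # realized / demanded predation; equals (1 - e^{-z dt}) / (z dt) <= 1
    demand_dt = predation_demand * dt
    scale = np.where(demand_dt > 0,
                     losses["predation"] / np.maximum(demand_dt, _TINY), 1.0)
    return surv, losses, scale


def recruit(state: GroupState, gdef: FunctionalGroupDef) -> tuple[float, float]:
    """Beverton-Holt recruitment with a body-condition multiplier.

    Spawning stock ``S = sum_a maturity(a) N(a) w(a) (w(a)/w_ref(a))`` in
    tonnes; recruits ``R = alpha S / (beta + S)`` individuals.  Returns
    (recruits, spawning_stock).
    """
    n_tot = state.numbers.sum(axis=0)
    w = state.weight_at_age
    s = float(
        (gdef.maturity_at_bin * n_tot * w * (w / gdef.w_ref)).sum() / G_PER_TONNE
    )
    if s <= 0 or gdef.recruit_alpha <= 0:
        return 0.0, s
    return gdef.recruit_alpha * s / (gdef.recruit_beta + s), s


def add_recruits(state: GroupState, gdef: FunctionalGroupDef, recruits: float,
                 distribution: np.ndarray | None = None) -> float:
    """Insert recruits into age bin 0, mixing weights toward w_ref(0).

    Returns the biomass added (tonnes).  Mutates ``state`` in place.
    """
    if recruits <= 0:
        return 0.0
    p = state.distribution() if distribution is None else distribution
    n0 = state.numbers[:, 0].sum()
    w0 = state.weight_at_age[0]
    state.numbers[:, 0] += p * recruits
    state.weight_at_age[0] = (n0 * w0 + recruits * gdef.w_ref[0]) / (n0 + recruits)
    return recruits * gdef.w_ref[0] / G_PER_TONNE


def age_step(state: GroupState, gdef: FunctionalGroupDef) -> GroupState:
    """Annual fractional promotion between age bins with a plus group.

    A fraction ``1 / years_per_bin(a)`` of bin ``a`` moves to bin ``a+1``;
    the final bin accumulates.  Promoted fish carry their weight, so the
    receiving bin's coastwide weight becomes the numbers-weighted mean.
    Total numbers and biomass are conserved exactly.
    """
    n = state.numbers
    w = state.weight_at_age
    nb, na = n.shape
    frac = 1.0 / np.asarray(gdef.years_per_bin, dtype=float)
    new_n = np.zeros_like(n)
    new_w = w.copy()
    stay = n * (1.0 - frac[None, :])
    move = n * frac[None, :]
    new_n[:, 0] = stay[:, 0]
    for a in range(1, na):
        incoming = move[:, a - 1]
        if a == na - 1:
            retained = n[:, a]  # plus group: nothing leaves
        else:
            retained = stay[:, a]
        new_n[:, a] = retained + incoming
        tot = retained.sum() + incoming.sum()
        if tot > 0:
            new_w[a] = (retained.sum() * w[a] + incoming.sum() * w[a - 1]) / tot
    return GroupState(group_id=state.group_id, kind=state.kind,
                      numbers=new_n, weight_at_age=new_w)


def producer_growth(
    biomass: np.ndarray, light_saturation_rate: float, t_scalar: np.ndarray,
    carrying_capacity: np.ndarray, dt: float,
) -> np.ndarray:
    """Logistic producer growth ``B' = B + dt ts r B (1 - B/K)``, floored at 0."""
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise EcologyError("producer biomass must be non-negative")
    k = np.maximum(np.broadcast_to(
        np.asarray(carrying_capacity, dtype=float), b.shape), _TINY)
    return np.maximum(b + dt * t_scalar * light_saturation_rate * b * (1 - b / k),
                      0.0)


# ---------------------------------------------------------------------------
# full-ecosystem stepping
# ---------------------------------------------------------------------------

@dataclass
class FishingField:
    """Static per-box fishing rates, precomputed from the fleet set.

    ``rates[group_id]`` is the summed per-day rate per box; ``shares`` maps
    (group_id) -> (n_fleets, n_boxes) array of each fleet's share of the rate
    in each box (zero rows where the fleet has no access); ``fleet_ids``
    orders the share rows.
    """

    rates: dict[str, np.ndarray]
    shares: dict[str, np.ndarray]
    fleet_ids: list[str]

    @classmethod
    def empty(cls, group_ids, n_boxes: int) -> "FishingField":
        return cls(
            rates={g: np.zeros(n_boxes) for g in group_ids},
            shares={g: np.zeros((0, n_boxes)) for g in group_ids},
            fleet_ids=[],
        )


@dataclass
class Ecosystem:
    """All state needed to step the coupled system on one geometry."""

    geometry: "ModelGeometry"
    defs: dict[str, FunctionalGroupDef]
    avail: AvailabilityMatrix
    states: dict[str, GroupState]
    fishing: FishingField
    sdm_series: dict[str, DistributionSeries] = field(default_factory=dict)
    pinned_distributions: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        nb = self.geometry.n_boxes
        for gid, st in self.states.items():
            if gid not in self.defs:
                raise EcologyError(f"state for unknown group {gid}")
            if st.kind != self.defs[gid].kind:
                raise EcologyError(f"{gid}: state/def kind mismatch")
            shape = st.numbers.shape[0] if st.kind == "age_structured" \
                else st.biomass.shape[0]
            if shape != nb:
                raise EcologyError(f"{gid}: state does not cover all boxes")
        for gid in self.sdm_series:
            if gid not in self.defs:
                raise EcologyError(f"SDM series for unknown group {gid}")
        for gid in self.defs:
            if gid not in self.states:
                raise EcologyError(f"missing initial state for {gid}")
            if gid not in self.fishing.rates:
                raise EcologyError(f"missing fishing field for {gid}")


def _prey_components(eco: Ecosystem):
    """Flatten all groups into prey components.

    Returns (index list of (gid, age-or-None), biomass (n_comp, n_boxes),
    indiv weights (n_comp,), stages (n_comp,), comp slices per group).
    """
    idx, weights, stages, rows = [], [], [], []
    slices = {}
    for gid, st in eco.states.items():
        gdef = eco.defs[gid]
        start = len(idx)
        if st.kind == "age_structured":
            bb = st.numbers * st.weight_at_age[None, :] / G_PER_TONNE
            for a in range(gdef.n_age_bins):
                idx.append((gid, a))
                rows.append(bb[:, a])
                weights.append(st.weight_at_age[a])
                stages.append(gdef.stage_of_bin(a))
        else:
            idx.append((gid, None))
            rows.append(st.biomass.copy())
            weights.append(gdef.pool_individual_weight)
            stages.append("adult")
        slices[gid] = slice(start, len(idx))
    biomass = (
        np.array(rows) if rows else np.zeros((0, eco.geometry.n_boxes))
    )
    return idx, biomass, np.array(weights), stages, slices


def step_ecosystem(
    eco: Ecosystem,
    temp_field: np.ndarray,
    t: float,
    dt: float,
    annual: bool = False,
    ledgers: dict[str, MortalityLedger] | None = None,
    catch_by_fleet: dict[str, np.ndarray] | None = None,
    step_index: int = 0,
) -> None:
    """Advance the whole system by one timestep (in place).

    ``temp_field`` is per-box temperature (degC) for this step, ``t`` the
    decimal year, ``dt`` the step length in days.  When ``annual`` is true,
    recruitment and age promotion run after the within-step dynamics.
    ``ledgers`` (group_id -> MortalityLedger) and ``catch_by_fleet``
    (group_id -> (n_steps, n_fleets) array) are filled at ``step_index``
    when provided.
    """
    defs, states, avail = eco.defs, eco.states, eco.avail

    # (1) redistribute: SDM-forced groups follow the interpolated snapshot,
    # unforced groups are pinned to their configured static distribution.
    for gid, st in states.items():
        gdef = defs[gid]
        if gid in eco.sdm_series:
            p = interpolate_distribution(eco.sdm_series[gid], t)
        elif gid in eco.pinned_distributions:
            p = eco.pinned_distributions[gid]
        else:
            continue
        p = apply_tolerance_mask(p, temp_field, gdef.tolerance, group_id=gid)
        states[gid] = st.with_distribution(p)

    # (2) temperature scalar per box
    ts_box = temperature_scalar(temp_field)

    def ts_for(gdef):
        return ts_box if gdef.q10_sensitive else np.ones_like(ts_box)

    # (3) producer growth
    for gid, st in states.items():
        gdef = defs[gid]
        if gdef.kind != "producer":
            continue
        b_new = producer_growth(st.biomass, gdef.growth_rate, ts_for(gdef),
                                gdef.carrying_capacity, dt)
        if ledgers is not None:
            ledgers[gid].production[step_index] = (b_new - st.biomass).sum()
        st.biomass = b_new

    # (4) consumption: per-predator demand on every prey component
    comp_idx, comp_b, comp_w, comp_stage, comp_slices = _prey_components(eco)
    n_comp, n_boxes = comp_b.shape
    avail_cache = getattr(eco, "_avail_cache", None)
    if avail_cache is None or avail_cache.get("_n_comp") != n_comp:
        avail_cache = {"_n_comp": n_comp}
        for gid, gdef in defs.items():
            if not gdef.is_consumer:
                continue
            for stage in ("juv", "adult"):
                avail_cache[(gid, stage)] = np.array([
                    avail.get(gid, stage, cg, cs)
                    for (cg, _), cs in zip(comp_idx, comp_stage)
                ])
        eco._avail_cache = avail_cache
    demand_total = np.zeros((n_comp, n_boxes))
    pred_demands: dict[str, np.ndarray] = {}  # gid -> (n_bins, n_comp, n_boxes)
    for gid, st in states.items():
        gdef = defs[gid]
        if not gdef.is_consumer:
            continue
        ts = ts_for(gdef)
        if st.kind == "age_structured":
            n_bins = gdef.n_age_bins
            pred_w = st.weight_at_age
            forage_b = st.numbers * gdef.w_ref[None, :] / G_PER_TONNE  # (box, bin)
        else:
            n_bins = 1
            pred_w = np.array([gdef.pool_individual_weight])
            forage_b = st.biomass[:, None]
        lo, hi = gdef.gape_window
        ratios = comp_w[None, :] / pred_w[:, None]  # (bin, comp)
        gape_ok = ((ratios >= lo) & (ratios <= hi)).astype(float)
        dem = np.zeros((n_bins, n_comp, n_boxes))
        for a in range(n_bins):
            stage = gdef.stage_of_bin(a) if st.kind == "age_structured" else "adult"
            a_eff = avail_cache[(gid, stage)] * gape_ok[a]
            if not np.any(a_eff > 0):
                continue
            enc = gdef.clearance_rate * a_eff[:, None] * comp_b  # (comp, box)
            enc_sum = enc.sum(axis=0)
            denom = gdef.max_ingestion + enc_sum
            # per-unit-forage-biomass intake of each comp (1/day)
            intake_pu = ts[None, :] * gdef.max_ingestion * enc / denom[None, :]
            dem[a] = intake_pu * forage_b[:, a][None, :]
        pred_demands[gid] = dem
        demand_total += dem.sum(axis=0)

    # (5) mortality: competing exponential rates per component
    surv_by_group: dict[str, np.ndarray] = {}
    scale = np.ones((n_comp, n_boxes))
    for gid, st in states.items():
        gdef = defs[gid]
        sl = comp_slices[gid]
        ncg = sl.stop - sl.start
        b = comp_b[sl].T  # (box, comp)
        dem = demand_total[sl].T
        f = np.repeat(eco.fishing.rates[gid][:, None], ncg, axis=1)
        m_lin = ts_for(gdef)[:, None] * gdef.linear_mortality * np.ones((1, ncg))
        if gdef.quadratic_mortality > 0:
            # density-dependent closure (unresolved predators); not Q10-scaled
            m_lin = m_lin + gdef.quadratic_mortality * b
        surv, losses, sc = apply_mortality(b, dem, f, m_lin, dt)
        scale[sl] = sc.T
        surv_by_group[gid] = surv
        if st.kind == "age_structured":
            st.numbers *= surv
        else:
            st.biomass = st.biomass * surv[:, 0]
        if ledgers is not None:
            led = ledgers[gid]
            led.predation[step_index] = losses["predation"].sum(axis=0)
            led.fishing[step_index] = losses["fishing"].sum(axis=0)
            led.linear[step_index] = losses["linear"].sum(axis=0)
        if catch_by_fleet is not None and eco.fishing.shares[gid].shape[0]:
            catch_box = losses["fishing"].sum(axis=1)  # (box,)
            catch_by_fleet[gid][step_index] = eco.fishing.shares[gid] @ catch_box

    # (6) growth from realized (cap-rescaled) intake
    for gid, st in states.items():
        gdef = defs[gid]
        if not gdef.is_consumer:
            continue
        realized = pred_demands[gid] * scale[None, :, :]  # (bin, comp, box)
        intake_box = realized.sum(axis=1)  # tonnes/day per (bin, box)
        ts = ts_for(gdef)
        if st.kind == "age_structured":
            forage_b = st.numbers * gdef.w_ref[None, :] / G_PER_TONNE
            n_surv = st.numbers
            assim_t = 0.0
            gain_t = 0.0
            w_new = st.weight_at_age.copy()
            for a in range(gdef.n_age_bins):
                n_a = n_surv[:, a]
                n_sum = n_a.sum()
                if n_sum <= 0:
                    continue
                # realized per-unit-forage intake, numbers-weighted over boxes
                fb = forage_b[:, a]
                i_pu = np.where(fb > 0, intake_box[a] / np.maximum(fb, _TINY), 0.0)
                mean_ipu = (n_a * i_pu).sum() / n_sum
                assim_ind = gdef.assimilation_eff * mean_ipu * gdef.w_ref[a]
                w_new[a] = grow(
                    st.weight_at_age[a], assim_ind, gdef.respiration_coeff,
                    t_scalar=1.0, dt=dt,
                    w_floor=gdef.starvation_floor * gdef.w_ref[a],
                )
                assim_t += n_sum * assim_ind * dt / G_PER_TONNE
                gain_t += n_sum * (w_new[a] - st.weight_at_age[a]) / G_PER_TONNE
            st.weight_at_age = w_new
            if ledgers is not None:
                led = ledgers[gid]
                led.assimilated[step_index] = assim_t
                led.respiration[step_index] = assim_t - gain_t
        else:  # consuming pool
            assim = gdef.assimilation_eff * intake_box[0] * dt  # tonnes per box
            resp = gdef.respiration_coeff * st.biomass * dt
            b_new = np.maximum(st.biomass + assim - resp, 0.0)
            if ledgers is not None:
                led = ledgers[gid]
                led.assimilated[step_index] = assim.sum()
                led.respiration[step_index] = \
                    assim.sum() - (b_new - st.biomass).sum()
            st.biomass = b_new

    # annual events: recruitment (spawning output from the pre-aging stock)
    # then age promotion; the new cohort enters the vacated first bin so it
    # is not promoted in the same year it was spawned
    if annual:
        for gid, st in states.items():
            gdef = defs[gid]
            if gdef.kind != "age_structured":
                continue
            r, _ = recruit(st, gdef)
            dist = st.distribution()
            aged = age_step(st, gdef)
            added = add_recruits(aged, gdef, r, distribution=dist)
            if ledgers is not None:
                ledgers[gid].recruitment[step_index] = added
            states[gid] = aged
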