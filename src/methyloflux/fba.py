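"""Flux balance analysis with isotope-derived side constraints.

The linear program maximizes the biomass objective subject to steady-state
mass balance over internal metabolites, flux bounds, and the scenario's
side constraints:

* fixed exchange rates (methanol uptake, formate production),
* flux-ratio equalities ``v_num - ratio * v_den = 0``,
* flux-order inequalities ``v_greater >= v_lesser``,
* an O2/methanol consumption-ratio floor,
* biomass-composition couplings (glycogen/EPS sink flux proportional to
  growth), and growth-associated / non-growth-associated ATP maintenance.

Solved with scipy's HiGHS backend.  Only the optimal objective and
explicitly constrained fluxes are contract-stable: degenerate optima can
return different flux vectors.  ``minimize_total_flux=True`` adds a
lexicographic second stage (minimum sum of absolute fluxes at the optimal
growth) for a canonical vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, assert_valid

METHANOL_MOLAR_MASS = 0.03204  # g/mmol

FEASIBILITY_TOL = 1e-9
REPORT_TOL = 1e-6


class ConfigurationError(ValueError):
    """A scenario references a reaction or role the model does not define."""


@dataclass
class RatioConstraint:
    """Enforce v_numerator = ratio * v_denominator."""

    numerator_reaction: str
    denominator_reaction: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")


@dataclass
class OrderConstraint:
    """Enforce v_greater >= v_lesser."""

    greater_reaction: str
    lesser_reaction: str


@dataclass
class MaintenanceConfig:
    gam: float = 54.35   # mmol ATP/gcdw
    ngam: float = 8.39   # mmol ATP/(gcdw.h)

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance parameters must be >= 0")


@dataclass
class ScenarioConfig:
    """One FBA scenario: measured rates, biomass fractions, maintenance and
    isotope-derived constraints.  ``None`` leaves the model untouched."""

    name: str = "scenario"
    methanol_uptake: float | None = None      # mmol/(gcdw.h), fixed
    formate_production: float | None = None   # mmol/(gcdw.h), fixed
    glycogen_fraction: float | None = None    # share of dry weight
    eps_fraction: float | None = None
    o2_per_methanol_min: float | None = None
    maintenance: MaintenanceConfig | None = None
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    order_constraints: list[OrderConstraint] = field(default_factory=list)
    fixed_fluxes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, what in ((self.methanol_uptake, "methanol_uptake"),
                        (self.formate_production, "formate_production")):
            if v is not None and v < 0:
                raise ValueError(f"{what} must be >= 0")
        for v, what in ((self.glycogen_fraction, "glycogen_fraction"),
                        (self.eps_fraction, "eps_fraction")):
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{what} must be in [0, 1]")

    def extended(self, **changes) -> "ScenarioConfig":
        """Copy with additional constraints appended (ladder building)."""
        new = replace(
            self,
            ratio_constraints=list(self.ratio_constraints),
            order_constraints=list(self.order_constraints),
            fixed_fluxes=dict(self.fixed_fluxes),
        )
        for key, value in changes.items():
            if key in ("ratio_constraints", "order_constraints"):
                getattr(new, key).extend(value)
            elif key == "fixed_fluxes":
                new.fixed_fluxes.update(value)
            else:
                setattr(new, key, value)
        return new


@dataclass
class FBASolution:
    status: str  # optimal | infeasible | unbounded
    growth_rate: float
    fluxes: dict[str, float]
    o2_per_methanol: float | None = None
    biomass_yield: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class RobustnessCurve:
    reaction: str
    grid: list[float]
    growth: list[float | None]  # None marks infeasible grid points
    max_feasible: float | None

    def argmax_interval(self, tol: float = REPORT_TOL) -> tuple[float, float]:
        feas = [(g, mu) for g, mu in zip(self.grid, self.growth)
                if mu is not None]
        if not feas:
            raise ValueError("curve has no feasible point")
        best = max(mu for _, mu in feas)
        at = [g for g, mu in feas if mu >= best - tol]
        return min(at), max(at)


# ---------------------------------------------------------------------------
# LP assembly


def _apply_gam(model: MetabolicModel, gam: float) -> MetabolicModel:
    """Override growth-associated maintenance by rewriting the ATP term of
    the biomass reaction (annotation hook: roles gam_atp/gam_adp)."""
    roles = model.annotations.get("roles", {})
    bio = roles.get("biomass")
    atp = roles.get("gam_atp")
    adp = roles.get("gam_adp")
    if bio is None or atp is None:
        raise ConfigurationError(
            "scenario sets GAM but model lacks biomass/gam_atp role hooks")
    m = model.copy()
    r = m.get_reaction(bio)
    r.stoichiometry[atp] = -gam
    if adp is not None:
        r.stoichiometry[adp] = gam
    m.annotations["gam_in_biomass"] = gam
    return m


def _resolve(model: MetabolicModel, rid: str, what: str) -> int:
    for i, r in enumerate(model.reactions):
        if r.id == rid:
            return i
    raise ConfigurationError(f"{what}: reaction {rid!r} not in model")


def _role_index(model: MetabolicModel, role: str) -> int:
    rid = model.role(role)
    if rid is None:
        raise ConfigurationError(
            f"scenario requires model role {role!r} (annotations['roles'])")
    return _resolve(model, rid, f"role {role}")


class _LP:
    """Assembled standard-form LP for one (model, scenario) pair."""

    def __init__(self, model: MetabolicModel,
                 scenario: ScenarioConfig | None) -> None:
        scenario = scenario or ScenarioConfig()
        if scenario.maintenance is not None and scenario.maintenance.gam >= 0:
            if model.role("biomass") is not None:
                model = _apply_gam(model, scenario.maintenance.gam)
        self.model = model
        self.scenario = scenario
        n = len(model.reactions)
        self.n = n
        self.c = np.array([r.objective_coefficient for r in model.reactions])
        self.lb = np.array([r.lower_bound for r in model.reactions], float)
        self.ub = np.array([r.upper_bound for r in model.reactions], float)

        externals = model.external_ids()
        internal = [m.id for m in model.metabolites if not m.is_external]
        self.met_index = {m: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), n))
        for j, r in enumerate(model.reactions):
            for m, coeff in r.stoichiometry.items():
                if m not in externals:
                    S[self.met_index[m], j] = coeff
        self.S = S

        eq_rows: list[np.ndarray] = []
        eq_rhs: list[float] = []
        ub_rows: list[np.ndarray] = []
        ub_rhs: list[float] = []

        sc = scenario
        if sc.methanol_uptake is not None:
            j = _role_index(model, "methanol_uptake")
            self.lb[j] = self.ub[j] = sc.methanol_uptake
        if sc.formate_production is not None:
            j = _role_index(model, "formate_excretion")
            self.lb[j] = self.ub[j] = sc.formate_production
        if sc.maintenance is not None:
            j = _role_index(model, "maintenance")
            self.lb[j] = max(self.lb[j], sc.maintenance.ngam)
        for rid, value in sc.fixed_fluxes.items():
            j = _resolve(model, rid, "fixed flux")
            self.lb[j] = self.ub[j] = value
        # fumarase-style knockouts via fixed_fluxes work for reversible
        # reactions because both bounds are pinned.

        masses = model.annotations.get("monomer_mass", {})
        for frac, role, mkey in ((sc.glycogen_fraction, "glycogen_sink",
                                  "glycogen"),
                                 (sc.eps_fraction, "eps_sink", "eps")):
            if frac is None:
                continue
            j = _role_index(model, role)
            jb = _role_index(model, "biomass")
            mass = float(masses.get(mkey, 0.162))
            row = np.zeros(n)
            row[j] = 1.0
            row[jb] = -frac / mass
            eq_rows.append(row)
            eq_rhs.append(0.0)
        if sc.o2_per_methanol_min is not None:
            jo = _role_index(model, "o2_uptake")
            jm = _role_index(model, "methanol_uptake")
            row = np.zeros(n)  # -(v_o2 - r*v_meoh) <= 0
            row[jo] = -1.0
            row[jm] = sc.o2_per_methanol_min
            ub_rows.append(row)
            ub_rhs.append(0.0)
        for rc in sc.ratio_constraints:
            jn = _resolve(model, rc.numerator_reaction, "ratio numerator")
            jd = _resolve(model, rc.denominator_reaction, "ratio denominator")
            row = np.zeros(n)
            row[jn] = 1.0
            row[jd] = -rc.ratio
            eq_rows.append(row)
            eq_rhs.append(0.0)
        for oc in sc.order_constraints:
            jg = _resolve(model, oc.greater_reaction, "order greater")
            jl = _resolve(model, oc.lesser_reaction, "order lesser")
            row = np.zeros(n)  # v_lesser - v_greater <= 0
            row[jg] = -1.0
            row[jl] = 1.0
            ub_rows.append(row)
            ub_rhs.append(0.0)

        self.A_eq = np.vstack([S] + [r[None, :] for r in eq_rows])
        self.b_eq = np.concatenate([np.zeros(S.shape[0]), np.array(eq_rhs)])
        self.A_ub = (np.vstack(ub_rows) if ub_rows
                     else np.zeros((0, n)))
        self.b_ub = np.array(ub_rhs)

    def solve(self) -> tuple[str, float, np.ndarray | None]:
        res = linprog(-self.c, A_ub=self.A_ub if len(self.b_ub) else None,
                      b_ub=self.b_ub if len(self.b_ub) else None,
                      A_eq=self.A_eq, b_eq=self.b_eq,
                      bounds=list(zip(self.lb, self.ub)), method="highs")
        if res.status == 0:
            return "optimal", float(-res.fun), res.x
        if res.status == 2:
            return "infeasible", float("nan"), None
        if res.status == 3:
            return "unbounded", float("inf"), None
        return "infeasible", float("nan"), None  # pragma: no cover

    def solve_min_total_flux(self, growth: float) -> np.ndarray | None:
        """Second lexicographic stage: min sum |v| s.t. objective = growth."""
        n = self.n
        # v = p - q, p,q >= 0
        c2 = np.ones(2 * n)
        A_eq = np.hstack([self.A_eq, -self.A_eq])
        b_eq = self.b_eq
        obj_row = np.hstack([self.c, -self.c])
        A_eq = np.vstack([A_eq, obj_row])
        b_eq = np.concatenate([b_eq, [growth]])
        A_ub_rows = []
        b_ub = []
        if len(self.b_ub):
            A_ub_rows.append(np.hstack([self.A_ub, -self.A_ub]))
            b_ub.append(self.b_ub)
        # lb <= p - q <= ub
        eye = np.eye(n)
        A_ub_rows.append(np.hstack([eye, -eye]))
        b_ub.append(self.ub)
        A_ub_rows.append(np.hstack([-eye, eye]))
        b_ub.append(-self.lb)
        res = linprog(c2, A_ub=np.vstack(A_ub_rows), b_ub=np.concatenate(b_ub),
                      A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * 2 * n,
                      method="highs")
        if res.status != 0:
            return None
        return res.x[:n] - res.x[n:]


def solve_fba(model: MetabolicModel, scenario: ScenarioConfig | None = None,
              minimize_total_flux: bool = False) -> FBASolution:
    """Maximize the biomass objective under the scenario's constraints.

    Returns an :class:`FBASolution`; on infeasibility/unboundedness the flux
    map is empty and ``growth_rate`` is NaN/inf.  Feasible solutions satisfy
    mass balance to within ``REPORT_TOL`` (asserted).
    """
    assert_valid(model)
    lp = _LP(model.copy(), scenario)
    status, growth, x = lp.solve()
    if x is None:
        return FBASolution(status, growth, {})
    if minimize_total_flux:
        x2 = lp.solve_min_total_flux(growth)
        if x2 is not None:
            x = x2
    residual = np.abs(lp.S @ x).max() if lp.S.size else 0.0
    if residual > REPORT_TOL:  # pragma: no cover - solver contract
        raise RuntimeError(f"mass-balance residual {residual:.2e} > tol")
    fluxes = {r.id: float(v) for r, v in zip(lp.model.reactions, x)}
    o2_ratio = None
    byield = None
    roles = lp.model.annotations.get("roles", {})
    if "o2_uptake" in roles and "methanol_uptake" in roles:
        vm = abs(fluxes.get(roles["methanol_uptake"], 0.0))
        vo = abs(fluxes.get(roles["o2_uptake"], 0.0))
        if vm > REPORT_TOL:
            o2_ratio = vo / vm
            byield = growth / (vm * METHANOL_MOLAR_MASS)
    return FBASolution(status, growth, fluxes, o2_ratio, byield)


# ---------------------------------------------------------------------------
# analyses


def run_scenario_ladder(model: MetabolicModel,
                        scenarios: Sequence[ScenarioConfig],
                        minimize_total_flux: bool = False) -> list[dict]:
    """Solve an ordered list of scenarios (each typically extending the
    previous) and return one summary row per scenario.  Infeasible scenarios
    are reported in-row; the ladder continues."""
    rows = []
    for sc in scenarios:
        sol = solve_fba(model, sc, minimize_total_flux=minimize_total_flux)
        rows.append({
            "scenario": sc.name,
            "status": sol.status,
            "growth_rate": sol.growth_rate if sol.optimal else float("nan"),
            "o2_per_methanol": sol.o2_per_methanol,
            "biomass_yield": sol.biomass_yield,
        })
    return rows


def robustness_scan(model: MetabolicModel, scenario: ScenarioConfig | None,
                    reaction: str, step: float = 0.1,
                    max_value: float | None = None,
                    refine: bool = True) -> RobustnessCurve:
    """Fix ``reaction`` at 0, step, 2*step, ... (equality), re-optimizing
    growth each time; stop at the first infeasible point or ``max_value``.

    ``max_feasible`` is refined by bisection to within step/10 of the true
    feasibility boundary.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    scenario = scenario or ScenarioConfig()
    _resolve(model, reaction, "robustness reaction")

    def growth_at(value: float) -> float | None:
        sc = scenario.extended(fixed_fluxes={reaction: value})
        sol = solve_fba(model, sc)
        return sol.growth_rate if sol.optimal else None

    grid: list[float] = []
    growth: list[float | None] = []
    value = 0.0
    last_feasible: float | None = None
    first_infeasible: float | None = None
    max_iter = 100000
    for _ in range(max_iter):
        if max_value is not None and value > max_value + 1e-12:
            break
        mu = growth_at(value)
        grid.append(value)
        growth.append(mu)
        if mu is None:
            first_infeasible = value
            break
        last_feasible = value
        value = round(value + step, 12)
    max_feasible = last_feasible
    if (refine and last_feasible is not None
            and first_infeasible is not None):
        lo, hi = last_feasible, first_infeasible
        while hi - lo > step / 10:
            mid = 0.5 * (lo + hi)
            if growth_at(mid) is not None:
                lo = mid
            else:
                hi = mid
        max_feasible = lo
    return RobustnessCurve(reaction, grid, growth, max_feasible)


def ratio_sensitivity_scan(model: MetabolicModel,
                           scenario: ScenarioConfig | None,
                           numerator: str, denominator: str,
                           ratio_values: Iterable[float]
                           ) -> list[tuple[float, float]]:
    """Optimal growth as a function of an injected flux-ratio constraint
    (e.g. EMP/ED).  Logarithmic grids are the caller's choice of values."""
    scenario = scenario or ScenarioConfig()
    out = []
    for ratio in ratio_values:
        if ratio <= 0:
            raise ValueError("ratio values must be positive")
        sc = scenario.extended(ratio_constraints=[
            RatioConstraint(numerator, denominator, ratio)])
        sol = solve_fba(model, sc)
        out.append((float(ratio),
                    sol.growth_rate if sol.optimal else float("nan")))
    return out


def atpm_grid(model: MetabolicModel, scenario: ScenarioConfig | None,
              gam_values: Sequence[float],
              ngam_values: Sequence[float]) -> np.ndarray:
    """Growth rate over a (GAM, NGAM) grid; rows index gam_values, columns
    ngam_values.  NaN marks infeasible cells."""
    scenario = scenario or ScenarioConfig()
    out = np.full((len(gam_values), len(ngam_values)), np.nan)
    for i, gam in enumerate(gam_values):
        for j, ngam in enumerate(ngam_values):
            if gam < 0 or ngam < 0:
                raise ValueError("maintenance grid values must be >= 0")
            sc = replace(scenario, maintenance=MaintenanceConfig(gam, ngam))
            sol = solve_fba(model, sc)
            if sol.optimal:
                out[i, j] = sol.growth_rate
    return out
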