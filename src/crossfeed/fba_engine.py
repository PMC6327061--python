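"""Linear-programming core: growth maximization and costless secretions.

Growth maximization is a standard flux-balance LP (maximize the biomass flux
subject to S.v = 0 and flux bounds). Costless secretions come from a
two-stage solve: stage 1 fixes the optimal growth rate v_g0, stage 2
minimizes the summed absolute flux subject to growth >= v_g0 (with a 1e-9
relative slack against solver tolerance) and reports every exchange flux at
or above the 0.01 mmol/gDW/h secretion cutoff. Forced-secretion probes pin
one exchange flux and re-maximize growth to categorize the secretion as
costly, costless, or beneficial.

The LP subroutine is scipy.optimize.linprog with the HiGHS backend; absolute
values are linearized by splitting each flux into non-negative forward and
backward parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix, eye, hstack, vstack

from .media import Medium, apply_medium
from .model_core import MetabolicModel

SECRETION_CUTOFF = 0.01
UPTAKE_CUTOFF = 0.01
GROWTH_THRESHOLD = 1e-6
GROWTH_SLACK_REL = 1e-9
ALT_OBJECTIVE_MIN_GROWTH = 0.01
STEADY_STATE_TOL = 1e-6

Objective = Literal["max_growth", "min_biomass", "max_atp", "min_atp"]

__all__ = [
    "FluxSolution",
    "SecretionProfile",
    "solve_growth",
    "costless_secretions",
    "secretion_cost",
    "solve_alternative_objective",
    "verify_secretion_uniqueness",
    "SECRETION_CUTOFF",
    "UPTAKE_CUTOFF",
    "GROWTH_THRESHOLD",
]


@dataclass
class FluxSolution:
    status: Literal["optimal", "infeasible", "unbounded"]
    growth_rate: float
    fluxes: dict[str, float] = field(default_factory=dict)
    total_abs_flux: float = 0.0
    objective_value: float = 0.0
    steady_state_residual: float = 0.0

    @property
    def grows(self) -> bool:
        return self.status == "optimal" and self.growth_rate >= GROWTH_THRESHOLD

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("reaction_id\tflux\n")
            for rid, flux in self.fluxes.items():
                fh.write(f"{rid}\t{flux:.10g}\n")
        return path


@dataclass
class SecretionProfile:
    """Exchange fluxes at or above the secretion cutoff, by metabolite."""

    secretions: dict[str, float] = field(default_factory=dict)
    cutoff: float = SECRETION_CUTOFF

    def __contains__(self, met_id: str) -> bool:
        return met_id in self.secretions

    def __iter__(self):
        return iter(self.secretions)

    def __len__(self) -> int:
        return len(self.secretions)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("metabolite_id\tflux\n")
            for met, flux in sorted(self.secretions.items()):
                fh.write(f"{met}\t{flux:.10g}\n")
        return path


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _stoichiometric_matrix(model: MetabolicModel) -> coo_matrix:
    rows, cols, data = [], [], []
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoich.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coeff)
    return coo_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def _bounded(model: MetabolicModel, medium: Medium | None, oxygen_override: bool | None):
    if medium is not None:
        return apply_medium(model, medium, oxygen_override)
    return model


def _solution_from_lp(model: MetabolicModel, res, objective_value: float) -> FluxSolution:
    n = len(model.reactions)
    v = np.asarray(res.x[:n])
    S = _stoichiometric_matrix(model)
    residual = float(np.max(np.abs(S @ v))) if n else 0.0
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    growth = fluxes[model.biomass_reaction_id]
    return FluxSolution(
        status="optimal",
        growth_rate=growth,
        fluxes=fluxes,
        total_abs_flux=float(np.sum(np.abs(v))),
        objective_value=objective_value,
        steady_state_residual=residual,
    )


def _optimize(
    model: MetabolicModel,
    objective_rxn: str,
    sense: Literal["max", "min"],
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    minimize_total_flux: bool = False,
) -> FluxSolution:
    """Solve one LP over the model's flux space.

    With ``minimize_total_flux`` the objective becomes sum|v| (flux splitting
    v = p - q) and ``objective_rxn``/``sense`` are ignored.
    """
    n = len(model.reactions)
    S = _stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if extra_bounds:
        idx = {r.id: j for j, r in enumerate(model.reactions)}
        for rid, (lo, hi) in extra_bounds.items():
            j = idx[rid]
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)
            if lb[j] > ub[j]:
                return FluxSolution(status="infeasible", growth_rate=0.0)

    if minimize_total_flux:
        # variables [v, p, q]; S v = 0; v - p + q = 0; min sum(p + q)
        balance = hstack([S, coo_matrix((S.shape[0], 2 * n))])
        split = hstack([eye(n), -eye(n), eye(n)])
        A_eq = vstack([balance, split]).tocsr()
        b_eq = np.zeros(S.shape[0] + n)
        c = np.concatenate([np.zeros(n), np.ones(2 * n)])
        bounds = (
            [(lb[j], ub[j]) for j in range(n)]
            + [(0.0, None)] * n
            + [(0.0, None)] * n
        )
    else:
        A_eq = S.tocsr()
        b_eq = np.zeros(S.shape[0])
        c = np.zeros(n)
        j_obj = next(j for j, r in enumerate(model.reactions) if r.id == objective_rxn)
        c[j_obj] = -1.0 if sense == "max" else 1.0
        bounds = [(lb[j], ub[j]) for j in range(n)]

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        kind = "infeasible" if status in ("infeasible", "iteration_limit", "numerical") else "unbounded"
        return FluxSolution(status=kind, growth_rate=0.0)
    if minimize_total_flux:
        objective_value = float(res.fun)
    else:
        objective_value = float(-res.fun if sense == "max" else res.fun)
    return _solution_from_lp(model, res, objective_value)


def solve_growth(
    model: MetabolicModel,
    medium: Medium | None = None,
    oxygen_override: bool | None = None,
) -> FluxSolution:
    """Maximize biomass flux on the (medium-bounded) model.

    Infeasible models (e.g. an unsatisfiable maintenance minimum) report
    ``status='infeasible'`` with growth 0 by contract.
    """
    bounded = _bounded(model, medium, oxygen_override)
    return _optimize(bounded, bounded.biomass_reaction_id, "max")


def _extract_secretions(model: MetabolicModel, solution: FluxSolution) -> SecretionProfile:
    secretions = {}
    for rxn in model.exchange_reactions:
        flux = solution.fluxes.get(rxn.id, 0.0)
        if flux >= SECRETION_CUTOFF:
            secretions[rxn.exchanged_metabolite] = flux
    return SecretionProfile(secretions=secretions)


def extract_uptakes(model: MetabolicModel, solution: FluxSolution) -> dict[str, float]:
    """Exchange fluxes below the -0.01 uptake-evidence cutoff, by metabolite."""
    uptakes = {}
    for rxn in model.exchange_reactions:
        flux = solution.fluxes.get(rxn.id, 0.0)
        if flux <= -UPTAKE_CUTOFF:
            uptakes[rxn.exchanged_metabolite] = flux
    return uptakes


def _growth_floor(v: float) -> float:
    return v * (1.0 - GROWTH_SLACK_REL) if v >= 0 else v * (1.0 + GROWTH_SLACK_REL)


def costless_secretions(
    model: MetabolicModel,
    medium: Medium | None = None,
    oxygen_override: bool | None = None,
) -> tuple[FluxSolution, SecretionProfile]:
    """Two-stage solve: optimal growth, then minimum total flux at that growth.

    Returns the stage-2 (minimum-|v|) solution together with the secretion
    profile read off its exchange fluxes. If stage 1 finds no growth above
    the threshold, the stage-1 solution and an empty profile are returned.
    """
    bounded = _bounded(model, medium, oxygen_override)
    stage1 = _optimize(bounded, bounded.biomass_reaction_id, "max")
    if not stage1.grows:
        return stage1, SecretionProfile()
    floor = _growth_floor(stage1.growth_rate)
    stage2 = _optimize(
        bounded,
        bounded.biomass_reaction_id,
        "max",
        extra_bounds={bounded.biomass_reaction_id: (floor, np.inf)},
        minimize_total_flux=True,
    )
    if stage2.status != "optimal":  # solver-tolerance fallback: loosen once more
        stage2 = _optimize(
            bounded,
            bounded.biomass_reaction_id,
            "max",
            extra_bounds={
                bounded.biomass_reaction_id: (floor * (1.0 - 1e-6), np.inf)
            },
            minimize_total_flux=True,
        )
    if stage2.status != "optimal":
        return stage1, _extract_secretions(bounded, stage1)
    return stage2, _extract_secretions(bounded, stage2)


def secretion_cost(
    model: MetabolicModel,
    medium: Medium | None,
    metabolite: str,
    v_s: float,
    oxygen_override: bool | None = None,
) -> dict:
    """Force secretion of ``metabolite`` at rate ``v_s`` and re-maximize growth.

    Returns ``{"category", "growth_rate", "delta_growth", "baseline_growth"}``
    with category costless iff v_g,s >= v_g,0 within 1e-9 relative tolerance,
    beneficial iff strictly greater, costly otherwise, and "infeasible" when
    the forced secretion admits no steady state.
    """
    bounded = _bounded(model, medium, oxygen_override)
    exchange = bounded.exchange_for(metabolite)
    if exchange is None:
        raise ValueError(f"metabolite {metabolite!r} has no exchange reaction")
    baseline = _optimize(bounded, bounded.biomass_reaction_id, "max")
    if baseline.status != "optimal":
        return {
            "category": "infeasible",
            "growth_rate": 0.0,
            "delta_growth": 0.0,
            "baseline_growth": 0.0,
        }
    forced = _optimize(
        bounded,
        bounded.biomass_reaction_id,
        "max",
        extra_bounds={exchange.id: (v_s, v_s)},
    )
    if forced.status != "optimal":
        return {
            "category": "infeasible",
            "growth_rate": 0.0,
            "delta_growth": -baseline.growth_rate,
            "baseline_growth": baseline.growth_rate,
        }
    v_g0, v_gs = baseline.growth_rate, forced.growth_rate
    tol = GROWTH_SLACK_REL * max(1.0, abs(v_g0))
    if v_gs > v_g0 + tol:
        category = "beneficial"
    elif v_gs >= v_g0 - tol:
        category = "costless"
    else:
        category = "costly"
    return {
        "category": category,
        "growth_rate": v_gs,
        "delta_growth": v_gs - v_g0,
        "baseline_growth": v_g0,
    }


def solve_alternative_objective(
    model: MetabolicModel,
    medium: Medium | None = None,
    objective: Objective = "max_growth",
    oxygen_override: bool | None = None,
) -> tuple[FluxSolution, SecretionProfile]:
    """Optimize an alternative objective, then minimize total flux.

    Non-growth objectives require an ATP maintenance reaction and pin the
    biomass flux to at least 0.01/h. ``max_growth`` is exactly
    :func:`costless_secretions`.
    """
    if objective == "max_growth":
        return costless_secretions(model, medium, oxygen_override)
    bounded = _bounded(model, medium, oxygen_override)
    biomass = bounded.biomass_reaction_id
    growth_floor = {biomass: (ALT_OBJECTIVE_MIN_GROWTH, np.inf)}
    if objective == "min_biomass":
        obj_rxn, sense = biomass, "min"
    elif objective in ("max_atp", "min_atp"):
        if not bounded.atp_maintenance_reaction_id:
            raise ValueError(
                f"model {bounded.model_id!r} has no ATP maintenance reaction; "
                f"required for objective {objective!r}"
            )
        obj_rxn = bounded.atp_maintenance_reaction_id
        sense = "max" if objective == "max_atp" else "min"
    else:
        raise ValueError(f"unknown objective {objective!r}")

    stage1 = _optimize(bounded, obj_rxn, sense, extra_bounds=growth_floor)
    if stage1.status != "optimal":
        return stage1, SecretionProfile()
    opt = stage1.objective_value
    slack = GROWTH_SLACK_REL * max(1.0, abs(opt))
    stage2_bounds = dict(growth_floor)
    lo, hi = stage2_bounds.get(obj_rxn, (-np.inf, np.inf))
    if sense == "max":
        lo = max(lo, opt - slack)
    else:
        hi = min(hi, opt + slack)
    stage2_bounds[obj_rxn] = (lo, hi)
    stage2 = _optimize(
        bounded,
        obj_rxn,
        sense,
        extra_bounds=stage2_bounds,
        minimize_total_flux=True,
    )
    if stage2.status != "optimal":
        return stage1, _extract_secretions(bounded, stage1)
    return stage2, _extract_secretions(bounded, stage2)


def verify_secretion_uniqueness(
    model: MetabolicModel,
    medium: Medium | None = None,
    oxygen_override: bool | None = None,
) -> dict[str, bool]:
    """Exhaustive degeneracy probe for small models.

    For each reported costless secretion, re-solve with that secretion
    suppressed (exchange flux capped below the cutoff) at optimal growth;
    the secretion is unique (non-degenerate) iff the suppressed problem is
    infeasible. Intended for toy networks only.
    """
    bounded = _bounded(model, medium, oxygen_override)
    solution, profile = costless_secretions(bounded)
    if not solution.grows:
        return {}
    floor = _growth_floor(solution.growth_rate)
    out = {}
    for met in profile:
        exchange = bounded.exchange_for(met)
        probe = _optimize(
            bounded,
            bounded.biomass_reaction_id,
            "max",
            extra_bounds={
                bounded.biomass_reaction_id: (floor, np.inf),
                exchange.id: (-np.inf, SECRETION_CUTOFF / 2),
            },
        )
        out[met] = probe.status != "optimal"
    return out
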