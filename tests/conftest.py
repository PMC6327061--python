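"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from crossfeed.media import build_medium
from crossfeed.toyforge import ACSP_SPEC, FERM_SPEC, make_organism


@pytest.fixture
def ferm():
    return make_organism(FERM_SPEC)


@pytest.fixture
def acsp():
    return make_organism(ACSP_SPEC)


@pytest.fixture
def glc_medium_anoxic():
    return build_medium(base={"nh4_e"}, carbon_sources=("glc_e",), oxygen=False)


@pytest.fixture
def glc_medium_oxic():
    return build_medium(base={"nh4_e"}, carbon_sources=("glc_e",), oxygen=True)


def dense_lp_growth(model) -> float:
    """Independent brute-force growth LP: dense matrix, no flux splitting.

    Assembled metabolite-by-metabolite (row-major) rather than through the
    engine's sparse reaction-major construction, and solved with the dual
    simplex; used as an oracle for solve_growth on small networks.
    """
    n = len(model.reactions)
    m = len(model.metabolites)
    A = np.zeros((m, n))
    for i, met in enumerate(model.metabolites):
        for j, rxn in enumerate(model.reactions):
            A[i, j] = rxn.stoich.get(met.id, 0.0)
    c = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        if rxn.id == model.biomass_reaction_id:
            c[j] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(c, A_eq=A, b_eq=np.zeros(m), bounds=bounds, method="highs-ds")
    if res.status != 0:
        return 0.0
    return float(-res.fun)


def cobra_growth(model) -> float:
    """Second independent oracle: the same LP through cobra + GLPK."""
    from cobra import Metabolite, Model
    from cobra import Reaction as CobraReaction

    cm = Model(model.model_id)
    mets = {
        met.id: Metabolite(met.id, compartment="e" if met.external else "c")
        for met in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = CobraReaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({mets[k]: v for k, v in r.stoich.items()})
        rxns.append(cr)
    cm.add_reactions(rxns)
    cm.objective = model.biomass_reaction_id
    cm.solver = "glpk"
    sol = cm.optimize()
    if sol.status != "optimal":
        return 0.0
    return float(sol.objective_value)
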