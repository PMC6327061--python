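"""Synthetic fixture generator: small metabolic models with known answers.

Every generated network follows one template: external metabolites ``X_e``
are moved by exchange reactions ``EX_X_e`` (coefficient -1, secretion
positive) and reversible transporters ``t_X`` into internal pools ``X_c``;
ATP-producing pathways (fermentation, respiration, byproduct oxidation)
convert substrates; a single ``BIOMASS`` reaction drains substrate, ATP and
nitrogen; ``NGAM`` is an ordinary ATP-hydrolysis reaction with a minimum
flux. Stoichiometry is flux-consistent but deliberately not elementally
balanced.

The flagship organisms are hand-solvable:

* ``FERM`` -- facultative glucose user. Fermentation yields 2 ATP + 2 ac +
  2 co2 per glc; respiration yields 10 ATP + 6 co2 per glc; biomass takes
  1 glc + 2 ATP + 0.5 nh4. With glucose uptake capped at 10: anoxic growth
  5.0/h secreting acetate at 10.0; oxic growth 25/3 with no acetate.
* ``ACSP`` -- acetate specialist with no glucose transporter: 1 ATP + 1 co2
  per ac, biomass 1 ac + 1 ATP + 0.5 nh4; grows only once acetate appears.

``make_motif_pair`` emits organism pairs plus media engineered so that the
full pipeline recovers a requested interaction motif code exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .media import Medium, build_medium, write_medium_tsv
from .model_core import MetaboliteRef, MetabolicModel, Reaction, write_model

BIG = 1000.0

__all__ = [
    "Pathway",
    "ToyOrganismSpec",
    "GroundTruth",
    "make_organism",
    "make_motif_pair",
    "make_suite",
    "FERM_SPEC",
    "ACSP_SPEC",
    "MOTIF_PAIR_CODES",
]


@dataclass(frozen=True)
class Pathway:
    """Irreversible internal conversion, coefficients over internal pools."""

    rxn_id: str
    consumes: Mapping[str, float]
    produces: Mapping[str, float]


@dataclass(frozen=True)
class ToyOrganismSpec:
    organism_id: str
    transported: tuple[str, ...]          # external metabolites with transporters
    pathways: tuple[Pathway, ...]
    biomass: Mapping[str, float]          # internal pools consumed per unit growth
    ngam_min: float = 0.0
    extra_exchanges: tuple[str, ...] = () # exchange-only metabolites (no transporter)


@dataclass
class GroundTruth:
    """Hand-derived expectations, asserted by the test suite."""

    solo_growth: dict[str, bool] = field(default_factory=dict)
    final_growth: dict[str, bool] = field(default_factory=dict)
    expected_growth_rate: dict[str, float] = field(default_factory=dict)
    expected_secretions: dict[str, set[str]] = field(default_factory=dict)
    expected_motif: str = ""
    expected_obligate: dict[str, bool] = field(default_factory=dict)
    derivation: str = ""

    def to_json(self) -> dict:
        return {
            "solo_growth": self.solo_growth,
            "final_growth": self.final_growth,
            "expected_growth_rate": self.expected_growth_rate,
            "expected_secretions": {k: sorted(v) for k, v in self.expected_secretions.items()},
            "expected_motif": self.expected_motif,
            "expected_obligate": self.expected_obligate,
            "derivation": self.derivation,
        }


def make_organism(spec: ToyOrganismSpec, seed: int = 0) -> MetabolicModel:
    """Build a model from a spec. The spec fully determines the model; the
    seed argument exists for interface symmetry and is ignored."""
    del seed
    internal_pools: set[str] = set()
    for pw in spec.pathways:
        internal_pools |= set(pw.consumes) | set(pw.produces)
    internal_pools |= set(spec.biomass)

    transported_pools = {f"{m}_c" for m in spec.transported}
    producible = transported_pools | {
        pool for pw in spec.pathways for pool in pw.produces
    }
    consumed = set(spec.biomass) | {
        pool for pw in spec.pathways for pool in pw.consumes
    }
    unsourced = consumed - producible
    if unsourced:
        raise ValueError(
            f"{spec.organism_id}: consumed pools with no transporter or "
            f"producing pathway: {sorted(unsourced)}"
        )
    metabolites: list[MetaboliteRef] = []
    for m in spec.transported:
        metabolites.append(MetaboliteRef(id=f"{m}_e", external=True))
    for m in spec.extra_exchanges:
        metabolites.append(MetaboliteRef(id=f"{m}_e", external=True))
    for pool in sorted(internal_pools | transported_pools):
        metabolites.append(MetaboliteRef(id=pool, external=False))

    declared = {m.id for m in metabolites}
    for pw in spec.pathways:
        missing = (set(pw.consumes) | set(pw.produces)) - declared
        if missing:
            raise ValueError(
                f"{spec.organism_id}: pathway {pw.rxn_id} uses undeclared pools {missing}"
            )
    missing = set(spec.biomass) - declared
    if missing:
        raise ValueError(f"{spec.organism_id}: biomass uses undeclared pools {missing}")

    reactions: list[Reaction] = []
    for m in spec.transported + spec.extra_exchanges:
        reactions.append(
            Reaction(
                id=f"EX_{m}_e",
                stoich={f"{m}_e": -1.0},
                lower_bound=-BIG,
                upper_bound=BIG,
                is_exchange=True,
            )
        )
    for m in spec.transported:
        reactions.append(
            Reaction(
                id=f"t_{m}",
                stoich={f"{m}_e": -1.0, f"{m}_c": 1.0},
                lower_bound=-BIG,
                upper_bound=BIG,
            )
        )
    for pw in spec.pathways:
        stoich = {k: -v for k, v in pw.consumes.items()}
        for k, v in pw.produces.items():
            stoich[k] = stoich.get(k, 0.0) + v
        reactions.append(
            Reaction(id=pw.rxn_id, stoich=stoich, lower_bound=0.0, upper_bound=BIG)
        )
    reactions.append(
        Reaction(
            id="BIOMASS",
            stoich={k: -v for k, v in spec.biomass.items()},
            lower_bound=0.0,
            upper_bound=BIG,
        )
    )
    atpm_id = ""
    if "atp" in internal_pools:
        atpm_id = "NGAM"
        reactions.append(
            Reaction(
                id="NGAM",
                stoich={"atp": -1.0},
                lower_bound=spec.ngam_min,
                upper_bound=BIG,
            )
        )
    return MetabolicModel(
        model_id=spec.organism_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
        atp_maintenance_reaction_id=atpm_id,
    )


# ---------------------------------------------------------------------------
# named organisms


def _ferm_pathways(substrate: str) -> tuple[Pathway, Pathway]:
    return (
        Pathway(
            f"FERM_{substrate}",
            consumes={f"{substrate}_c": 1.0},
            produces={"ac_c": 2.0, "co2_c": 2.0, "atp": 2.0},
        ),
        Pathway(
            f"RESP_{substrate}",
            consumes={f"{substrate}_c": 1.0, "o2_c": 6.0},
            produces={"co2_c": 6.0, "atp": 10.0},
        ),
    )


FERM_SPEC = ToyOrganismSpec(
    organism_id="FERM",
    transported=("glc", "ac", "co2", "nh4", "o2"),
    pathways=_ferm_pathways("glc"),
    biomass={"glc_c": 1.0, "atp": 2.0, "nh4_c": 0.5},
    extra_exchanges=("pi",),
)

ACSP_SPEC = ToyOrganismSpec(
    organism_id="ACSP",
    transported=("ac", "co2", "nh4"),
    pathways=(
        Pathway("ACOX", consumes={"ac_c": 1.0}, produces={"co2_c": 1.0, "atp": 1.0}),
    ),
    biomass={"ac_c": 1.0, "atp": 1.0, "nh4_c": 0.5},
)


def _respirer(organism_id: str, substrate: str) -> ToyOrganismSpec:
    return ToyOrganismSpec(
        organism_id=organism_id,
        transported=(substrate, "co2", "nh4", "o2"),
        pathways=(
            Pathway(
                f"RESP_{substrate}",
                consumes={f"{substrate}_c": 1.0, "o2_c": 6.0},
                produces={"co2_c": 6.0, "atp": 10.0},
            ),
        ),
        biomass={f"{substrate}_c": 1.0, "atp": 2.0, "nh4_c": 0.5},
    )


GENA_SPEC = ToyOrganismSpec(
    # anaerobic generalist: ferments glucose, oxidizes acetate
    organism_id="GENA",
    transported=("glc", "ac", "co2", "nh4"),
    pathways=(
        Pathway(
            "FERM_glc",
            consumes={"glc_c": 1.0},
            produces={"ac_c": 2.0, "co2_c": 2.0, "atp": 2.0},
        ),
        Pathway("ACOX", consumes={"ac_c": 1.0}, produces={"co2_c": 1.0, "atp": 2.0}),
    ),
    biomass={"glc_c": 1.0, "atp": 2.0, "nh4_c": 0.5},
)

XGEN_SPEC = ToyOrganismSpec(
    # anaerobic xylose fermenter needing both carbons for biomass, eats acetate
    organism_id="XGEN",
    transported=("glc", "xyl", "ac", "co2", "nh4"),
    pathways=(
        Pathway(
            "FERM_xyl",
            consumes={"xyl_c": 1.0},
            produces={"ac_c": 2.0, "co2_c": 2.0, "atp": 2.0},
        ),
        Pathway("ACOX", consumes={"ac_c": 1.0}, produces={"co2_c": 1.0, "atp": 2.0}),
    ),
    biomass={"glc_c": 0.5, "xyl_c": 0.5, "atp": 2.0, "nh4_c": 0.5},
)

NREG_SPEC = ToyOrganismSpec(
    # nitrogen regenerator: deaminating energy route releases surplus ammonium
    organism_id="NREG",
    transported=("glc", "aa", "ac", "co2", "nh4"),
    pathways=(
        Pathway(
            "DEAM",
            consumes={"glc_c": 1.0, "aa_c": 1.0},
            produces={"atp": 2.0, "nh4_c": 1.0},
        ),
        Pathway("ACOX", consumes={"ac_c": 1.0}, produces={"co2_c": 1.0, "atp": 2.0}),
    ),
    biomass={"glc_c": 1.0, "atp": 2.0, "nh4_c": 0.2},
)

NREGX_SPEC = ToyOrganismSpec(
    organism_id="NREGX",
    transported=("xyl", "aa", "ac", "co2", "nh4"),
    pathways=(
        Pathway(
            "DEAM",
            consumes={"xyl_c": 1.0, "aa_c": 1.0},
            produces={"atp": 2.0, "nh4_c": 1.0},
        ),
        Pathway("ACOX", consumes={"ac_c": 1.0}, produces={"co2_c": 1.0, "atp": 2.0}),
    ),
    biomass={"xyl_c": 1.0, "atp": 2.0, "nh4_c": 0.2},
)

RESPAB_SPEC = ToyOrganismSpec(
    # respires xylose but needs both glucose and xylose as biomass substrates
    organism_id="RESPAB",
    transported=("glc", "xyl", "co2", "nh4", "o2"),
    pathways=(
        Pathway(
            "RESP_xyl",
            consumes={"xyl_c": 1.0, "o2_c": 6.0},
            produces={"co2_c": 6.0, "atp": 10.0},
        ),
    ),
    biomass={"glc_c": 0.5, "xyl_c": 0.5, "atp": 2.0, "nh4_c": 0.5},
)


# ---------------------------------------------------------------------------
# motif pairs


MOTIF_PAIR_CODES = ("N1b", "N2a", "N2b", "C1a", "C1b", "C2b", "M1b", "M2a")


def make_motif_pair(
    motif_code: str,
) -> tuple[MetabolicModel, MetabolicModel, Medium, GroundTruth]:
    """Organism pair + medium whose pipeline outcome is the requested motif."""
    if motif_code == "C1a":
        m1, m2 = make_organism(FERM_SPEC), make_organism(ACSP_SPEC)
        medium = build_medium(base={"nh4_e"}, carbon_sources=("glc_e",), oxygen=False)
        gt = GroundTruth(
            solo_growth={"FERM": True, "ACSP": False},
            final_growth={"FERM": True, "ACSP": True},
            expected_growth_rate={"FERM": 5.0, "ACSP": 5.0},
            expected_secretions={"FERM": {"ac_e", "co2_e"}, "ACSP": {"co2_e"}},
            expected_motif="C1a",
            expected_obligate={"FERM": False, "ACSP": True},
            derivation=(
                "FERM anoxic: glc split v+f<=10, ATP 2f=2v => v=f=5, ac=co2=10. "
                "ACSP on crossfed ac<=10: b+p=10, p>=b => growth 5, co2=5."
            ),
        )
    elif motif_code == "N1b":
        m1 = make_organism(_respirer("RESP1", "glc"))
        m2 = make_organism(_respirer("RESP2", "glc"))
        medium = build_medium(base={"nh4_e"}, carbon_sources=("glc_e",), oxygen=True)
        gt = GroundTruth(
            solo_growth={"RESP1": True, "RESP2": True},
            final_growth={"RESP1": True, "RESP2": True},
            expected_growth_rate={"RESP1": 25.0 / 3.0, "RESP2": 25.0 / 3.0},
            expected_secretions={"RESP1": {"co2_e"}, "RESP2": {"co2_e"}},
            expected_motif="N1b",
            expected_obligate={"RESP1": False, "RESP2": False},
            derivation="pure respirers: 1.2v<=10 => v=25/3; CO2 secreted, never taken up.",
        )
    elif motif_code == "N2a":
        m1 = make_organism(_respirer("RESPA", "glc"))
        m2 = make_organism(_respirer("RESPB", "xyl"))
        medium = build_medium(
            base={"nh4_e"}, carbon_sources=("glc_e", "xyl_e"), oxygen=True
        )
        gt = GroundTruth(
            solo_growth={"RESPA": True, "RESPB": True},
            final_growth={"RESPA": True, "RESPB": True},
            expected_growth_rate={"RESPA": 25.0 / 3.0, "RESPB": 25.0 / 3.0},
            expected_secretions={"RESPA": {"co2_e"}, "RESPB": {"co2_e"}},
            expected_motif="N2a",
            expected_obligate={"RESPA": False, "RESPB": False},
            derivation="disjoint substrates, no exchange: orthogonal respirers.",
        )
    elif motif_code == "N2b":
        m1 = make_organism(_respirer("RESP1", "glc"))
        m2 = make_organism(RESPAB_SPEC)
        medium = build_medium(
            base={"nh4_e"}, carbon_sources=("glc_e", "xyl_e"), oxygen=True
        )
        gt = GroundTruth(
            solo_growth={"RESP1": True, "RESPAB": True},
            final_growth={"RESP1": True, "RESPAB": True},
            expected_growth_rate={"RESP1": 25.0 / 3.0, "RESPAB": 100.0 / 7.0},
            expected_secretions={"RESP1": {"co2_e"}, "RESPAB": {"co2_e"}},
            expected_motif="N2b",
            expected_obligate={"RESP1": False, "RESPAB": False},
            derivation=(
                "RESPAB: xyl = 0.5v + 0.2v <= 10 => v=100/7, consumes glc 0.5v; "
                "shares glc with RESP1, no exchanged metabolites."
            ),
        )
    elif motif_code == "C1b":
        m1, m2 = make_organism(FERM_SPEC), make_organism(GENA_SPEC)
        medium = build_medium(base={"nh4_e"}, carbon_sources=("glc_e",), oxygen=False)
        gt = GroundTruth(
            solo_growth={"FERM": True, "GENA": True},
            final_growth={"FERM": True, "GENA": True},
            expected_growth_rate={"FERM": 5.0, "GENA": 10.0},
            expected_secretions={"FERM": {"ac_e", "co2_e"}},
            expected_motif="C1b",
            expected_obligate={"FERM": False, "GENA": False},
            derivation=(
                "final GENA: glc all to biomass (v=10), ATP from crossfed ac (10); "
                "ac flows FERM->GENA while both consume glc."
            ),
        )
    elif motif_code == "C2b":
        m1, m2 = make_organism(FERM_SPEC), make_organism(XGEN_SPEC)
        medium = build_medium(
            base={"nh4_e"}, carbon_sources=("glc_e", "xyl_e"), oxygen=False
        )
        gt = GroundTruth(
            solo_growth={"FERM": True, "XGEN": True},
            final_growth={"FERM": True, "XGEN": True},
            expected_growth_rate={"FERM": 5.0, "XGEN": 16.0},
            expected_secretions={"FERM": {"ac_e", "co2_e"}},
            expected_motif="C2b",
            expected_obligate={"FERM": False, "XGEN": False},
            derivation=(
                "XGEN final: u_ac=v-3f<=10, xyl 0.5v+f<=10 => v=16; consumes glc, "
                "xyl and FERM's acetate; glc shared => competition."
            ),
        )
    elif motif_code == "M1b":
        m1, m2 = make_organism(FERM_SPEC), make_organism(NREG_SPEC)
        medium = build_medium(base={"aa_e"}, carbon_sources=("glc_e",), oxygen=False)
        gt = GroundTruth(
            solo_growth={"FERM": False, "NREG": True},
            final_growth={"FERM": True, "NREG": True},
            expected_growth_rate={"FERM": 5.0, "NREG": 10.0},
            expected_secretions={"FERM": {"ac_e", "co2_e"}, "NREG": {"nh4_e", "co2_e"}},
            expected_motif="M1b",
            expected_obligate={"FERM": True, "NREG": False},
            derivation=(
                "no nh4 in base: FERM waits for NREG's surplus ammonium "
                "(DEAM yields 1 nh4 per 2 ATP, biomass uses 0.2); at the final "
                "iteration NREG's growth is glc-limited so ATP must come from "
                "FERM's acetate. Reciprocal ac/nh4 edges over shared glucose."
            ),
        )
    elif motif_code == "M2a":
        m1, m2 = make_organism(FERM_SPEC), make_organism(NREGX_SPEC)
        medium = build_medium(
            base={"aa_e"}, carbon_sources=("glc_e", "xyl_e"), oxygen=False
        )
        gt = GroundTruth(
            solo_growth={"FERM": False, "NREGX": True},
            final_growth={"FERM": True, "NREGX": True},
            expected_growth_rate={"FERM": 5.0, "NREGX": 10.0},
            expected_secretions={"FERM": {"ac_e", "co2_e"}, "NREGX": {"nh4_e", "co2_e"}},
            expected_motif="M2a",
            expected_obligate={"FERM": True, "NREGX": False},
            derivation=(
                "as M1b but NREGX lives on xylose: disjoint primary carbons, "
                "reciprocal ac/nh4 exchange."
            ),
        )
    else:
        raise ValueError(
            f"motif code {motif_code!r} is unknown or not constructible; "
            f"available: {MOTIF_PAIR_CODES}"
        )
    return m1, m2, medium, gt


# ---------------------------------------------------------------------------
# randomized suites


_BYPRODUCTS = ("ac", "lac", "etoh", "form")


def _suite_organism(
    index: int,
    carbons: Sequence[str],
    rng: np.random.Generator,
    n_organisms: int,
) -> ToyOrganismSpec:
    n_carbons = len(carbons)
    # guaranteed coverage: organism i ferments every carbon k with k % n == i
    assigned = [k for k in range(n_carbons) if k % n_organisms == index]
    extra = [
        k
        for k in range(n_carbons)
        if k not in assigned and rng.random() < 0.25
    ]
    substrates = sorted(assigned + extra)[:4]

    pathways: list[Pathway] = []
    transported: set[str] = {"co2", "nh4"}
    uses_o2 = False
    for k in substrates:
        sub = carbons[k]
        transported.add(sub)
        pathways.append(
            Pathway(f"ASSIM_{sub}", consumes={f"{sub}_c": 1.0}, produces={"cint_c": 1.0})
        )
        guaranteed = k in assigned
        if guaranteed or rng.random() < 0.7:
            bp = _BYPRODUCTS[int(rng.integers(len(_BYPRODUCTS)))]
            transported.add(bp)
            pathways.append(
                Pathway(
                    f"FERM_{sub}",
                    consumes={f"{sub}_c": 1.0},
                    produces={"atp": 2.0, f"{bp}_c": 2.0, "co2_c": 1.0},
                )
            )
        if rng.random() < 0.5:
            uses_o2 = True
            pathways.append(
                Pathway(
                    f"RESP_{sub}",
                    consumes={f"{sub}_c": 1.0, "o2_c": 6.0},
                    produces={"co2_c": 6.0, "atp": 10.0},
                )
            )
    produced = {
        pool[:-2]
        for pw in pathways
        for pool in pw.produces
        if pool.endswith("_c") and pool[:-2] in _BYPRODUCTS
    }
    candidates = [b for b in _BYPRODUCTS if b not in produced]
    if candidates and rng.random() < 0.6:
        bp = candidates[int(rng.integers(len(candidates)))]
        transported.add(bp)
        pathways.append(
            Pathway(
                f"OX_{bp}", consumes={f"{bp}_c": 1.0}, produces={"co2_c": 1.0, "atp": 2.0}
            )
        )
    if uses_o2:
        transported.add("o2")
    return ToyOrganismSpec(
        organism_id=f"ORG{index:02d}",
        transported=tuple(sorted(transported)),
        pathways=tuple(pathways),
        biomass={"cint_c": 1.0, "atp": 2.0, "nh4_c": 0.5},
    )


def make_suite(
    n_organisms: int,
    n_carbons: int,
    seed: int = 0,
) -> tuple[list[MetabolicModel], Medium, list[str]]:
    """Seeded random organism collection with >=1 anaerobic grower per carbon.

    Returns (models, base medium with placeholder carbon pair, carbon list).
    The returned medium carries the base composition; sweep planning swaps in
    actual carbon pairs.
    """
    if n_organisms < 2:
        raise ValueError("need at least 2 organisms")
    rng = np.random.default_rng(seed)
    carbons = [f"carb{k}" for k in range(n_carbons)]
    models = [
        make_organism(_suite_organism(i, carbons, rng, n_organisms))
        for i in range(n_organisms)
    ]
    carbon_ids = [f"{c}_e" for c in carbons]
    medium = build_medium(
        base={"nh4_e"}, carbon_sources=tuple(carbon_ids[:2]), oxygen=False
    )
    return models, medium, carbon_ids


def emit_suite(
    out_dir: str | Path, n_organisms: int, n_carbons: int, seed: int = 0
) -> dict:
    """Write a suite to disk: toy_json models, media TSV, carbon list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models, medium, carbon_ids = make_suite(n_organisms, n_carbons, seed)
    model_dir = out_dir / "models"
    model_dir.mkdir(exist_ok=True)
    paths = []
    for model in models:
        p = model_dir / f"{model.model_id}.json"
        write_model(model, p, format="toy_json")
        paths.append(str(p))
    write_medium_tsv(medium, out_dir / "medium.tsv")
    (out_dir / "carbons.txt").write_text("".join(c + "\n" for c in carbon_ids))
    manifest = {
        "models": paths,
        "medium": str(out_dir / "medium.tsv"),
        "carbons": str(out_dir / "carbons.txt"),
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
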