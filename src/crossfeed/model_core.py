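"""Constraint-based metabolic network data model and readers/writers.

A :class:`MetabolicModel` is a plain stoichiometric description: an ordered
metabolite list, an ordered reaction list with flux bounds, one flagged
biomass reaction, and (optionally) an ATP maintenance reaction. Compartments
are reduced to internal/external; exchange reactions are boundary reactions
touching exactly one external metabolite with coefficient -1, under the sign
convention *positive exchange flux = secretion, negative = uptake*.

Two on-disk formats are supported:

* ``toy_json`` -- the reference dialect (documented below), used by the
  synthetic-model generator.
* ``sbml`` -- SBML Level 3 with flux bounds encoded as parameters, read and
  written through libsbml.

``toy_json`` dialect (version 1)::

    {
      "format_version": 1,
      "id": "FERM",
      "metabolites": [{"id": "glc_e", "external": true, "name": "..."}, ...],
      "reactions":   [{"id": "EX_glc_e", "stoich": {"glc_e": -1.0},
                       "lb": -1000.0, "ub": 1000.0, "exchange": true}, ...],
      "biomass": "BIOMASS",
      "atp_maintenance": "NGAM"          # optional
    }
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0

__all__ = [
    "MetaboliteRef",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "NamespaceError",
    "read_model",
    "write_model",
    "harmonize",
]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class NamespaceError(ValueError):
    """Raised when a namespace map cannot be applied."""


@dataclass(frozen=True)
class MetaboliteRef:
    id: str
    external: bool = False
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False

    @property
    def exchanged_metabolite(self) -> str:
        """External metabolite moved by this exchange reaction ('' if none)."""
        if not self.is_exchange:
            return ""
        return next(iter(self.stoich))

    def reversed_sign(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """Stoichiometric model: S, bounds, biomass, exchanges."""

    model_id: str
    metabolites: list[MetaboliteRef]
    reactions: list[Reaction]
    biomass_reaction_id: str
    atp_maintenance_reaction_id: str = ""
    _met_index: dict[str, int] = field(default_factory=dict, repr=False)
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()
        self.validate()

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ----------------------------------------------------------

    def metabolite(self, met_id: str) -> MetaboliteRef:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def external_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites if m.external]

    def exchange_for(self, met_id: str) -> Reaction | None:
        """Exchange reaction moving the external metabolite, if any."""
        for r in self.reactions:
            if r.is_exchange and r.exchanged_metabolite == met_id:
                return r
        return None

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if not self.reactions:
            raise ModelValidationError(f"model {self.model_id!r} has no reactions")
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        if not self.biomass_reaction_id:
            raise ModelValidationError(f"model {self.model_id!r}: no biomass reaction")
        if self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        if (
            self.atp_maintenance_reaction_id
            and self.atp_maintenance_reaction_id not in self._rxn_index
        ):
            raise ModelValidationError(
                f"ATP maintenance reaction {self.atp_maintenance_reaction_id!r} not in model"
            )
        for rxn in self.reactions:
            for met_id in rxn.stoich:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            if rxn.is_exchange:
                ext = [m for m in rxn.stoich if self.metabolite(m).external]
                if len(rxn.stoich) != 1 or len(ext) != 1:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id!r} must touch exactly one "
                        f"external metabolite"
                    )
                coeff = rxn.stoich[ext[0]]
                if not math.isclose(coeff, -1.0):
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id!r} must carry coefficient -1 "
                        f"on {ext[0]!r} (secretion-positive convention), got {coeff}"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
            atp_maintenance_reaction_id=self.atp_maintenance_reaction_id,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with the listed reactions re-bounded."""
        new_rxns = []
        for r in self.reactions:
            if r.id in bounds:
                lb, ub = bounds[r.id]
                new_rxns.append(replace(r, lower_bound=lb, upper_bound=ub))
            else:
                new_rxns.append(r)
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=new_rxns,
            biomass_reaction_id=self.biomass_reaction_id,
            atp_maintenance_reaction_id=self.atp_maintenance_reaction_id,
        )


def _detect_exchanges(
    metabolites: Sequence[MetaboliteRef], reactions: Sequence[Reaction]
) -> list[Reaction]:
    """Auto-flag boundary reactions by the single-external-metabolite rule."""
    external = {m.id for m in metabolites if m.external}
    out = []
    for r in reactions:
        if r.is_exchange:
            out.append(r)
            continue
        if len(r.stoich) == 1:
            (met_id, coeff), = r.stoich.items()
            if met_id in external and math.isclose(coeff, -1.0):
                r = replace(r, is_exchange=True)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# toy_json


def _model_to_dict(model: MetabolicModel) -> dict:
    doc = {
        "format_version": 1,
        "id": model.model_id,
        "metabolites": [
            {"id": m.id, "external": m.external, **({"name": m.name} if m.name else {})}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoich),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
    }
    if model.atp_maintenance_reaction_id:
        doc["atp_maintenance"] = model.atp_maintenance_reaction_id
    return doc


def _model_from_dict(doc: Mapping) -> MetabolicModel:
    metabolites = [
        MetaboliteRef(
            id=m["id"], external=bool(m.get("external", False)), name=m.get("name", "")
        )
        for m in doc.get("metabolites", [])
    ]
    reactions = [
        Reaction(
            id=r["id"],
            stoich={k: float(v) for k, v in r["stoich"].items()},
            lower_bound=float(r.get("lb", -DEFAULT_BOUND)),
            upper_bound=float(r.get("ub", DEFAULT_BOUND)),
            is_exchange=bool(r.get("exchange", False)),
        )
        for r in doc.get("reactions", [])
    ]
    reactions = _detect_exchanges(metabolites, reactions)
    return MetabolicModel(
        model_id=doc.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=doc.get("biomass", ""),
        atp_maintenance_reaction_id=doc.get("atp_maintenance", ""),
    )


# ---------------------------------------------------------------------------
# SBML (Level 3, flux bounds as parameters)

_SBML_EXTERNAL_COMPARTMENT = "e"
_SBML_INTERNAL_COMPARTMENT = "c"


def _sbml_sid(raw: str) -> str:
    """Escape an id into a valid SBML SId."""
    out = []
    for ch in raw:
        out.append(ch if ch.isalnum() or ch == "_" else "__")
    sid = "".join(out)
    if sid and sid[0].isdigit():
        sid = "_" + sid
    return sid


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    doc = libsbml.SBMLDocument(ns)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_sid(model.model_id))
    sbml_model.setName(model.model_id)

    for comp_id in (_SBML_INTERNAL_COMPARTMENT, _SBML_EXTERNAL_COMPARTMENT):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    met_sid: dict[str, str] = {}
    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sid = "M_" + _sbml_sid(met.id)
        met_sid[met.id] = sid
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(
            _SBML_EXTERNAL_COMPARTMENT if met.external else _SBML_INTERNAL_COMPARTMENT
        )
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    def add_parameter(pid: str, value: float) -> None:
        p = sbml_model.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)

    for i, rxn in enumerate(model.reactions):
        rx = sbml_model.createReaction()
        rid = "R_" + _sbml_sid(rxn.id)
        rx.setId(rid)
        rx.setName(rxn.id)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        for met_id, coeff in rxn.stoich.items():
            if coeff < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(met_sid[met_id])
            ref.setConstant(True)
        lb_id, ub_id = f"lb_{i}", f"ub_{i}"
        add_parameter(lb_id, rxn.lower_bound)
        add_parameter(ub_id, rxn.upper_bound)
        kl = rx.createKineticLaw()
        # flux bounds carried as local annotation-free parameters referenced
        # through the kinetic law notes (fbc-free L3 core encoding)
        kl.setMath(libsbml.parseL3Formula(f"{lb_id} + {ub_id} * 0"))
        rx.appendNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>LOWER_BOUND: {rxn.lower_bound!r}</p>"
            f"<p>UPPER_BOUND: {rxn.upper_bound!r}</p>"
            f"<p>EXCHANGE: {int(rxn.is_exchange)}</p>"
            f"<p>SOURCE_ID: {rxn.id}</p>"
            f"</body>"
        )

    sbml_model.appendNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>BIOMASS: {model.biomass_reaction_id}</p>"
        f"<p>ATP_MAINTENANCE: {model.atp_maintenance_reaction_id}</p>"
        f"</body>"
    )

    # metabolite source ids preserved in species notes
    for met in model.metabolites:
        sp = sbml_model.getSpecies(met_sid[met.id])
        sp.appendNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>SOURCE_ID: {met.id}</p>"
            f"</body>"
        )

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def _notes_fields(notes_str: str) -> dict[str, str]:
    fields = {}
    for line in notes_str.splitlines():
        line = line.strip()
        if line.startswith("<p>") and line.endswith("</p>") and ":" in line:
            body = line[3:-4]
            key, _, value = body.partition(":")
            fields[key.strip()] = value.strip()
    return fields


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelValidationError(f"SBML parse failure in {path}: {msgs}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"SBML file {path} contains no model")

    sid_to_source: dict[str, str] = {}
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fields = _notes_fields(sp.getNotesString() or "")
        source_id = fields.get("SOURCE_ID", sp.getId())
        sid_to_source[sp.getId()] = source_id
        metabolites.append(
            MetaboliteRef(
                id=source_id,
                external=sp.getCompartment() == _SBML_EXTERNAL_COMPARTMENT,
                name=sp.getName() if sp.getName() != source_id else "",
            )
        )

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        fields = _notes_fields(rx.getNotesString() or "")
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[sid_to_source[ref.getSpecies()]] = (
                stoich.get(sid_to_source[ref.getSpecies()], 0.0) - ref.getStoichiometry()
            )
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[sid_to_source[ref.getSpecies()]] = (
                stoich.get(sid_to_source[ref.getSpecies()], 0.0) + ref.getStoichiometry()
            )
        lb = float(fields.get("LOWER_BOUND", -DEFAULT_BOUND))
        ub = float(fields.get("UPPER_BOUND", DEFAULT_BOUND))
        reactions.append(
            Reaction(
                id=fields.get("SOURCE_ID", rx.getId()),
                stoich=stoich,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=bool(int(fields.get("EXCHANGE", "0"))),
            )
        )

    model_fields = _notes_fields(sbml_model.getNotesString() or "")
    reactions = _detect_exchanges(metabolites, reactions)
    return MetabolicModel(
        model_id=sbml_model.getName() or sbml_model.getId(),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=model_fields.get("BIOMASS", ""),
        atp_maintenance_reaction_id=model_fields.get("ATP_MAINTENANCE", ""),
    )


# ---------------------------------------------------------------------------
# public I/O


def read_model(path: str | Path, format: str = "toy_json") -> MetabolicModel:
    """Read a validated model from ``path`` in ``toy_json`` or ``sbml`` format."""
    path = Path(path)
    if format == "toy_json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(f"cannot parse {path}: {exc}") from exc
        return _model_from_dict(doc)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str = "toy_json") -> Path:
    """Write ``model`` so that :func:`read_model` round-trips it exactly."""
    model.validate()
    path = Path(path)
    if format == "toy_json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1)
            fh.write("\n")
        return path
    if format == "sbml":
        _write_sbml(model, path)
        return path
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# namespace harmonization


def harmonize(
    models: Iterable[MetabolicModel],
    namespace_map: Mapping[str, str],
    strict: bool = True,
) -> list[MetabolicModel]:
    """Rename external metabolites to canonical ids shared across models.

    ``namespace_map`` maps model-local external metabolite ids to canonical
    ids. With ``strict=True`` every external metabolite of every model must be
    covered; otherwise unmapped ids pass through unchanged with a warning.
    A map that sends two local ids of one model onto the same canonical id is
    rejected ("duplicate canonical exchange").
    """
    out = []
    for model in models:
        unmapped = [m for m in model.external_metabolites if m not in namespace_map]
        if unmapped and strict:
            raise NamespaceError(
                f"model {model.model_id!r}: unmapped external metabolites {unmapped}"
            )
        if unmapped:
            logger.warning(
                "model %s: external metabolites pass through unmapped: %s",
                model.model_id,
                unmapped,
            )
        rename = {
            m: namespace_map.get(m, m) for m in model.external_metabolites
        }
        canonical = list(rename.values())
        dupes = {c for c in canonical if canonical.count(c) > 1}
        if dupes:
            raise NamespaceError(
                f"model {model.model_id!r}: duplicate canonical exchange ids {sorted(dupes)}"
            )
        new_mets = [
            replace(m, id=rename[m.id]) if m.external else m for m in model.metabolites
        ]
        new_rxns = [
            replace(r, stoich={rename.get(k, k): v for k, v in r.stoich.items()})
            for r in model.reactions
        ]
        out.append(
            MetabolicModel(
                model_id=model.model_id,
                metabolites=new_mets,
                reactions=new_rxns,
                biomass_reaction_id=model.biomass_reaction_id,
                atp_maintenance_reaction_id=model.atp_maintenance_reaction_id,
            )
        )
    return out
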