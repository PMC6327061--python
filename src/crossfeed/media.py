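"""Growth media: construction, application as exchange bounds, and expansion.

A :class:`Medium` is a set description, not a concentration vector: base
(non-limiting) metabolites, growth-limiting carbon sources, an oxygen flag,
and metabolites accumulated through cross-feeding expansion. Applying a
medium to a model opens the uptake direction of the matching exchange
reactions (1000 mmol/gDW/h for base metabolites and oxygen, 10 for carbon
sources, a configurable bound -- default 10 -- for cross-fed metabolites)
and zeroes uptake of everything else; the secretion direction of every
exchange is left open.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

OXYGEN_ID = "o2_e"

CARBON_UPTAKE_MAX = 10.0
NONLIMITING_UPTAKE_MAX = 1000.0
SECRETION_MAX = 1000.0

__all__ = [
    "Medium",
    "BoundPolicy",
    "build_medium",
    "apply_medium",
    "expand_medium",
    "read_medium_tsv",
    "write_medium_tsv",
    "read_carbon_list",
    "OXYGEN_ID",
]


@dataclass(frozen=True)
class BoundPolicy:
    carbon_uptake_max: float = CARBON_UPTAKE_MAX
    nonlimiting_uptake_max: float = NONLIMITING_UPTAKE_MAX
    crossfed_uptake_max: float = CARBON_UPTAKE_MAX


@dataclass(frozen=True)
class Medium:
    base_metabolites: frozenset[str]
    carbon_sources: tuple[str, ...]
    oxygen: bool
    crossfed_metabolites: frozenset[str] = frozenset()
    bound_policy: BoundPolicy = BoundPolicy()
    oxygen_id: str = OXYGEN_ID

    @property
    def all_metabolites(self) -> frozenset[str]:
        mets = set(self.base_metabolites) | set(self.carbon_sources) | set(
            self.crossfed_metabolites
        )
        if self.oxygen:
            mets.add(self.oxygen_id)
        return frozenset(mets)

    def contains(self, met_id: str) -> bool:
        return met_id in self.all_metabolites


def build_medium(
    base: Iterable[str],
    carbon_sources: Sequence[str],
    oxygen: bool,
    bound_policy: BoundPolicy | None = None,
    oxygen_id: str = OXYGEN_ID,
) -> Medium:
    """Construct the initial medium M_0 (no cross-fed metabolites yet)."""
    base = frozenset(base)
    carbons = tuple(carbon_sources)
    if len(carbons) < 1:
        raise ValueError("at least one carbon source is required")
    if len(set(carbons)) != len(carbons):
        dupes = sorted({c for c in carbons if carbons.count(c) > 1})
        raise ValueError(f"duplicate carbon source(s): {dupes}")
    overlap = base & set(carbons)
    if overlap:
        raise ValueError(f"carbon source(s) also listed as base metabolites: {sorted(overlap)}")
    return Medium(
        base_metabolites=base,
        carbon_sources=carbons,
        oxygen=oxygen,
        bound_policy=bound_policy or BoundPolicy(),
        oxygen_id=oxygen_id,
    )


def apply_medium(
    model: MetabolicModel,
    medium: Medium,
    oxygen_override: bool | None = None,
) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set by ``medium``.

    ``oxygen_override`` replaces the medium's oxygen flag for this organism,
    enabling hybrid oxic--anoxic co-simulations. A medium metabolite without
    a matching exchange reaction is logged and skipped: the organism simply
    cannot take it up.
    """
    oxygen = medium.oxygen if oxygen_override is None else oxygen_override
    policy = medium.bound_policy

    uptake: dict[str, float] = {}
    for met in medium.base_metabolites:
        uptake[met] = policy.nonlimiting_uptake_max
    for met in medium.carbon_sources:
        uptake[met] = policy.carbon_uptake_max
    for met in medium.crossfed_metabolites:
        uptake.setdefault(met, policy.crossfed_uptake_max)
    if oxygen:
        uptake[medium.oxygen_id] = policy.nonlimiting_uptake_max
    else:
        uptake.pop(medium.oxygen_id, None)

    exchange_by_met = {r.exchanged_metabolite: r for r in model.exchange_reactions}
    missing = [m for m in uptake if m not in exchange_by_met]
    if missing:
        logger.info(
            "model %s has no exchange for medium metabolite(s) %s",
            model.model_id,
            sorted(missing),
        )

    bounds = {}
    for met, rxn in exchange_by_met.items():
        bounds[rxn.id] = (-uptake.get(met, 0.0), SECRETION_MAX)
    return model.with_bounds(bounds)


def expand_medium(medium: Medium, secreted_ids: Iterable[str]) -> tuple[Medium, bool]:
    """Supplement the medium with newly secreted metabolites.

    Returns ``(new_medium, changed)`` where ``changed`` is True iff the set of
    metabolites present grew (the expansion-step fixed-point test). Oxygen is
    never added through secretion.
    """
    present = medium.all_metabolites
    new = frozenset(secreted_ids) - present - {medium.oxygen_id}
    if not new:
        return medium, False
    return (
        replace(medium, crossfed_metabolites=medium.crossfed_metabolites | new),
        True,
    )


# ---------------------------------------------------------------------------
# TSV interchange


def write_medium_tsv(medium: Medium, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metabolite_id", "role", "uptake_max"])
        for met in sorted(medium.base_metabolites):
            writer.writerow([met, "base", medium.bound_policy.nonlimiting_uptake_max])
        for met in medium.carbon_sources:
            writer.writerow([met, "carbon", medium.bound_policy.carbon_uptake_max])
        for met in sorted(medium.crossfed_metabolites):
            writer.writerow([met, "crossfed", medium.bound_policy.crossfed_uptake_max])
    return path


def read_medium_tsv(path: str | Path, oxygen: bool = False) -> Medium:
    base: set[str] = set()
    carbons: list[str] = []
    crossfed: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            role = row["role"]
            if role == "base":
                base.add(row["metabolite_id"])
            elif role == "carbon":
                carbons.append(row["metabolite_id"])
            elif role == "crossfed":
                crossfed.add(row["metabolite_id"])
            else:
                raise ValueError(f"unknown medium role {role!r}")
    medium = build_medium(base, carbons, oxygen)
    return replace(medium, crossfed_metabolites=frozenset(crossfed))


def read_carbon_list(path: str | Path) -> list[str]:
    """One carbon-source id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
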