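"""Iterative pairwise cross-feeding experiments and combinatorial sweeps.

One experiment couples two organisms through a shared, set-based medium.
Each iteration solves the two-stage costless-secretion problem for each
organism independently (no resource partitioning); if at least one organism
grows, the pooled set of newly secreted metabolites is added to the medium
and the loop repeats until the medium reaches a fixed point. The number of
distinct external metabolites across both models bounds the iteration count.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .fba_engine import costless_secretions, extract_uptakes
from .media import Medium, apply_medium, expand_medium
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "IterationResult",
    "PairExperimentRecord",
    "SweepPlan",
    "run_pair_experiment",
    "plan_sweep",
    "run_sweep",
    "RESULT_COLUMNS",
]


@dataclass
class IterationResult:
    """One application of the growth/secretion function F to both organisms."""

    iteration: int
    growth: tuple[bool, bool]
    growth_rates: tuple[float, float]
    secretions: tuple[dict[str, float], dict[str, float]]
    uptakes: tuple[dict[str, float], dict[str, float]]
    medium_metabolites: frozenset[str]


@dataclass
class PairExperimentRecord:
    organisms: tuple[str, str]
    carbon_sources: tuple[str, ...]
    oxygen: tuple[bool, bool]
    iterations: list[IterationResult] = field(default_factory=list)
    final_iteration: int = 0
    solo_growth: tuple[bool, bool] = (False, False)
    nonterminated: bool = False

    @property
    def final(self) -> IterationResult:
        return self.iterations[-1]

    @property
    def final_growth(self) -> tuple[bool, bool]:
        return self.final.growth

    def secreted_union(self, organism_index: int) -> set[str]:
        """All metabolites the organism secreted in any iteration."""
        out: set[str] = set()
        for it in self.iterations:
            out |= set(it.secretions[organism_index])
        return out

    def swapped(self) -> "PairExperimentRecord":
        """The same record with organism roles mirrored."""
        return PairExperimentRecord(
            organisms=(self.organisms[1], self.organisms[0]),
            carbon_sources=self.carbon_sources,
            oxygen=(self.oxygen[1], self.oxygen[0]),
            iterations=[
                IterationResult(
                    iteration=it.iteration,
                    growth=(it.growth[1], it.growth[0]),
                    growth_rates=(it.growth_rates[1], it.growth_rates[0]),
                    secretions=(it.secretions[1], it.secretions[0]),
                    uptakes=(it.uptakes[1], it.uptakes[0]),
                    medium_metabolites=it.medium_metabolites,
                )
                for it in self.iterations
            ],
            final_iteration=self.final_iteration,
            solo_growth=(self.solo_growth[1], self.solo_growth[0]),
            nonterminated=self.nonterminated,
        )


def run_pair_experiment(
    model_i: MetabolicModel,
    model_j: MetabolicModel,
    medium0: Medium,
    oxygen_i: bool | None = None,
    oxygen_j: bool | None = None,
    max_iter: int | None = None,
) -> PairExperimentRecord:
    """Run one in-silico co-culture experiment to medium fixed point.

    ``oxygen_i``/``oxygen_j`` override the medium's oxygen flag per organism
    (hybrid oxic--anoxic designs); ``None`` uses the medium's flag. The
    default ``max_iter`` is the number of distinct external metabolites across
    both models, a guaranteed termination bound for the monotone medium.
    """
    models = (model_i, model_j)
    oxy = (
        medium0.oxygen if oxygen_i is None else oxygen_i,
        medium0.oxygen if oxygen_j is None else oxygen_j,
    )
    if max_iter is None:
        max_iter = len(
            set(model_i.external_metabolites) | set(model_j.external_metabolites)
        )
    max_iter = max(max_iter, 1)

    record = PairExperimentRecord(
        organisms=(model_i.model_id, model_j.model_id),
        carbon_sources=medium0.carbon_sources,
        oxygen=oxy,
    )
    medium = medium0
    for c in range(1, max_iter + 1):
        secretions, uptakes, grows, rates = [], [], [], []
        for k, model in enumerate(models):
            bounded = apply_medium(model, medium, oxygen_override=oxy[k])
            solution, profile = costless_secretions(bounded)
            grows.append(solution.grows)
            rates.append(solution.growth_rate if solution.grows else 0.0)
            secretions.append(dict(profile.secretions) if solution.grows else {})
            uptakes.append(extract_uptakes(bounded, solution) if solution.grows else {})
        record.iterations.append(
            IterationResult(
                iteration=c,
                growth=(grows[0], grows[1]),
                growth_rates=(rates[0], rates[1]),
                secretions=(secretions[0], secretions[1]),
                uptakes=(uptakes[0], uptakes[1]),
                medium_metabolites=medium.all_metabolites,
            )
        )
        if c == 1:
            record.solo_growth = (grows[0], grows[1])
        if not any(grows):
            record.final_iteration = c
            return record
        pooled = set(secretions[0]) | set(secretions[1])
        medium, changed = expand_medium(medium, pooled)
        if not changed:
            record.final_iteration = c
            return record
    record.final_iteration = max_iter
    record.nonterminated = True
    logger.error(
        "pair experiment %s/%s did not reach a medium fixed point in %d iterations",
        model_i.model_id,
        model_j.model_id,
        max_iter,
    )
    return record


# ---------------------------------------------------------------------------
# sweeps


@dataclass(frozen=True)
class SweepConfig:
    organism_i: str
    organism_j: str
    carbon_a: str
    carbon_b: str
    oxygen_i: bool
    oxygen_j: bool


@dataclass
class SweepPlan:
    model_ids: tuple[str, ...]
    carbon_sources: tuple[str, ...]
    oxygen_conditions: tuple[tuple[bool, bool], ...]
    n_organisms_per_experiment: int = 2
    n_carbons_per_experiment: int = 2
    configs: list[SweepConfig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.configs)


def plan_sweep(
    models: Sequence[MetabolicModel | str],
    carbon_sources: Sequence[str],
    oxygen_conditions: Iterable[bool | tuple[bool, bool]] = (True, False),
    n_carbons_per_experiment: int = 2,
) -> SweepPlan:
    """Enumerate unordered organism pairs x unordered carbon pairs x oxygen.

    ``models`` may be model objects or bare ids (for counting-only plans).
    An oxygen condition may be a single flag (applied to both organisms) or a
    per-organism pair for hybrid designs.
    """
    ids = tuple(m if isinstance(m, str) else m.model_id for m in models)
    if len(ids) < 2:
        raise ValueError("need at least 2 models")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids")
    carbons = tuple(carbon_sources)
    if len(set(carbons)) != len(carbons):
        raise ValueError("duplicate carbon sources")
    if len(carbons) < n_carbons_per_experiment:
        raise ValueError("not enough carbon sources")
    oxy = tuple(
        (o, o) if isinstance(o, bool) else (bool(o[0]), bool(o[1]))
        for o in oxygen_conditions
    )
    configs = [
        SweepConfig(i, j, *cpair, o[0], o[1])
        for (i, j) in itertools.combinations(ids, 2)
        for cpair in itertools.combinations(carbons, n_carbons_per_experiment)
        for o in oxy
    ]
    return SweepPlan(
        model_ids=ids,
        carbon_sources=carbons,
        oxygen_conditions=oxy,
        n_carbons_per_experiment=n_carbons_per_experiment,
        configs=configs,
    )


RESULT_COLUMNS = [
    "org_i",
    "org_j",
    "carbon_a",
    "carbon_b",
    "o2_i",
    "o2_j",
    "grow_i",
    "grow_j",
    "solo_grow_i",
    "solo_grow_j",
    "c_s",
    "secreted_i",
    "secreted_j",
    "uptaken_i",
    "uptaken_j",
    "interaction",
    "motif",
]


def _join_fluxes(fluxes: dict[str, float]) -> str:
    return ";".join(f"{m}:{v:.6g}" for m, v in sorted(fluxes.items()))


def _config_key(cfg: SweepConfig) -> tuple:
    return (
        cfg.organism_i,
        cfg.organism_j,
        cfg.carbon_a,
        cfg.carbon_b,
        int(cfg.oxygen_i),
        int(cfg.oxygen_j),
    )


def record_to_row(record: PairExperimentRecord, label) -> dict:
    final = record.final
    sec_i = {m: max(it.secretions[0].get(m, 0.0) for it in record.iterations)
             for m in record.secreted_union(0)}
    sec_j = {m: max(it.secretions[1].get(m, 0.0) for it in record.iterations)
             for m in record.secreted_union(1)}
    return {
        "org_i": record.organisms[0],
        "org_j": record.organisms[1],
        "carbon_a": record.carbon_sources[0],
        "carbon_b": record.carbon_sources[1] if len(record.carbon_sources) > 1 else "",
        "o2_i": int(record.oxygen[0]),
        "o2_j": int(record.oxygen[1]),
        "grow_i": int(final.growth[0]),
        "grow_j": int(final.growth[1]),
        "solo_grow_i": int(record.solo_growth[0]),
        "solo_grow_j": int(record.solo_growth[1]),
        "c_s": record.final_iteration,
        "secreted_i": _join_fluxes(sec_i),
        "secreted_j": _join_fluxes(sec_j),
        "uptaken_i": _join_fluxes(final.uptakes[0]),
        "uptaken_j": _join_fluxes(final.uptakes[1]),
        "interaction": label.iclass if label is not None else "",
        "motif": label.motif_code if label is not None else "",
    }


def run_sweep(
    plan: SweepPlan,
    models: Sequence[MetabolicModel],
    base_medium: Medium,
    output_path: str | Path,
    resume: bool = False,
) -> Path:
    """Execute every config in ``plan``, writing one TSV row per config.

    ``base_medium`` supplies the base metabolites and bound policy; its
    carbon sources are replaced by each config's carbon pair. With
    ``resume=True`` rows already present in ``output_path`` are kept and
    their configs skipped; determinism makes the final table identical to an
    uninterrupted run.
    """
    from dataclasses import replace as _replace

    from .interactions import classify_interaction

    output_path = Path(output_path)
    by_id = {m.model_id: m for m in models}

    done: set[tuple] = set()
    rows: list[dict] = []
    if resume and output_path.exists():
        with open(output_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames != RESULT_COLUMNS:
                raise ValueError(
                    f"cannot resume: {output_path} has unexpected columns "
                    f"{reader.fieldnames}"
                )
            for row in reader:
                if any(row[c] is None for c in RESULT_COLUMNS):
                    raise ValueError(f"cannot resume: truncated row in {output_path}")
                rows.append(row)
                done.add(
                    (
                        row["org_i"],
                        row["org_j"],
                        row["carbon_a"],
                        row["carbon_b"],
                        int(row["o2_i"]),
                        int(row["o2_j"]),
                    )
                )

    n_done = len(done)
    for idx, cfg in enumerate(plan.configs):
        if _config_key(cfg) in done:
            continue
        medium = _replace(
            base_medium,
            carbon_sources=(cfg.carbon_a, cfg.carbon_b),
            crossfed_metabolites=frozenset(),
        )
        record = run_pair_experiment(
            by_id[cfg.organism_i],
            by_id[cfg.organism_j],
            medium,
            oxygen_i=cfg.oxygen_i,
            oxygen_j=cfg.oxygen_j,
        )
        label = None
        if all(record.final_growth):
            label = classify_interaction(record)
        rows.append(record_to_row(record, label))
        if (idx + 1) % 50 == 0:
            logger.info("sweep progress: %d/%d configs", idx + 1, len(plan.configs))

    key_order = {_config_key(c): i for i, c in enumerate(plan.configs)}
    rows.sort(
        key=lambda r: key_order.get(
            (
                r["org_i"],
                r["org_j"],
                r["carbon_a"],
                r["carbon_b"],
                int(r["o2_i"]),
                int(r["o2_j"]),
            ),
            len(key_order),
        )
    )
    with open(output_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=RESULT_COLUMNS, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    logger.info(
        "sweep complete: %d configs (%d resumed) -> %s",
        len(plan.configs),
        n_done,
        output_path,
    )
    return output_path
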