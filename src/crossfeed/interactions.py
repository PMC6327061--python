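"""Interaction classification, motif codes, syntrophy, and sweep summaries.

An interaction label is derived from a finished pair experiment:

* competition -- some primary carbon source is taken up (flux < -0.01) by
  both organisms in the final iteration;
* an exchange edge (i, m, j) exists iff organism i secreted m costlessly in
  some iteration and organism j takes m up in the final-iteration solution,
  with m not on the exclusion list (water and protons by default; CO2 and
  ammonium deliberately count as enabling byproducts);
* interaction class N/C/M from edge directions, and the motif code is
  class + number of primary carbons consumed + 'a'/'b' (competition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cosim import PairExperimentRecord

DEFAULT_EXCLUSION = frozenset({"h2o_e", "h_e"})

NO_PAIR_GROWTH = "no-pair-growth"

__all__ = [
    "InteractionLabel",
    "CooperativityInputs",
    "classify_interaction",
    "obligate_syntrophy",
    "cooperativity_index",
    "summarize_sweep",
    "DEFAULT_EXCLUSION",
    "NO_PAIR_GROWTH",
]


@dataclass
class InteractionLabel:
    competition: bool
    iclass: str                       # 'N' | 'C' | 'M' ('' for no pair growth)
    direction: str                    # 'i->j' | 'j->i' | 'both' | 'none'
    n_carbons_consumed: int
    motif_code: str
    exchange_edges: list[tuple[str, str, str]] = field(default_factory=list)


def classify_interaction(
    record: PairExperimentRecord,
    exclusion: Iterable[str] = DEFAULT_EXCLUSION,
) -> InteractionLabel:
    """Label a finished record; pairs without joint growth get a sentinel."""
    if record.nonterminated:
        raise ValueError(
            f"record {record.organisms} flagged nonterminated; cannot classify"
        )
    if not all(record.final_growth):
        return InteractionLabel(
            competition=False,
            iclass="",
            direction="none",
            n_carbons_consumed=0,
            motif_code=NO_PAIR_GROWTH,
        )

    exclusion = frozenset(exclusion)
    final = record.final
    carbons = record.carbon_sources

    consumed_by = [
        {c for c in carbons if c in final.uptakes[k]} for k in (0, 1)
    ]
    competition = bool(consumed_by[0] & consumed_by[1])
    n_carbons = len(consumed_by[0] | consumed_by[1])

    ids = record.organisms
    edges: list[tuple[str, str, str]] = []
    for giver, receiver in ((0, 1), (1, 0)):
        for met in sorted(record.secreted_union(giver) - exclusion):
            if met in final.uptakes[receiver]:
                edges.append((ids[giver], met, ids[receiver]))

    fwd = any(e[0] == ids[0] for e in edges)
    rev = any(e[0] == ids[1] for e in edges)
    if fwd and rev:
        iclass, direction = "M", "both"
    elif fwd:
        iclass, direction = "C", "i->j"
    elif rev:
        iclass, direction = "C", "j->i"
    else:
        iclass, direction = "N", "none"

    motif_code = f"{iclass}{n_carbons}{'b' if competition else 'a'}"
    return InteractionLabel(
        competition=competition,
        iclass=iclass,
        direction=direction,
        n_carbons_consumed=n_carbons,
        motif_code=motif_code,
        exchange_edges=edges,
    )


def obligate_syntrophy(record: PairExperimentRecord) -> tuple[bool, bool]:
    """Per organism: no solo growth on M_0, but growth in the pair."""
    return tuple(
        (not record.solo_growth[k]) and record.final_growth[k] for k in (0, 1)
    )


# ---------------------------------------------------------------------------
# cooperativity


@dataclass(frozen=True)
class CooperativityInputs:
    g_pair: int      # growth-yielding simulations on the carbon pair
    n_pair: int      # organisms tested on the pair (normalizer C(n,2))
    g_alpha: int
    n_alpha: int
    g_beta: int
    n_beta: int


def cooperativity_index(inputs: CooperativityInputs) -> float:
    """Normalized pair-growth frequency minus the product of single-source ones."""
    terms = []
    for g, n in (
        (inputs.g_pair, inputs.n_pair),
        (inputs.g_alpha, inputs.n_alpha),
        (inputs.g_beta, inputs.n_beta),
    ):
        norm = math.comb(n, 2)
        if norm == 0:
            raise ValueError(f"normalizer C({n},2) is zero")
        if not 0 <= g <= norm:
            raise ValueError(f"count {g} outside [0, C({n},2)={norm}]")
        terms.append(g / norm)
    return terms[0] - terms[1] * terms[2]


# ---------------------------------------------------------------------------
# sweep summaries


def _parse_fluxes(cell: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if isinstance(cell, str) and cell:
        for part in cell.split(";"):
            met, _, val = part.partition(":")
            out[met] = float(val)
    return out


def summarize_sweep(results: pd.DataFrame | str) -> dict[str, pd.DataFrame]:
    """Aggregate a sweep results table into summary frames.

    Returns motif frequencies, c_s distributions, per-metabolite secretion
    frequencies, per-pair outcome counts, and a Spearman rank correlation
    matrix of binary secretion indicators across growth-yielding simulations
    (constant indicators yield missing correlations).
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.read_csv(results, sep="\t", keep_default_na=False)
    if results.empty:
        raise ValueError("empty results table")
    df = results.copy()
    df["any_growth"] = (df["grow_i"].astype(int) | df["grow_j"].astype(int)).astype(bool)
    df["pair_growth"] = (df["grow_i"].astype(int) & df["grow_j"].astype(int)).astype(bool)
    df["condition"] = df.apply(
        lambda r: f"o2={int(r['o2_i'])}{int(r['o2_j'])}", axis=1
    )

    motif = (
        df[df["pair_growth"]]
        .groupby(["condition", "motif"])
        .size()
        .rename("count")
        .reset_index()
    )

    cs_dist = (
        df[df["any_growth"]]
        .groupby(["condition", "c_s"])
        .size()
        .rename("count")
        .reset_index()
    )

    grown = df[df["any_growth"]]
    secretion_sets = [
        set(_parse_fluxes(row["secreted_i"])) | set(_parse_fluxes(row["secreted_j"]))
        for _, row in grown.iterrows()
    ]
    all_mets = sorted(set().union(*secretion_sets)) if secretion_sets else []
    indicator = pd.DataFrame(
        [[met in s for met in all_mets] for s in secretion_sets],
        columns=all_mets,
        index=grown.index,
        dtype=float,
    )
    sec_freq = pd.DataFrame(
        {
            "metabolite_id": all_mets,
            "n_secreted": [int(indicator[m].sum()) for m in all_mets],
            "frequency": [
                float(indicator[m].mean()) if len(indicator) else np.nan
                for m in all_mets
            ],
        }
    )

    if len(indicator.columns) >= 2 and len(indicator) >= 2:
        spearman = indicator.corr(method="spearman")  # constant cols -> NaN
    else:
        spearman = pd.DataFrame(index=all_mets, columns=all_mets, dtype=float)

    pairwise = (
        df.assign(n_pair_growth=df["pair_growth"].astype(int))
        .groupby(["org_i", "org_j"])
        .agg(
            n_experiments=("pair_growth", "size"),
            n_pair_growth=("n_pair_growth", "sum"),
        )
        .reset_index()
    )
    inter = (
        df[df["pair_growth"]]
        .groupby(["org_i", "org_j", "interaction"])
        .size()
        .rename("count")
        .reset_index()
    )

    return {
        "motif_frequencies": motif,
        "cs_distribution": cs_dist,
        "secretion_frequencies": sec_freq,
        "cooccurrence_spearman": spearman,
        "pairwise_outcomes": pairwise,
        "pairwise_interactions": inter,
    }


def cooperativity_from_results(
    results: pd.DataFrame,
    carbon_alpha: str,
    carbon_beta: str,
    single_growth: Mapping[str, int],
    single_n: Mapping[str, int],
) -> float:
    """Eq.-style index from a two-carbon sweep plus single-carbon growth counts."""
    mask = (
        ((results["carbon_a"] == carbon_alpha) & (results["carbon_b"] == carbon_beta))
        | ((results["carbon_a"] == carbon_beta) & (results["carbon_b"] == carbon_alpha))
    )
    sub = results[mask]
    orgs = set(sub["org_i"]) | set(sub["org_j"])
    g_pair = int(
        ((sub["grow_i"].astype(int) == 1) & (sub["grow_j"].astype(int) == 1)).sum()
    )
    inputs = CooperativityInputs(
        g_pair=g_pair,
        n_pair=len(orgs),
        g_alpha=int(single_growth[carbon_alpha]),
        n_alpha=int(single_n[carbon_alpha]),
        g_beta=int(single_growth[carbon_beta]),
        n_beta=int(single_n[carbon_beta]),
    )
    return cooperativity_index(inputs)
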