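"""Command-line entry points tying the pipeline together.

Every subcommand writes its outputs alongside a ``config.json`` snapshot
sufficient to reproduce them (inputs, cutoffs, seeds); tabular outputs are
TSV, nested records JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click

from . import __version__
from .chemostat import ChemostatParams, stability_map
from .cosim import plan_sweep, run_pair_experiment, run_sweep
from .fba_engine import GROWTH_THRESHOLD, SECRETION_CUTOFF, UPTAKE_CUTOFF
from .interactions import (
    CooperativityInputs,
    classify_interaction,
    cooperativity_index,
    obligate_syntrophy,
    summarize_sweep,
)
from .media import read_carbon_list, read_medium_tsv
from .model_core import read_model
from .toyforge import emit_suite

logger = logging.getLogger("crossfeed")


def _snapshot(out_dir: Path, command: str, options: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshot = {
        "tool": "crossfeed",
        "version": __version__,
        "command": command,
        "options": options,
        "cutoffs": {
            "secretion": SECRETION_CUTOFF,
            "uptake_evidence": UPTAKE_CUTOFF,
            "growth_threshold": GROWTH_THRESHOLD,
        },
    }
    (out_dir / "config.json").write_text(json.dumps(snapshot, indent=1) + "\n")


def _load_models(models_dir: str):
    paths = sorted(Path(models_dir).glob("*.json"))
    if not paths:
        raise click.ClickException(f"no toy_json models in {models_dir}")
    return [read_model(p, format="toy_json") for p in paths]


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable info-level logging.")
def cli(verbose: bool) -> None:
    """Costless-secretion cross-feeding simulator."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("gen-toy")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--organisms", default=4, show_default=True)
@click.option("--carbons", default=6, show_default=True)
@click.option("--seed", default=0, show_default=True)
def gen_toy(out_dir: str, organisms: int, carbons: int, seed: int) -> None:
    """Generate a synthetic organism suite (models, medium, carbon list)."""
    manifest = emit_suite(out_dir, organisms, carbons, seed)
    _snapshot(
        Path(out_dir),
        "gen-toy",
        {"organisms": organisms, "carbons": carbons, "seed": seed},
    )
    click.echo(json.dumps(manifest, indent=1))


@cli.command("run-pair")
@click.option("--model-i", required=True, type=click.Path(exists=True))
@click.option("--model-j", required=True, type=click.Path(exists=True))
@click.option("--medium", "medium_path", required=True, type=click.Path(exists=True))
@click.option("--o2", type=click.Choice(["both", "none", "i-only", "j-only"]), default="none")
@click.option("--out", "out_dir", required=True, type=click.Path())
def run_pair(model_i: str, model_j: str, medium_path: str, o2: str, out_dir: str) -> None:
    """Run one iterative pair experiment and classify the interaction."""
    mi = read_model(model_i)
    mj = read_model(model_j)
    medium = read_medium_tsv(medium_path, oxygen=o2 == "both")
    oxy_i = o2 in ("both", "i-only")
    oxy_j = o2 in ("both", "j-only")
    record = run_pair_experiment(mi, mj, medium, oxygen_i=oxy_i, oxygen_j=oxy_j)
    label = classify_interaction(record)
    obligate = obligate_syntrophy(record)
    out = Path(out_dir)
    _snapshot(out, "run-pair", {"model_i": model_i, "model_j": model_j, "o2": o2})
    payload = {
        "organisms": record.organisms,
        "c_s": record.final_iteration,
        "solo_growth": record.solo_growth,
        "final_growth": record.final_growth,
        "obligate": obligate,
        "motif": label.motif_code,
        "exchange_edges": label.exchange_edges,
        "iterations": [
            {
                "c": it.iteration,
                "growth": it.growth,
                "growth_rates": it.growth_rates,
                "secretions": it.secretions,
                "uptakes": it.uptakes,
            }
            for it in record.iterations
        ],
    }
    (out / "record.json").write_text(json.dumps(payload, indent=1) + "\n")
    click.echo(f"motif={label.motif_code} c_s={record.final_iteration}")


@cli.command("sweep")
@click.option("--models", "models_dir", required=True, type=click.Path(exists=True))
@click.option("--medium", "medium_path", required=True, type=click.Path(exists=True))
@click.option("--carbons", "carbons_path", required=True, type=click.Path(exists=True))
@click.option("--o2", type=click.Choice(["both", "oxic", "anoxic"]), default="both")
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--resume", is_flag=True)
def sweep(models_dir, medium_path, carbons_path, o2, out_path, resume) -> None:
    """Run the combinatorial pairwise sweep to a results TSV."""
    models = _load_models(models_dir)
    medium = read_medium_tsv(medium_path)
    carbons = read_carbon_list(carbons_path)
    oxy = {"both": (True, False), "oxic": (True,), "anoxic": (False,)}[o2]
    plan = plan_sweep(models, carbons, oxygen_conditions=oxy)
    out_path = Path(out_path)
    _snapshot(
        out_path.parent if out_path.parent != Path("") else Path("."),
        "sweep",
        {"models": models_dir, "carbons": carbons_path, "o2": o2, "configs": len(plan)},
    )
    run_sweep(plan, models, medium, out_path, resume=resume)
    click.echo(f"{len(plan)} configs -> {out_path}")


@cli.command("classify")
@click.option("--model-i", required=True, type=click.Path(exists=True))
@click.option("--model-j", required=True, type=click.Path(exists=True))
@click.option("--medium", "medium_path", required=True, type=click.Path(exists=True))
@click.option("--o2", type=click.Choice(["both", "none", "i-only", "j-only"]), default="none")
def classify(model_i, model_j, medium_path, o2) -> None:
    """Classify the interaction motif for one pair (no files written)."""
    mi = read_model(model_i)
    mj = read_model(model_j)
    medium = read_medium_tsv(medium_path, oxygen=o2 == "both")
    record = run_pair_experiment(
        mi, mj, medium, oxygen_i=o2 in ("both", "i-only"), oxygen_j=o2 in ("both", "j-only")
    )
    label = classify_interaction(record)
    click.echo(
        json.dumps(
            {
                "motif": label.motif_code,
                "iclass": label.iclass,
                "competition": label.competition,
                "direction": label.direction,
                "edges": label.exchange_edges,
            }
        )
    )


@cli.command("coopindex")
@click.option("--g-pair", type=int, required=True)
@click.option("--n-pair", type=int, required=True)
@click.option("--g-alpha", type=int, required=True)
@click.option("--n-alpha", type=int, required=True)
@click.option("--g-beta", type=int, required=True)
@click.option("--n-beta", type=int, required=True)
def coopindex(g_pair, n_pair, g_alpha, n_alpha, g_beta, n_beta) -> None:
    """Cooperativity index from growth counts and organism-set sizes."""
    value = cooperativity_index(
        CooperativityInputs(g_pair, n_pair, g_alpha, n_alpha, g_beta, n_beta)
    )
    click.echo(f"{value:.6g}")


@cli.command("stability")
@click.option("--motif", required=True)
@click.option("--grid", "grid_n", default=51, show_default=True)
@click.option("--params", "params_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def stability(motif, grid_n, params_path, out_dir) -> None:
    """Compute a motif stability map over the (mu1, mu2) grid."""
    kwargs = {}
    if params_path:
        kwargs = json.loads(Path(params_path).read_text())
    params = ChemostatParams(**kwargs)
    result = stability_map(motif, params, grid_n=grid_n)
    out = Path(out_dir)
    _snapshot(out, "stability", {"motif": motif, "grid": grid_n, "params": kwargs})
    result.to_tsv(out / f"stability_{motif}.tsv")
    meta = {
        "motif": motif,
        "grid_n": grid_n,
        "stable_fraction": float(result.stable.mean()),
    }
    (out / f"stability_{motif}.json").write_text(json.dumps(meta, indent=1) + "\n")
    click.echo(json.dumps(meta))


@cli.command("report")
@click.option("--results", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def report(results, out_dir) -> None:
    """Summary tables (motif/secretion frequencies, c_s histogram, Spearman)."""
    tables = summarize_sweep(results)
    out = Path(out_dir)
    _snapshot(out, "report", {"results": results})
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=name == "cooccurrence_spearman")
    click.echo(f"wrote {len(tables)} tables to {out}")


def main(argv=None) -> int:
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.exceptions.UsageError as exc:
        click.echo(f"error: {exc.format_message()}", err=True)
        return 2
    except click.exceptions.Abort:
        return 1
    except click.ClickException as exc:
        exc.show()
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
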