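# crossfeed

Simulation toolkit for *costless* metabolic secretions and the microbial
interactions they enable. The pipeline:

1. **Flux balance analysis** (`crossfeed.fba_engine`) — maximize biomass on a
   defined medium, then minimize total absolute flux at that optimum and read
   off every exchange flux above the 0.01 mmol·gDW⁻¹·h⁻¹ secretion cutoff.
   A secretion is *costless* when forcing it at its reported rate does not
   reduce the maximal growth rate (checked with a dedicated probe,
   `secretion_cost`). Alternative objectives (biomass minimization, ATP
   max/min with growth pinned at 0.01 h⁻¹) are supported.
2. **Iterative co-culture experiments** (`crossfeed.cosim`) — two organisms
   share a set-based medium; each iteration solves both organisms
   independently, pools their costless secretions into the medium, and
   repeats until no new metabolite appears. Combinatorial sweeps enumerate
   unordered organism pairs × unordered carbon-source pairs × oxygen states
   (14 organisms × 108 carbons × 2 O₂ states → 1,051,596 configs).
3. **Interaction classification** (`crossfeed.interactions`) — competition
   (shared primary carbon uptake), exchange edges (secreted by one organism,
   taken up by the other), interaction class N/C/M, and motif codes such as
   `C1a` or `M2b`; plus obligate-syntrophy flags, a carbon-source
   cooperativity index, and sweep summary tables (motif frequencies,
   secretion co-occurrence Spearman matrices, …).
4. **Chemostat stability** (`crossfeed.chemostat`) — Monod ODE systems wired
   per motif topology, integrated for 500 h; a (μmax₁, μmax₂) grid cell is
   stable when both abundances exceed 0.05 g/L at the end.
5. **Synthetic fixtures** (`crossfeed.toyforge`) — small, hand-solvable
   metabolic models (≤ 15 reactions) with analytically known growth rates,
   secretion sets and motif outcomes; the repository's ground-truth engine.

Models are plain stoichiometric networks (`crossfeed.model_core`) readable
and writable as a documented `toy_json` dialect or SBML Level 3; external
metabolite namespaces can be harmonized across models with an explicit
mapping.

## CLI

```sh
# generate a synthetic suite (models/, medium.tsv, carbons.txt)
crossfeed gen-toy --out suite/ --organisms 4 --carbons 6 --seed 7

# one pair experiment with classification
crossfeed run-pair --model-i suite/models/ORG00.json \
    --model-j suite/models/ORG01.json --medium suite/medium.tsv \
    --o2 none --out out/

# full combinatorial sweep (resumable)
crossfeed sweep --models suite/models --medium suite/medium.tsv \
    --carbons suite/carbons.txt --o2 both --out results.tsv --resume

# summary tables from a sweep
crossfeed report --results results.tsv --out report/

# cooperativity index from growth counts
crossfeed coopindex --g-pair 45 --n-pair 14 --g-alpha 30 --n-alpha 14 \
    --g-beta 60 --n-beta 14

# motif stability map over the growth-rate grid
crossfeed stability --motif C1a --grid 51 --out stab/
```

Every command writes a `config.json` snapshot (inputs, cutoffs, seeds)
alongside its outputs.

### Worked example: fermenter + acetate specialist

`FERM` ferments glucose anaerobically (2 ATP + 2 acetate + 2 CO₂ per
glucose) or respires it aerobically (10 ATP + 6 CO₂); `ACSP` can only use
acetate. On an anoxic glucose medium, iteration 1: FERM grows at 5.0 h⁻¹
and secretes acetate (10.0) and CO₂ costlessly; ACSP cannot grow.
Iteration 2: ACSP grows on the cross-fed acetate and the medium stops
changing. The interaction classifies as commensalism without carbon
competition on one carbon source — motif `C1a` — with ACSP flagged as an
obligate syntroph:

```sh
python - <<'PY'
from crossfeed import run_pair_experiment, classify_interaction
from crossfeed.toyforge import make_motif_pair
m1, m2, medium, _ = make_motif_pair("C1a")
record = run_pair_experiment(m1, m2, medium)
print(classify_interaction(record).motif_code, record.final_iteration)
PY
```

## Formats

* `toy_json` model: `{"id", "metabolites": [{"id", "external"}],
  "reactions": [{"id", "stoich", "lb", "ub", "exchange"}], "biomass",
  "atp_maintenance"?}`; exchange reactions carry coefficient −1 on one
  external metabolite (positive flux = secretion, negative = uptake).
* Media TSV: `metabolite_id  role∈{base,carbon,crossfed}  uptake_max`.
* Sweep results TSV: one row per config with growth flags, `c_s`,
  `met:flux` lists for secretions/uptakes, interaction class and motif code.
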