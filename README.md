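# crcscreen

A Markov cohort cost-effectiveness model for colorectal-cancer (CRC)
screening. The package compares four strategies in a simulated average-risk
cohort of 100,000 persons followed annually from age 50 to 75:

* **no screening** (reference),
* **FIT** — annual faecal immunochemical test, colonoscopy on a positive,
* **COLOTECT** — annual multi-target stool-DNA test, colonoscopy on a positive,
* **colonoscopy** — primary colonoscopy repeated 10 years after a normal result.

All screening arms share a 3-yearly surveillance colonoscopy cycle after
polypectomy and a 10-year pause after a normal colonoscopy. The engine
reports CRC cases by stage, cancer deaths, procedure and complication
counts, a discounted cost ledger (3%/year), discounted life-years lost,
pairwise ICERs, the efficiency frontier with extended dominance, and one-way
sensitivity analyses (tornado table, compliance × kit-cost ICER grid).

Because the registry incidence extract and reference life table behind the
original analysis are not publicly deposited, `crcscreen.synthetic_epi`
generates structurally similar stand-ins (an exponentially age-increasing
incidence curve and a Gompertz–Makeham life table); both can also be read
from plain two-column text files.

## Layout

| Module | Contents |
| --- | --- |
| `crcscreen.params` | parameter dataclasses, defaults, YAML config load/validate |
| `crcscreen.synthetic_epi` | synthetic incidence / life tables, life expectancy, text IO |
| `crcscreen.strategies` | protocol schedules and screening eligibility rules |
| `crcscreen.engine` | deterministic cohort engine + seeded microsimulation oracle |
| `crcscreen.economics` | discounting, ICER, frontier / dominance, WTP threshold |
| `crcscreen.sensitivity` | one-way sweeps, tornado, compliance×cost grid, threshold search |
| `crcscreen.reporting`, `crcscreen.cli` | result tables, manifests, `crcscreen` CLI |

## CLI

```bash
# synthetic inputs as delimited text
crcscreen synth --seed 1 --out data/

# run all four strategies; writes results.csv, frontier.csv, manifest.json
crcscreen run --out out/ --seed 1

# selected strategies, custom parameters, file-based inputs
crcscreen run --strategy none --strategy colotect --config my.yml \
    --incidence data/incidence.csv --life-table data/life_table.csv --out out/

# tornado table and compliance x cost ICER grid
crcscreen sensitivity --out sens/ --costs 55,60,65

# efficiency frontier
crcscreen frontier
```

Parameter overrides use dotted YAML keys mirroring the baseline tables,
e.g.:

```yaml
colotect:
  compliance: 0.90
  cost: 65
colonoscopy:
  perforation_rate: 0.0008
settings:
  discount_rate: 0.0
```

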