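# acidtrace

Comparative analysis of **clustered-acidic C-terminal domains** in protein
families. Some homeodomain transcription factors (the Dbx family being the
motivating case) carry, besides their DNA-binding homeodomain and
Groucho-recruiting repressor domains, a short C-terminal cluster of acidic
residues (Asp/Glu) whose patchy distribution across species raises a
classic molecular-evolution question: was the domain gained once in a deep
ancestor and lost repeatedly, or gained convergently in separate lineages?

`acidtrace` is a toolkit for researchers asking that question about their
own family of interest. It provides:

* **Acidic-window scanning** — a sequence is Cter-positive when some
  window of `w` consecutive residues in its C-terminal tail has an acidic
  fraction of at least `f` (defaults `w = 10`, `f = 0.8`, i.e. ≥ 8 of 10
  residues D/E).
* **Domain projection** — reference domain coordinates (1-based inclusive,
  e.g. RD1 = 36–50) mapped through a family alignment; per-taxon coverage
  and similarity (identity or shared ClustalX strong group) yield
  presence/absence calls; ClustalX `* : .` conservation strings.
* **Gain/loss parsimony** — per character on a rooted Newick tree: Fitch
  cost (minimum changes, polytomy-safe); the Dollo scenario (single gain
  above the MRCA of bearers + the unique minimal loss set, event count
  `1 + #losses`); the gains-only cost (losses forbidden: one gain per
  maximal all-present clade). The verdict `convergence_scenario` /
  `losses_scenario` / `tie` compares the two event counts.
* **Global pairwise identity** — Needleman–Wunsch/Gotoh affine-gap
  alignment (BLOSUM62, open 10, extend 0.5) with deterministic
  tie-breaking and percent identity over mutually ungapped columns.
* **RSA summaries** — per-domain mean ± sd of NetSurfP-style per-residue
  relative solvent accessibility, compared across domains with a
  two-sided Mann–Whitney U test (exact for small untied samples).
* **A ground-truthed simulator** — synthetic families with conserved
  domain blocks, a planted/erasable acidic cluster, and recorded gain/loss
  events, so every stage is testable without downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 12-taxon family whose acidic C-terminal cluster was present at
the root and lost once, then run the full pipeline:

```bash
acidtrace simulate --n-taxa 12 --seed 11 --out demo/
acidtrace run --config analysis.yaml   # paths to demo/ files, reference t1,
                                       # domains RD1:36-46 RD2:105-115
```

The presence matrix (report `presence_matrix.tsv`) recovers the simulated
truth — both repressor blocks everywhere, the Cter lost in the clade
holding `t1` and `t10`:

```
taxon  t1  t10  t11  t12  t2  t3  t4  t5  t6  t7  t8  t9
RD1     1    1    1    1   1   1   1   1   1   1   1   1
RD2     1    1    1    1   1   1   1   1   1   1   1   1
Cter    0    0    1    1   1   1   1   1   1   1   1   1
```

and the scenario table (`scenarios.tsv`) weighs the two histories per
character:

```
character  fitch_cost dollo_gain_node dollo_losses  dollo_event_count  gains_only_cost         verdict
      RD1           0              N1                               1                1             tie
      RD2           0              N1                               1                1             tie
     Cter           1              N1          N10                  2                4 losses_scenario
```

Read the Cter row as: a single ancestral gain at the root (`N1`) plus one
loss on the branch above node `N10` explains the data with 2 events,
whereas forbidding losses would require 4 independent gains — so for this
family the losses scenario is the parsimonious one (2 < 4). A character
scattered across many distant clades flips the verdict to
`convergence_scenario`; a clean single clade is a `tie` (one gain either
way). The simulated truth here was exactly one gain at `N1` and one loss
at `N10`, which the Dollo reconstruction recovered.

Each stage is also a standalone subcommand (`identity`, `cterscan`,
`domains`, `scenarios`, `rsa`, `construct`, `simulate`); run
`acidtrace <cmd> --help` for flags. Everything is equally usable as a
library (`import acidtrace`).

To validate the aligner against real data, `scripts/fetch_real_dbx.py`
(network required) downloads the mouse Dbx1/Dbx2 records and prints their
global percent identity under the package defaults; the offline test suite
never depends on it.

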