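# Methods

`acidtrace` analyses the evolution of a clustered-acidic C-terminal domain
(here called *Cter*) in a homeodomain transcription-factor family, together
with the conserved repressor-domain blocks (RD1, RD2) and the homeodomain
that surround it. This note records the models and procedures implemented,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate.

## The acidic-window statistic

A sequence is called Cter-positive when some window of `window` consecutive
residues within its C-terminal `tail_len` residues contains at least
`min_fraction` acidic residues (Asp or Glu by default). Defaults are
`window = 10`, `min_fraction = 0.8`, matching the operational definition of
the domain as "a stretch of ten amino acids with at least 80 % D or E".

Numerical choices:

* The fraction comparison is **inclusive**: with window 10, exactly 8
  acidic residues qualifies. A small epsilon (1e-12) guards the floating
  comparison `count/window >= min_fraction`.
* `X` (unknown/ambiguity-collapsed) residues never count as acidic.
* `tail_len` defaults to 50 residues. The extent of "the C-terminus" is
  not a fixed biological quantity; 50 comfortably covers a 25-residue
  terminal domain plus drift in its position, and is exposed as a
  parameter (`"all"` disables the restriction). This default is a package
  choice, not a claim about how any particular dataset was originally
  screened.
* All hits are reported (overlaps included); the per-sequence call only
  needs existence. The best hit maximises the acidic fraction, ties broken
  by the rightmost (most C-terminal) start so the call is deterministic.
* Sequences shorter than the window are negative with a logged warning.

## Pairwise identity

Global alignment uses the Needleman–Wunsch/Gotoh three-state recursion with
affine gaps: a gap of length *k* costs `gap_open + (k-1)·gap_extend`, with
terminal gaps penalised like internal ones. Defaults are BLOSUM62, open 10,
extend 0.5 — conventional protein-alignment parameters; none of the
downstream biology here is sensitive to them because family identity is
dominated by the strongly conserved homeodomain.

Co-optimal alignments are resolved deterministically: the traceback prefers
substitution (diagonal) over a gap in the second sequence (up) over a gap
in the first (left), at every step and at the final cell (M > X > Y).

Percent identity is computed over **mutually ungapped columns** by default;
`denominator="shorter"` divides by the shorter sequence length instead.
Both modes are exposed because conventions differ between tools; reports
echo the mode used. Tests check the optimum score against exhaustive
enumeration of every global alignment (sequences ≤ 6 residues) and against
an independent dynamic-programming implementation (biopython's
`PairwiseAligner`) on longer pairs.

## Domain projection, conservation, presence

Reference domain coordinates are 1-based inclusive throughout (e.g. RD1 =
36–50 on a 335-residue reference). Projection walks the reference row of
the family alignment counting non-gap residues; the domain's columns are
exactly those carrying its residues, so reference-internal gap columns are
excluded and `|columns| == domain length` always holds.

Column conservation follows the ClustalX nomenclature: `*` for a
single-residue column without gaps, `:` when all residues fall in one
ClustalX *strong* group, `.` for one *weak* group, space otherwise. Any gap
in a column suppresses all three symbols. The strong groups (STA, NEQK,
NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW) and weak groups (CSA, ATV, SAG,
STNK, STPA, SGND, SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY) are hard-coded from
the ClustalX definition and unit-tested.

Per-taxon presence of a projected domain combines:

* **coverage** — non-gap positions over domain length, and
* **similarity** — the fraction of mutually ungapped positions where the
  taxon residue is identical to the reference residue *or shares a strong
  group with it*. Strong-group matches count because repressor-domain
  conservation across deeply diverged species is physico-chemical, not
  literal; identity alone would miss genuinely homologous blocks.

Defaults `min_coverage = 0.6`, `min_similarity = 0.4` are package choices
validated on synthetic data only — presence/absence in real families is
ultimately a judgment call, so both thresholds are exposed as flags and
echoed in every output row. Raising either threshold can only turn calls
from present to absent (monotonicity is tested). The reference taxon is
always present with similarity 1.

The construct editor (`delete_interval`, `truncate_cterm`, `append_cterm`)
performs exact 1-based interval arithmetic for in-silico deletion mutants
and tail transfers; edited records get deterministic id suffixes.

## Gain/loss parsimony

Characters are binary (domain present/absent) on a rooted tree; branch
lengths are ignored because the comparison is about event counts, not
rates. Three quantities per character:

* **Fitch cost** — the minimum number of 0↔1 changes, computed with
  Hartigan's maximum-count rule so polytomies are handled exactly; the
  top-down pass keeps the parent state where optimal (preferring 0 on free
  choices), yielding one deterministic optimal labeling.
* **Dollo scenario** — one gain on the branch above the MRCA of all
  present taxa, plus losses on the edges subtending maximal all-absent
  subtrees inside that clade. Given the single-gain constraint this loss
  set is unique and minimal. Event count = 1 + losses (0 for an all-absent
  character).
* **Gains-only cost** — with losses forbidden, the minimum number of
  independent gains equals the number of maximal all-present subtrees.

The verdict compares Dollo events against gains-only cost:
`convergence_scenario` when independent gains are cheaper,
`losses_scenario` when the single-gain history is cheaper, and an explicit
`tie` otherwise — the tie is reported rather than resolved, since both
histories are then equally parsimonious. This event-count comparison is an
operationalisation of the qualitative "unparsimonious number of losses"
argument; reports carry all three numbers so readers can apply their own
weighting of gains versus losses.

## RSA summaries

Per-residue relative solvent accessibility (in [0, 1]) is consumed from
NetSurfP-style tab-separated tables (`residue, position, rsa` columns,
`#` comments, positions contiguous 1..L); the prediction itself is out of
scope. Domain summaries report mean ± sample standard deviation (n−1
denominator) with n printed so readers can convert, plus the whole-protein
mean.

Domain-versus-domain comparison uses the two-sided Mann–Whitney U test —
chosen as the conventional nonparametric two-sample test for modest-n,
non-normal accessibility values — at `alpha = 0.01`. The exact null
distribution is used when the smaller group has ≤ 8 values and the pooled
values contain no ties; otherwise the normal approximation with tie (and
continuity) correction. The switch point keeps exact computation cheap
while covering the 11–25-residue domains this package targets. The exact
path is verified against full enumeration of group assignments for group
sizes ≤ 6.

## The synthetic-family generator

The generator provides ground truth, not phylogenetic realism:

* **Tree**: uniform random coalescent-style joining, 12 taxa by default,
  unit branch lengths.
* **Sequences**: a 360-residue root protein, uniform over the 20 standard
  amino acids except planted consensus blocks — RD1 (36–46) and RD2
  (105–115) seeded from the two canonical eh1-like endecapeptides
  (`LKFGVNAILSS`, `KSFLIENLLRA`) at relative rate 0.05, a homeodomain-like
  block (180–239) at 0.02. Each site substitutes along each branch with
  probability `background_rate × relative_rate` (default background 0.05)
  to a uniformly chosen different residue. Uniform replacement rather than
  an empirical matrix (WAG etc.) is a deliberate simplification: recovery
  tests need controllable truth, not realistic site patterns. No indels
  are simulated, so the true alignment is positional.
* **Cter character**: the final 25 residues. A present domain is realised
  as a planted cluster whose last `round(0.9 × 25) = 22` residues are
  D/E — packing the acidic run at the terminus guarantees a qualifying
  detector window whenever the planted fraction is at least the scan
  threshold. Loss randomises the region to non-acidic residues;
  drift inside the region is disabled so the character state, not
  substitution noise, controls detectability. Gains happen at the root by
  default (or on configured branches); losses happen per branch with
  probability 0.1.
* **Identifiability**: independent per-branch losses can produce
  unidentifiable histories — two sibling losses collapse into one
  canonical loss; losing an entire root-child clade moves the MRCA of the
  survivors. With `unambiguous_losses` (default on, single-gain models
  only) the state history is rejection-sampled until the realised events
  are exactly the canonical single-gain reconstruction, which is what
  makes *exact* gain-node and loss-set recovery a well-posed test. Turn it
  off to study ambiguous histories.

One `numpy` generator keyed by `seed` drives everything, with a documented
draw order (tree, state history, root sequence, per-branch substitutions in
preorder, cluster realisation), so runs are byte-reproducible.

What passing the synthetic tests shows: the detector finds exactly the
windows it defines, presence recovery is exact when planted clusters meet
the threshold, and the parsimony reconstructions invert the generative
model on identifiable histories. What it does not show: robustness to
indels and alignment error, to non-uniform substitution processes, to
acidic clusters near (rather than at) the terminus, or to borderline
clusters that drift across the threshold — real families can present all
of these.

## Suite and script sizing

The test suite verifies the scanner against brute-force window counting on
400 random sequences, the aligner against exhaustive alignment enumeration
on 25 random short pairs, Fitch against the exhaustive labeling minimum on
200 random trees of 4–8 leaves, the Mann–Whitney exact path against full
enumeration for all group-size pairs ≤ 6, and ground-truth recovery on 50
simulated 12-taxon families. These sizes keep the default run fast while
leaving each check far beyond plausible coincidence; they are package
choices and easy to raise locally.

## Known limitations

* Domain presence thresholds have no calibration against curated real
  families inside this package.
* The Dollo/gains-only comparison weighs gains and losses equally; a
  cost-ratio parameter would refine the verdict but is not implemented.
* The RSA stage trusts its input tables; no burial cutoff or
  residue-level classification is attempted.
* Percent identity of distant homologs depends on alignment parameters;
  only the two documented denominators and standard matrices are offered.
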