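# qcatdesign

Design of QconCAT/ALACAT peptide concatamer standards for absolute
protein quantitation by mass spectrometry.

Bottom-up quantitation measures a protein through surrogate tryptic
peptides, calibrated against spiked-in stable-isotope-labelled
standards — most economically a QconCAT: one recombinant protein
concatenating the quantification peptides of many targets, digested
alongside the sample. The design problem is picking, for each target,
peptides that are **proteotypic** (reliably detected whenever the
protein is present) and **quantotypic** (signal tracks protein
abundance), then assembling them into constructs whose tryptic
digestion releases every standard peptide exactly. `qcatdesign`
implements that workflow for proteomics practitioners building
targeted (SRM/DIA) assays:

- **Digestion** — in-silico tryptic limit digest (cleave after K/R
  unless the next residue is P), with 1-based coordinates and the
  native flanking residues that become construct linkers.
- **Scoring** — a weighted Boolean rule engine. Each metric *i* is
  graded PASS/FAIL (or INFO/ERROR) and

  &nbsp;&nbsp;&nbsp;&nbsp;POINTS = Σᵢ ASSESSMENTᵢ · WEIGHTᵢ,&nbsp; ASSESSMENTᵢ ∈ {0, 1}

  with default weight tiers DISABLED = 0, VERY_LOW = 1, LOW = 10²,
  NORMAL = 10⁴, HIGH = 10⁶, VERY_HIGH = 10⁸ — two orders of magnitude
  apart, so a single PASS on empirical evidence always outranks any
  accumulation of lower-tier prediction passes. Built-in metrics:
  empirical-evidence lookup, an expert elimination chain
  (C/M/H counts, NG/DG/DP/KP/RP motifs, Q start, K/R in the linkers,
  complete linkers), proteome sequence and monoisotopic-mass (MMI)
  repeat searches, within-submission repeats, and soft length/mass
  windows. External predictors plug in through a cached,
  failure-isolating adapter contract.
- **Assembly** — the top-scoring peptides per protein become a
  *Qbrick* (peptides wrapped in their native flanks), candidate bricks
  form a *Qblock* scored by the natural-order metric, and the best
  bricks are packed into the fewest *QconCAT* constructs under a
  length budget (exhaustive partition up to 8 blocks), emitting a
  *Qmenu*, construct FASTA and expected-fragment tables.
- **Evaluation** — peptides observed in an MS/MS-count table are split
  into Low/Medium/High detectability classes at the 33.3 % / 66.6 %
  count percentiles (never-observed digest peptides are NotFound);
  for every protein with ≥ 20 limit peptides the metric-favored
  peptide is compared with a random pick via
  log-odds = ln(n_favored / n_random) per class, with leave-one-out
  feature assessment.
- **Synthetic fixtures** — seeded generators for proteomes and
  observation tables with planted detectability effects, so the whole
  pipeline is testable offline.

## Worked example

```python
from qcatdesign import *
from qcatdesign.scoring import ScoringContext, score_peptides, \
    scorecards_to_table, default_metrics
from qcatdesign.assembly import score_qblocks

protein = ProteinRecord("P1", "MAKRPGKELRTTTSAGWTTKDDDFGHKLL")
peptides = tryptic_limit_digest(protein)
ctx = ScoringContext(evidence=frozenset({"DDDFGHK"}), submission=peptides)
cards = score_peptides(peptides, default_metrics(ctx), ctx)
print(scorecards_to_table(cards)[["subject_id", "sequence",
      "elimination_violations", "length", "points", "rank"]].to_string(index=False))
```

```
subject_id   sequence  elimination_violations  length  points  rank
    P1:1-3        MAK                       3       3   10000     3
    P1:4-7       RPGK                       2       4   10000     4
   P1:8-10        ELR                       1       3   10000     5
  P1:11-20 TTTSAGWTTK                       1      10   10200     2
  P1:21-27    DDDFGHK                       3       7 1010200     1
  P1:28-29         LL                       2       2   10000     6
```

DDDFGHK leads (1 010 200 points): its empirical-evidence PASS at HIGH
(10⁶) dominates everything else, plus uniqueness at NORMAL (10⁴) and
the length/mass windows at LOW (10² each). TTTSAGWTTK is second on
uniqueness + length + mass. The top two become a Qbrick with native
linkers and a construct:

```python
top = rank_and_select(cards, n=2)
block = build_qbricks([c.subject for c in top], protein)
score_qblocks([block])
menu = assemble_qconcats([block])
print(render_construct(menu.qconcats[0]))
```

```
>QconCAT proteins=P1 n_bricks=1 length=28
ELRTTTSAGWTTKDDDTTKDDDFGHKLL
```

Re-digesting this construct releases both designed peptides as exact
limit fragments (`expected_fragments` labels each fragment designed /
auxiliary / linker), because every linker has tryptic fragment
count 1.

The same stages are available as a CLI, composable through files:

```bash
qcatdesign digest targets.fasta -o out/
qcatdesign score targets.fasta --evidence observed.txt -o out/
qcatdesign design targets.fasta -o out/
qcatdesign evaluate proteome.fasta observations.tsv --seed 7 -o out/
```

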