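# Methods

## Problem and model

A QconCAT standard works only if every quantification peptide is (a) a
faithful reporter of its parent protein and (b) released from the
construct by trypsin exactly as it is released from the endogenous
protein. `qcatdesign` treats selection as a ranking problem over the
tryptic limit digest of each target, assembly as a packing problem over
the selected peptides with their native sequence context, and
evaluation as a class-enrichment comparison against empirical
detection data.

## Digestion

Trypsin is modelled as "cleave after K or R unless the next residue is
P", applied to completion (limit digest, zero missed cleavages).
Coordinates are 1-based inclusive. Ambiguity letters (B, Z, X, U) are
accepted at parse time but treated as non-cleaving during digestion —
a conservative choice that never invents a cut site — and rejected by
the mass/pI calculators, where they are uninterpretable. The digester
takes a `CleavageRule` object, so another protease could be
substituted, but nothing else in the package is tuned for non-tryptic
peptides and the defaults assume trypsin.

### Linker digestibility

Each designed peptide carries up to k = 3 native residues per side
(flanks), which become the construct's linkers. A linker's *fragment
count* is computed by embedding the flank between its construct
neighbours, digesting the joint string, and counting the digest
fragments that overlap the flank span. Under this convention the
release cuts at a linker's boundaries — including the cut after a
native N-flank's terminal K/R, which is precisely what frees the
designed peptide — delimit the linker without being penalised, while
any cut that actually splits the linker raises the count above the
ideal value of 1. Evaluating the count on the assembled construct
(`linker_fragment_counts`) uses the same digestion rule, so
junction-created or junction-suppressed sites (e.g. a K meeting a
P-initial neighbour) are handled identically.

## Physicochemical properties

Residue elemental compositions are the standard CHNOS formulas; one
water is added per peptide. Monoisotopic and average masses are
derived from the same formulas using CODATA isotope/atomic masses, so
mass, formula and composition are mutually consistent. Masses are for
the neutral, unmodified peptide; modifications enter the workflow only
as selection hazards (elimination chain), never as mass shifts.

The isoelectric point solves net charge = 0 by bisection on pH ∈
[0, 14] to |charge| < 1e-4, over Henderson–Hasselbalch terms for the
free termini and the D, E, C, Y, H, K, R side chains. The default pKa
set is the EMBOSS set, recorded with the output and swappable; the
termini guarantee a sign change over [0, 14], so bisection always
converges. Tests compare against a dense (1 mpH) grid-scan oracle.

## Scoring

POINTS = Σ ASSESSMENT × WEIGHT with ASSESSMENT ∈ {0, 1}. Default tier
values 0 / 1 / 10² / 10⁴ / 10⁶ / 10⁸ give strict tier dominance as
long as no tier carries more than 99 metrics. Grades: PASS, FAIL, INFO
(recorded, never scored — used for information-only outputs such as
pI) and ERROR (the metric could not be computed; the reason is stored
on the result, and the subject's POINTS simply lacks that term).
Head-to-head comparison (`compare_subjects`) additionally skips any
metric lacking a valid result on *either* side, so a transient adapter
failure cannot tilt a pairwise report.

Default metric tiers: evidence presence and zero elimination-chain
violations at HIGH; proteome sequence/MMI uniqueness and
within-submission uniqueness at NORMAL; length in [7, 25] and
monoisotopic mass in [700, 3500] Da at LOW. The length and mass
windows are soft mid-range preferences, explicitly configurable; they
are stand-in defaults, not empirically fitted thresholds. The MMI
repeat tolerance defaults to 0.001 Da — about the resolving power of a
high-resolution instrument for near-isobaric tryptic peptides — and is
configurable.

Ranking is deterministic: points descending, then earlier start
position, then lexicographic sequence. Requesting more peptides than
exist returns all with a warning.

External predictors and databases attach through registered adapters:
batch in, per-sequence values out, every exception converted to an
ERROR grade, successful results cached on disk keyed by (adapter name,
peptide sequence) — a file-based replacement for a database-backed
cache with the same semantics (never recompute a peptide seen before).
Errors are deliberately not cached, since they are usually transient.

## Assembly

For one or two selected peptides every ordering becomes a candidate
Qbrick; for longer selections only the natural and reversed orders are
generated, keeping the candidate set linear. The single default Qbrick
metric is natural order (units ascending by native start) at NORMAL;
there are no default construct-level metrics, only user hooks.

Construct packing minimises the number of QconCATs subject to a length
budget (construct = bricks + fixed elements). Up to 8 Qblocks the
minimum is found by exhaustive branch-and-bound over set partitions;
beyond that, first-fit-decreasing. Within a construct, bricks follow
the input protein order — the budget is the only stated objective, and
input order keeps assembly deterministic. Fixed auxiliary elements
(purification/normalisation tags) are config-supplied; the bundled
GluFib / c-Myc / His6 sequences are conventional laboratory tags, are
marked as such, and are excluded unless requested. Flanks are kept
per-unit and concatenated (adjacent flanks are not merged); the
expected-fragment table labels every digest fragment of the construct
as designed, auxiliary or linker-derived.

## Enrichment evaluation

Observed peptides are restricted to the limit-digest universe
(missed-cleavage or foreign observations are discarded with a
warning). The Low/Medium/High boundaries are the nearest-rank 33.3 %
and 66.6 % percentiles of the MS/MS counts with boundary ties assigned
downward (Low includes the first cut value), which resolves the shared
endpoints of count-bracket definitions; digest peptides never observed
are NotFound, and peptides observed with count 0 (e.g. inferred
between runs rather than directly identified) fall in Low by the same
rule. Per class, log-odds = ln(n_favored / n_random); when either cell
is zero a +0.5 pseudocount is applied to both (Haldane–Anscombe),
keeping the statistic finite without biasing populated cells. The
natural log is used; only sign and ordering are interpreted.

Proteins qualify with ≥ 20 limit peptides. The headline random
baseline is a single draw of one peptide per qualifying protein
(repetitions = 1); the leave-one-out assessment averages the baseline
over 10 seeded repetitions and reuses the *same* draws for every
feature subset, so per-feature deltas isolate the feature rather than
baseline noise. Both repetition counts are configurable and every
random path requires an explicit seed.

## Synthetic fixtures

The generator emulates the evaluation's data shape: a digest universe
plus per-peptide MS/MS counts over n_runs independent runs. Detection
is per-run Bernoulli with probability detect_prob × Π(multipliers of
satisfied planted properties), capped at 1; the MS/MS count is the
number of successful runs and zero-success peptides are omitted,
becoming NotFound downstream. Defaults: 300 proteins of 250–600
residue-wise uniform residues (≈ 25–60 limit peptides each, with
resampling guaranteeing ≥ 90 % qualify), 28 runs, baseline per-run
probability 0.02 — chosen so most of the universe is never observed,
matching the class structure of real shotgun data where the NotFound
group dominates. The planted-signal study triples detection for
methionine-free peptides (multiplier 3), a realistic effect direction:
methionine oxidation splits and weakens MS signal. The no-effect null
study uses 3500 proteins at per-run probability 0.05 with a
10-repetition baseline, sizing Monte-Carlo noise (σ ≈ 0.04 on each
class's log-odds) comfortably inside the |log-odds| < 0.1 acceptance
band.

What the fixtures do *not* model: intensity or retention time,
peptide-length- or composition-dependent ionisation, missed
cleavages, shared peptides between proteins beyond chance repeats, and
run-to-run correlation. Passing tests therefore demonstrate that the
pipeline recovers planted detectability structure and is unbiased in
its absence — not that the default metric weights are optimal for any
particular instrument or organism.

## Numerical and degenerate-input choices

- Digestion of a sequence with no cut sites returns the whole protein
  as one peptide (terminal type `whole_protein`); empty sequences are
  rejected at record construction.
- Degenerate percentiles (all counts equal) collapse the observed
  classes into Low with a warning rather than an error.
- An empty evidence list is usable but warns, since every peptide will
  score absent.
- Weight overrides must be non-negative; tier *order* is not enforced,
  so a user may deliberately invert tiers.
- Bisection for pI stops at |charge| < 1e-4 (≲ 0.002 pH for typical
  peptides); the grid oracle in tests bounds the deviation at 0.01 pH.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to exercise
every code path with tight statistics: 1000 random sequences for the
digestion oracle, 10 000 peptides for the elimination-chain oracle,
≤ 50-protein proteomes for the quadratic repeat oracle, 20 seeds × 300
proteins × 28 runs for planted-signal recovery, one 3500-protein null
study, and exhaustive-partition cross-checks on ≤ 6 Qblocks.

## Known limitations

- No external predictor models are bundled; adapters define the
  integration contract and tests use mocks.
- Remote sequence retrieval is out of scope; inputs are local FASTA,
  CSV or accession lists (accessions alone cannot be resolved to
  sequences offline).
- Codon-level design (reverse translation, oligo synthesis) is not
  implemented; output is amino-acid constructs.
- The pI model ignores charge suppression between neighbouring
  residues and conformational effects, as all pKa-table methods do.
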