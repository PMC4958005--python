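# Methods

## The question and the experimental design

Given a curated reference library with exactly one CO1 barcode per
species, every record is treated in turn as an "unknown" and queried
against the full library with the query's own record removed
(leave-self-out).  Each query keeps its ten best non-self hits with
E ≤ 1e-10.  A hit is a correct identification at genus (family) rank
when the hit's genus (family) equals the query's.  Because genera nest
within families, a correct genus implies a correct family, and families
always match at least as often as genera.

Two kinds of failure must be separated.  A record that is the only
member of its genus in the library *cannot* match correctly at genus
rank, and likewise for family singletons; these forced failures say
nothing about barcodes and everything about library coverage.
Singletons therefore remain in the library as targets (they make the
test harder and mimic public databases) but their hits are excluded
from rank-level accuracy assessments: at genus rank, queries that are
genus or family singletons; at family rank, queries that are family
singletons.

The analysis then asks: at what percent identity does a hit become
trustworthy?  For each rank the pipeline reports the integer PIdent
threshold `T` under an error budget `b` (default 0.05), under both
published phrasings of the rule:

* **error_share_below** (default): smallest `T` such that at least
  `1 − b` of all incorrect hits have PIdent < `T`.  This is the
  operational phrasing behind reported spider thresholds of 95 (genus)
  and 91 (family).
* **error_rate_above**: smallest `T` such that, among hits with
  PIdent ≥ `T`, the fraction incorrect is < `b`.

The two disagree when overall error rates are low (the rate definition
can be satisfied far below the barcode gap), which is why reports
always carry both, together with the full per-`T` cumulative table.
The boundary convention is fixed everywhere: a hit counts as above
threshold iff `pident >= T`; PIdent values are floor-binned onto the
integer grid.

Supporting outputs: best-hit accuracy above `T` (fraction of rank-1
hits with PIdent ≥ `T` that are correct); a two-sided rank-sum (or KS)
test that correct and incorrect PIdent distributions differ;
representation curves of hit quality versus species-per-genus and
genera-per-family; the congener best-match rate over multi-species
genera (under both "every query" and "any query" success semantics,
since the per-genus criterion is ambiguous in prose); and an
error-anatomy table of incorrect identifications sorted by PIdent
descending — the top of that table is where mislabeled database records
surface, since a wrong label turns the record's closest (highest
identity) true relatives into "errors".

## Alignment

Both aligners use affine gap costs in the BLAST convention (a gap of
length *k* costs `gap_open + k·gap_extend`) with the megaBLAST-like
integer scheme +1/−2, open 5, extend 2.  IUPAC ambiguity codes
(including N) always score as mismatches and never count as identities
— conservative and deterministic.  PIdent is
`100 × identities / aligned_columns` with gap columns in the
denominator, matching the BLAST tabular `pident` field; query coverage
is the aligned query span over the query length.

`smith_waterman` is the exhaustive dynamic program (all diagonals) and
serves as the oracle.  Co-optimal tracebacks are resolved
deterministically (diagonal > up > left; first-encountered best cell).

`seed_extend_align` is the production aligner: exact shared words of
length 11 are found by hashing, each seeded diagonal is extended
un-gapped with X-drop termination (X = 20), and the gapped stage
re-aligns inside a band of ±16 diagonals around the seeded
neighbourhood.  Word size 11 rather than megaBLAST's 28 because at
inter-family identities near 80% exact 28-mers are frequently absent,
which would erase exactly the cross-family hits the threshold analysis
needs; 28 remains available as a parameter.  The banded score can never
exceed the exhaustive optimum, and with single-base indels at realistic
rates the band virtually always contains the optimal path — the test
suite asserts equality on ≥ 95% of high-identity pairs and dominance on
all pairs.

Significance uses the Karlin–Altschul form
`bit = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bit)` with `n` the total
library length (database-search semantics).  λ = 1.33271 is the exact
root of `0.25·e^λ + 0.75·e^(−2λ) = 1` for the +1/−2 scheme at uniform
base composition (a unit test re-derives it); K = 0.296 was calibrated
once from the Gumbel location of optimal local scores of random
649-mers under the default gapped scheme and frozen.  Downstream
results are insensitive to K: it shifts all E-values by a constant
factor, and the E ≤ 1e-10 filter sits orders of magnitude away from
any hit the analysis uses.  The smallest significant score at
m = n = 649 (score 27) is frozen as a regression value.

Ranking within a query is total and reproducible: bit score
descending, then E-value ascending, then target id ascending.  Self
exclusion is by record id, not sequence equality, so identical
sequences under different ids remain hits of each other — mirroring the
behaviour that exposes duplicate/conflicting records in real libraries.
One alignment (the best extension) is kept per query–target pair.

## Synthetic libraries

The generator produces the study conditions for all tests: a scaled
library of ~150 species in 10 families whose identity structure matches
the spider library's PIdent regime.

**Taxonomy shape.**  Genus sizes are drawn from a truncated power law
(`k^−2.0`, k = 1…12), genera are dealt to the 10 families with
probability ∝ `rank^−1` (one guaranteed genus per family) until the
species total reaches 150.  This yields heavy-tailed family sizes
(largest family ≈ a third of the library), a species/genus mean near
2.5, roughly half of all genera monotypic — so ~25% of records are
genus singletons — and occasional family singletons, emulating at 150
species the composition ratios of an 816-species, 49-family,
313-genus empirical library.  Explicit count lists are accepted for
fully specified fixtures.

**Sequences.**  One random root (default 649 nt, uniform ACGT) evolves
into family ancestors, genus ancestors, then species, each branch
applying the exact Jukes–Cantor site-substitution probability
`q(d) = ¾(1 − e^(−4d/3))`, uniform over the three alternative bases.
Because JC distances compose additively, the per-branch distances are
set to half the increments between the rank-level *pairwise*
divergences (defaults 0.03 / 0.08 / 0.18 within genus / within family /
between families), giving expected pairwise identities of 97.1 / 92.4 /
84.0% with MRCA at genus / family / root.  Each branch's rate is
multiplied by a mean-one lognormal factor (σ = 0.4), so realized
rank-level identities spread ±1–4 points and overlap, as real lineages
do — without it all cross-family pairs would sit in a narrow band and
the family threshold would be an artifact of the binomial tail alone.
Single-base indels (rate 0.002/site/branch) exercise gap handling while
keeping query coverage near 1, and ~2% of records are truncated to
570–648 nt, emulating the shorter fragments real libraries admit.

**Corruptions.**  `inject_mislabels` moves a chosen fraction of records
into a different family, borrowing an existing genus of that family, and
records the truth in the manifest — emulating wrong-identification
records in public databases.  The manifest also carries per-record
substitution counts, singleton flags and the design identity brackets,
and equals the emitted library's composition whenever the mislabel rate
is zero.

**What the simulator does not model** — and hence what passing tests do
not show about real data: codon structure and CO1 base composition,
among-site rate heterogeneity, non-monophyletic genera, sequencing
error, and the phylogenetic correlation structure of a real tree
(families are a star around the root, so there are no "sister family"
pairs more similar than the lognormal spread allows).  Conclusions
about absolute threshold values on real libraries must come from real
libraries; the synthetic runs establish that the *pipeline* recovers
the thresholds implied by a known identity structure.

## Numerical and design choices

* **Duplicate-species resolution** during curation: keep the longest
  sequence, ties by lexicographically smallest record id — the
  empirical protocol's "choose one per species" without a stated rule
  needs a deterministic one.
* **Species key** is the (genus, species-string) pair, so identical
  epithets in different genera never collide; qualifiers like "cf." or
  "sp" pass through verbatim.
* **Taxonomy transport** is a fixed 4-column TSV; lineage is never
  parsed from FASTA headers.
* **Problem sizes**: default analyses use the ~150-species scaled
  library; the threshold-recovery experiment uses 20 seeds of it; the
  aligner-equivalence check uses 100 pairs of length ≤ 300.  These
  sizes were chosen so the whole suite re-runs comfortably on one CPU
  while leaving every statistical conclusion overdetermined.
* **Degenerate inputs**: an evaluable set with no incorrect hits yields
  a flagged degenerate threshold (the floor of the smallest observed
  PIdent); an empty best-hit scope yields a flagged undefined accuracy;
  zero hits for a query is a valid outcome, and such queries are simply
  absent from best-hit sets.

## Known limitations

* The gapped stage of the heuristic aligner is banded rather than a
  free gapped X-drop; pathological alignments whose optimal path drifts
  more than 16 diagonals from every seed would be under-scored.  At
  barcode lengths and indel rates this does not occur in practice (the
  oracle-dominance and equality tests quantify it).
* E-values use ungapped λ with a simulation-calibrated K; they are
  meant as a faithful filter and ranking statistic, not as replicas of
  any particular BLAST version's numbers.
* The congener best-match rate on synthetic data is near 1 because
  within-genus identity is planted well above cross-genus identity;
  the ~0.76 empirical value reflects database errors and non-monophyly
  that the simulator only reproduces when mislabels are injected.
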