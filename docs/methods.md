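# Methods

## The identification procedure

`ancid` determines the source species of a degraded-DNA sequencing
library from its alignments against a mitochondrial reference database.
The decision statistic is deliberately simple and count-based:

1. Every read is locally aligned against every database sequence, on
   both strands.
2. Within one reference sequence a read contributes at most one hit:
   the highest-identity one, equal-identity ties broken uniformly at
   random under a fixed seed. Hits to *different* reference sequences
   are all retained, so well-represented species accumulate more hits —
   this mirrors how multi-sequence mitochondrial databases are used in
   practice, and an optional `best_hit_per_read` mode restricts each
   read to its single best hit for databases with very uneven species
   representation.
3. Hits are filtered to a similarity band and a coverage floor
   (defaults: percent identity `L ≥ 98` and `L < 100`, query coverage
   `C ≥ 96`). The band's upper edge encodes a property of ancient
   templates: an ancient read should differ slightly from a modern
   reference (deamination, intraspecific distance), so a perfect match
   is disproportionately likely to be modern contamination. The
   coverage floor suppresses short partial alignments, which behave
   like random matches.
4. Optionally, hits are screened for postmortem-deamination evidence:
   at least one C→T or G→A column within the first or last `X` read
   bases (default `X = 10`, useful range 5–10). Damage-bearing reads
   are strong evidence of authentic ancient DNA; the screen sharpens
   the species signal at the cost of discarding undamaged endogenous
   reads. It presupposes a non-UDG library.
5. Surviving hits are the **valid mapping hits (VMH)**. Species are
   ranked by VMH count (the **species ranking, SR**); each species'
   share of total VMH is its **PoVMH** (percent of VMH); the ratio `R`
   of the top PoVMH to the runner-up PoVMH is the confidence measure.
   The call is the top-ranked species, unless fewer than `min_vmh`
   hits survive (default 10), in which case the sample is reported
   `unidentified` with a `low_vmh` flag — samples whose endogenous
   content maps in the single digits are not honestly callable.

No numeric threshold is imposed on `R` by default (`min_ratio = 1`
never flags): the ranking reports `R` and leaves the judgement
configurable, since any fixed cutoff would be an invention.

## The internal aligner

The aligner is a BLASTn-like seed-and-extend search, included so the
pipeline runs with no external binary. Exact 11-mers (configurable)
seed candidate regions on both strands; seed windows are merged per
diagonal neighbourhood; an ungapped x-drop extension of the seeds gates
each window (threshold: minimum reportable score minus one gap-open,
mirroring BLAST's ungapped gating); surviving windows are resolved by a
full affine-gap Smith–Waterman restricted to the window (the window
always contains the whole candidate region plus a read-length margin,
so for seeded alignments the reported score equals the unrestricted
optimum — the acceptance suite asserts exact score parity with an
independent full-matrix DP oracle on planted queries).

Scoring is classic blastn: +1 match, −2 mismatch, affine gaps with a
gap of length *k* costing 5 + 2*k*. N never counts as a match and never
qualifies as a damage column. Percent identity is identical columns
over alignment columns (gaps count against identity), matching the
convention under which the filter thresholds were calibrated. E-values
use Karlin–Altschul statistics with lambda solved exactly from the
scoring scheme and tabulated K; they will not numerically match any
particular BLAST release. This is deliberate and documented: the
pipeline's decisions depend only on percent identity and coverage,
which are robust to scoring-statistics details. Equal-score ties within
a subject resolve to the smallest subject start for determinism.

Two consequences of local alignment matter downstream and are faithful
to real BLAST behaviour: terminal mismatches are trimmed (a mismatch in
the first ~3 alignment columns can never raise the score), so damage at
the outermost read positions is invisible to the screen; and a read
whose only difference was trimmed away becomes a perfect match and is
then removed by the `L < 100` rule. Both effects are visible in the
simulation results and match the observation that screened changes
concentrate at positions ~4–10 rather than 1–3.

Limitations: one alignment is reported per merged seed window (hits to
separated regions of one reference still come out separately, which is
all the within-sequence dedup consumes); alignments whose every
ungapped segment scores below the prefilter threshold can be missed, as
in BLAST; no translated search, masking, or multithreading guarantees.

## The read simulator

The simulator emulates the statistical structure of shotgun libraries
from degraded remains; it is the test bed for every downstream claim.

* **Fragmentation** — fragments are drawn uniformly over each source
  sequence (circular by default, wrapping the origin), with lognormal
  lengths truncated to `[min_len, reference length]`; `min_len = 30`
  matches the usual adapter-trimming floor.
* **Damage** — strand-asymmetric terminal deamination: at distance *i*
  (0-based) from the 5′ terminus, a C becomes T with probability
  `d5·exp(−lam·i)`; G→A from the 3′ end with amplitude `d3`. This is a
  two-parameter exponential-decay model per terminus, not the full
  Briggs overhang/nick model: the pipeline consumes damage only as a
  screening signal ("≥ 1 terminal C→T/G→A"), which this model
  reproduces, and its parameters are directly recoverable from the
  misincorporation profile by log-linear regression (the acceptance
  suite recovers both within 10% relative error at 50,000 reads). A
  `single_stranded` flag switches the 3′ end to C→T, as in
  single-stranded libraries.
* **Contamination** — arbitrary source mixtures with per-source damage
  models; contaminants are undamaged by default (modern DNA).
  Per-source read counts follow largest-remainder allocation, exact to
  ±1 read.
* **Error** — uniform per-base substitution after damage. Qualities
  are constant Q40; the pipeline is quality-blind.
* **Truth** — every applied deamination, source interval and strand is
  recorded per read, enabling exact parameter-recovery tests and
  `true_alignments`, which reconstructs the gapless read-vs-source
  alignment from truth (used for damage profiling, where aligner
  end-trimming would bias terminal frequencies down).

Determinism: one seed drives fragmentation, damage, error and final
read-order shuffling; identical configs give byte-identical FASTQ and
truth tables.

What the simulator does **not** model: PCR duplicates, indel-type
damage, quality-dependent errors, reference biases within a species
(each species is one sequence in the toy database), and genuinely
homologous contaminants such as nuclear copies of mitochondrial genes.
Passing tests therefore demonstrate the decision logic under the
modelled conditions, not performance on any real library.

## Canonical toy study (presets)

The tests and the reproduction script use one fixed synthetic study
(`ancid.presets`): a 5-species database of 16 kb sequences at 10%
pairwise divergence (typical of mammalian mitochondrial interspecies
distance), an endogenous source with `d5 = d3 = 0.5`, `lam = 0.25`
(heavily damaged, as in the oldest permafrost samples; observed
terminal frequencies span ~2%–80%), fragment lengths 72 ± 18 bp (the
midpoint of reported per-sample means, ~46–93 bp), 0.2% sequencing
error, a 2% in-database undamaged contaminant (modern carryover), and
the remaining reads from a 100 kb sequence absent from the database
(the microbial/environmental background that dominates real
libraries). The damage level was fixed by a design power analysis: at
the hardest studied condition (1% endogenous in 10,000 reads) the
screen must leave enough hits to clear the `min_vmh = 10` floor, which
requires the strong-damage regime the screen is meant for; weakly
damaged samples at extreme dilution are genuinely below this method's
detection floor, and the pipeline reports them `unidentified` rather
than guessing.

Problem sizes in the test suite are chosen for a single-CPU run:
screening-efficacy uses 20 × 2,000-read simulations, species recovery
30 × 10,000-read simulations, the stability analysis one 3,000-read
mixture subsampled at depths 100–3,000 with 2 replicates, and
damage-parameter recovery one 50,000-read library.

## Numerical and tie-break choices

* PoVMH sums to 100 exactly (computed from integer VMH counts);
  equal-VMH species are ordered lexicographically.
* `R ≥ 1` by construction; `R` is undefined (reported `NA`/`null`)
  with fewer than two ranked species. Where a screened ranking
  collapses to one species, comparisons treat `R` as infinite
  (maximally decisive).
* All random tie-breaks (within-sequence dedup, best-hit mode) flow
  from explicit seeds; reports serialize deterministically and reruns
  are byte-identical.
* Misincorporation frequencies with zero denominators are reported as
  0 and flagged, never NaN-propagated; gap columns are excluded from
  numerator and denominator; decay fitting regresses `log f` on
  position over the first 10 positions with nonzero frequency.
* Coverage is `100·(qend − qstart + 1)/qlen` on BLAST's 1-based
  inclusive coordinates; minus-strand hits are encoded exactly as
  BLAST does (`sstart > send`), and all internal half-open arithmetic
  is converted at the boundary.
* The m8 writer emits standard 12-column tabular; round-trips are
  lossless except for float formatting of the E-value.
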