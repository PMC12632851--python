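# Methods

## The biological model

DRT10-class antiphage reverse transcriptases (RTs) synthesize long,
single-stranded, tandem-repeat cDNAs from a short template embedded in the
unpaired central loop of their associated ncRNA. The template architecture
is a direct repeat, written **A–B–A′**: A–B is the template proper and A′ is
a downstream copy of A. Synthesis is protein-primed (covalent 5′
protein–DNA linkage, modeled only as a boolean product flag), runs from the
3′ end of B to the 5′ template boundary at the start of A, and then the
nascent cDNA dissociates and its 3′ terminus — which is complementary to A —
re-anneals at A′, priming the next round. Each cycle appends one repeat
unit, the reverse complement of A–B. The mechanism is the bacterial
counterpart of telomerase repeat addition processivity: A–B plays the role
of the templating segment, A′ the alignment segment, and the stem-loop just
upstream of the template the template boundary element.

`repeatweaver` implements three connected pieces: the A–B–A′ detector and
designer (`templates`), a mechanistic stochastic simulator of the
repeat-addition cycle plus a synthetic miniprep-seq read generator
(`simulate`), and the sequencing-read analysis that discovers and
quantifies tandem-repeat motifs (`pipeline`), bound together by I/O and a
CLI (`seqio`, `workflow`, `cli`).

## Pattern detection (`templates`)

Coordinates on ncRNAs are 1-based inclusive, matching mutation nomenclature
such as U110A; read coordinates are 0-based. Detection requires exact
A = A′ identity — mismatch tolerance is a property of the polymerase during
realignment and lives in the simulator, which keeps the detector amenable
to an exhaustive brute-force oracle.

For a fixed pair of A/A′ start positions the repeat unit (A+B) is fixed, so
only the longest admissible A is reported; a pattern is additionally
suppressed when both copies of A can be extended one base 5′-ward within
bounds (the extension, which converts the last base of B into A, subsumes
it). Remaining patterns are ranked by `a_len` descending (A–A′ homology
length drives realignment efficiency), then `b_len` ascending, then
position. Defaults `min_a=2, max_a=10, min_motif=4, max_motif=30` bracket
the characterized natural systems (A–A′ homology of 2–4 nt, repeat units
from ~4 to tens of nt); no published parameterization exists for the
prevalence screens, so these bounds are exposed as configuration.

`design_template(motif, a_len)` inverts the mapping: reverse-complement RNA
of the motif followed by its own first `a_len` bases. The designed pattern
is always recovered among the detector's results; it is recovered *first*
unless the motif is self-similar (the designed template contains a repeated
`a_len`-mer other than the designed A/A′ pair), in which case an internal
repeat legitimately outranks it under longest-A-first ordering. Round-trip
tests therefore exclude self-similar designs via that a-priori criterion.

Template-loop restriction uses the annotated interval when given, else the
maximal unpaired run of a supplied dot-bracket structure; de novo RNA
folding is out of scope.

## Repeat-addition simulator (`simulate`)

Each product starts with one full unit (initiation at the 3′ end of B).
Per subsequent cycle:

1. **Continuation** — geometric with `p_continue` (default 0.98), capped at
   `max_cycles` (500). The experimental data show kilobase smears rather
   than a cycle-count distribution, so the law and default are free,
   exposed parameters.
2. **Register choice** — candidate annealing registers are every template
   position from the start of B through the end of A′ (re-annealing within
   A is disallowed); each is scored by the contiguous Watson–Crick match
   length at the primer 3′ terminus. Admissibility encodes the observed
   position-specific rules: depths 1–2 must pair (`strict_positions=2`);
   at depth 3 a purine:purine clash aborts while a pyrimidine:pyrimidine
   mismatch is tolerated (`purine_purine_block_depth=3`); from depth 4 any
   mismatch is tolerated (`free_depth=4`). The highest-scoring admissible
   register wins; ties break toward the canonical A′, then by a seeded
   draw. A cryptic copy of A inside B can therefore capture realignment
   and produce irregular unit lengths, as observed for the least precise
   natural homolog.
3. **Reset success** — `p_success_by_matchlen[score] * decay(len(A+B))`,
   with defaults 2→0.05, 3→0.5, ≥4→0.95: three bases of A–A′ homology
   support efficient resetting, two are marginal. `decay` is logistic in
   template length with midpoint 14 nt and scale 1.5 nt — a calibration
   choice (no quantitative mapping is published) set so that a native 9-nt
   unit resets at ~97% of the rule-based rate, a 10-mer B (14 nt total)
   at 50% ("attenuated but detectable"), and a 20-mer B (24 nt) below a
   0.2% per-cycle rate ("undetectable").

Templating always reads the actual A–B sequence and realignment always
reads the actual B/A′ bases, so mutant templates behave correctly without
special cases: mutating A alone or A′ alone leaves no admissible register
(loss of repeat addition), while jointly compensatory mutations restore
processive synthesis of the correspondingly mutated motif. Second-strand
synthesis is not modeled.

### Synthetic read generator

The generator emulates a miniprep-seq experiment: a WT library mixing
background reads with repeat-product reads, and an RT-dead control of
background only.

* Per-read condition draw: background with probability
  `background_fraction` (default 0.7, i.e. ~30% repeat-product reads in
  WT), so label counts are binomial, not fixed.
* Background reads are uniform random `read_len` (150 nt) windows of the
  reference, either strand. A small `artifact_fraction` (default 0.01) of
  background reads are random-sequence library artifacts. Real unmapped
  sets are dominated by such reference-unmappable junk (in the motivating
  experiments only a few percent of WT unmapped reads carry the motif); a
  generator without artifacts would leave the control's unmapped set empty
  and differential discovery undefined. Artifacts carry the `background`
  truth label but are excluded from the `n_reference_mapping` denominator.
* Repeat reads are windows of independently simulated products (products
  shorter than `read_len` are emitted whole), strand-randomized 50/50 to
  exercise both-orientation scanning downstream.
* Substitution errors at `seq_error_rate` (default 0.001) per base; FASTQ
  qualities are a constant placeholder ('I').

What the generator does **not** emulate: quality-score structure, indels,
adapter read-through, duplicates, host-genome contamination, coverage
biases, paired ends. Passing tests demonstrate recovery of the planted
signal under this idealized read model, not aligner-grade robustness on
real libraries.

## Read pipeline (`pipeline`)

* **Partition** — a read "maps" when it shares an exact ≥ `min_anchor`
  (default 30) nt substring with the reference or its reverse complement;
  a deliberately simple, testable stand-in for an aligner. The mapped
  count is the CPM denominator.
* **Discovery** — MEME-style black-box search is replaced by a transparent
  differential k-mer procedure. For each width 6–12, reads containing each
  k-mer (either orientation) are counted in WT-unmapped versus
  control-unmapped sets and scored with a one-sided pooled two-proportion
  z-test. Reported significance is the raw p times the number of distinct
  k-mers tested at that width (Bonferroni; the transparent analogue of a
  motif E-value). Top k-mers are greedily clustered: a candidate joins the
  first cluster whose seed it perfectly overlaps by ≥ 5 nt, matches in
  reverse complement, or lies within a tandem concatemer of (rotations and
  junction-spanning words of one repeat unit collapse together). The
  cluster consensus is the **longest member retaining ≥ 95% of the
  cluster's maximal WT read support**. This support-retention rule pins
  both unit width and phase: reads carrying a single repeat unit contain
  the true unit but neither its rotations nor any junction-spanning
  extension, so the true unit is the unique longest near-maximal-support
  member. The consensus is reported in the lexicographically greater
  orientation (the data are strand-symmetric; this is a deterministic
  reporting convention) and collapsed to one period if itself
  tandem-periodic. Consensi that are rotations/sub-words of an
  already-reported motif are suppressed.
* **Scanning** — exact, non-overlapping, greedy left-to-right; each read
  is scanned in both orientations and the orientation with more hits wins
  (ties: forward). An optional Hamming tolerance (default 0) exists for
  error-heavy data.
* **Quantification** — motif position graphs (hit starts relative to each
  read's first hit; `counts[0]` = number of motif-containing reads),
  longest-run histograms (run = chain of hits at exact motif spacing;
  single hit = 1, none = 0; a configurable number of interrupted units,
  default 0, may bridge a chain), reads with ≥ k consecutive repeats
  (default k=3) per million mapping reads, and flanking-context position
  frequency matrices (± 9 nt, truncated at read edges). The period
  estimate is the weighted mode of spacings between successive nonzero
  graph positions (weights `min(count_i, count_j)`, ties toward the
  smaller period) — chosen over autocorrelation for interpretability and
  an exact brute-force oracle; it raises rather than guesses when fewer
  than two positions are nonzero.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator`. The workflow derives
independent per-stage child seeds from the master seed via
`SeedSequence(seed, spawn_key)`, so identical configuration yields
byte-identical artifacts. Degenerate inputs raise (`n_reads <= 0`, missing
seed for a stochastic stage, restrict-to-loop without a loop, fewer than
two nonzero graph positions); they are never silently defaulted. Dropped or
filtered records are counted in the run report.

## Problem sizes

The packaged demonstration and test suite use 10,000 reads per condition
for the headline planted-motif recovery (the study-condition scale for that
analysis), 1,500–4,000 reads for auxiliary pipeline checks, 200–2,000
simulated products for mutational panels, and 20-seed pools (400 reads per
variant and seed) for the A–A′ truncation series — sizes at which the
tested contrasts are far from their decision thresholds while the whole
suite runs in minutes on one CPU.

## Known limitations

* The prevalence screen reproduces published collection-level fractions
  only given the corresponding ncRNA collections; the package ships the
  machinery (`batch_aba_prevalence`) and its generator-truth tests, not
  the collections.
* The anchor-substring partition is not an aligner; reads with dense
  errors near both ends can be misclassified relative to a full aligner.
* The logistic template-length decay and the geometric cycle-count law are
  calibration choices constrained only qualitatively by experiment.
* Discovery assumes substitution-type noise; indel-heavy reads would break
  exact k-mer containment and exact-spacing runs.
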