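# Methods

## Model of the module and of Cre recombination

A module is an alternating array `flank · lox · (segment · lox)* · flank`.
Because loxPsym is palindromic, recombination between any two sites can
delete, invert or tandem-duplicate the intervening block, and each outcome
preserves the alternating layout. lox sites are therefore implicit: the state
is a **signed sequence of segment ids** (a signed permutation generalised to
deletions and copies). Events are indexed by lox-site pairs `0 ≤ i < j ≤ m`
on the *current* genotype of length m; deletion removes the block, inversion
reverses it and flips orientations, duplication inserts a tandem copy after
it. Tandem geometry is the minimal Cre-consistent choice for duplications and
matches observed tandem gene amplification under selection. Orientation `+`
means reference strand as read from the left flank; `-` renders the reverse
complement. Coordinates are 0-based half-open internally; GFF3 output is
1-based inclusive.

The default construct (`his_module_design`) is a seven-cassette histidine
pathway module: cassette lengths 2.2–3.9 kb (native promoter + CDS + 3'UTR
scale), eight loxPsym linkers, 300 bp flanks carrying the primer anchors,
~20 kb total. Sequences are seeded random DNA; only lengths and layout enter
any statistic. The selectable marker sits outside the lox array by default
and never counts toward transcription-unit (TU) totals.

## Design-space counting

Iterated deletions + inversions from the intact module reach exactly the
signed arrangements of subsets: N(n) = Σₖ C(n,k)·k!·2ᵏ (inversions of blocks
generate the full signed symmetric group on the retained set; deletions give
subsets). This is *validated*, not assumed: `enumerate_reachable_bfs` computes
the closure of the event relation and agrees with the closed form for
n ≤ 5 (3, 13, 79, 633, 6331). Counting includes the fully deleted genotype
(`include_empty` flag); no mirror-image collapsing is done because the flanks
fix the reading orientation. Duplications make the space unbounded and are
rejected by the enumerator.

## Pool simulation

Per cell: Cre activity ~ Bernoulli(p_cre_active = 0.6); if active, event
count ~ Poisson(λ = 1.5) — the minimal memoryless choice for an induction
window — with event types drawn from weights (deletion 0.35, inversion 0.45,
duplication 0.20) and site pairs uniform; the GFP reporter flips with
p_reporter_flip = 0.9 in active cells and leaks at p_leak = 0.01 in inactive
ones (reporter and module events are conditionally independent given Cre
activity, so gated pools legitimately contain event-free cells). The
probabilities are not measured quantities; they are plausible defaults, all
exposed in `PoolConfig`. The default n_cells = 20,000 is a computational
scale-down of the >10⁶ cells a sorter would collect; it bounds Monte-Carlo
error on pool frequencies at ~0.7% and is configurable upward.

FACS gating reweights abundance by the GFP⁺ fraction. Selection is
deterministic exponential growth: abundance × 2^(g·μ/μ_max) over g
generations. The fitness model encodes the dosage biology: in `minus_his`
medium any genotype missing an essential cassette has μ = 0 (an optional
`dead_carryover` fraction models template amplified from dead cells);
otherwise μ/μ_max = mu_of_copy(copies of the dosage gene) with default
{0: 0, 1: 0.4, ≥2: 1.0} — one weak-promoter copy grows slowly, two restore
near-wild-type growth, further copies are neutral (saturating). PCR sampling
is multinomial with weight abundance·exp(−β·length/kb); β defaults to 0 (no
length enrichment), the bias being available as an option.

Read synthesis applies per-base substitutions/insertions/deletions
(defaults 0.03/0.02/0.04, a generic R9-era nanopore profile), uniform strand,
and truncation of 5% of reads at a uniform breakpoint; qualities are a
constant placeholder (the caller never uses them). Read ids embed the
ground-truth genotype key after `|gt=` strictly as a test oracle.

### Random-number plumbing

One global seed fans out to per-stage substreams keyed by hashed stage names
(`_rng.stage_rng`), so adding a stage never perturbs another stage's draws.
`run_iterative_rounds` keys each round's substream by **(seed, founder
genotype keys)** — common random numbers: two rounds that start from the same
founder reproduce identically, so round-to-round differences in the summary
reflect founder changes rather than resampling noise. This makes the
plateau diagnostic (dominant-genotype frequency non-decreasing once the
founder stops changing) exact rather than statistical.

## Genotype calling

1. **Full-length filtering.** Both flanks are located by semiglobal (infix)
   edit-distance alignment on both strands, allowing edits up to 0.2 × anchor
   length; a read is full-length iff both are found in consistent order, and
   it is re-oriented so the left anchor leads. Reads shorter than the
   empty-genotype amplicon are removed. Per-rule drop counts go to the QC
   report.
2. **Segment annotation.** loxPsym occurrences inside the module interior are
   found by iterative best-hit masking (≤10 edits per 34 bp site); the
   inter-lox intervals are each matched against the cassette catalogue (both
   strands, length prefilter ±30–45%) by infix alignment with
   k = (1 − min_identity)·|segment|. Unmatched adjacent intervals are merged
   (a spurious lox detection splits a cassette; a missed site fuses two) and
   re-searched by greedy iterative best-hit masking, which also handles
   tandem copies. Accepted hits need identity ≥ 0.70 and coverage ≥ 0.80;
   overlaps are resolved greedily (score, then length, then leftmost;
   ≤20% overlap of the shorter hit). Any method reproducing
   edit-distance-optimal infix alignment would be interchangeable here.
3. **Calling and aggregation.** Ordered signed hits form the canonical key
   (`+1,-2,...`); unannotated interior stretches >500 bp set a `gap` flag
   (flagged reads are excluded from tables by default, toggleable — partial
   annotations are flagged, not rejected, because both policies are
   defensible). The genotype table sorts by count then key; statistics are
   read-weighted: TU histogram, per-gene duplication (copy ≥2) and deletion
   (copy 0) frequencies, and the 3×/4×/≥5× copy spectrum. No correction for
   PCR length bias is applied at calling time; observed frequencies describe
   the read pool, not necessarily the cell population.

## Event explanation and gene impact

`diff_genotype` is descriptive, not a minimal event history (histories are
unidentifiable from one snapshot and parsimony reconstruction is out of
scope): copy 0 → deletion, copy ≥2 → duplication (copy_delta = copy−1), and
maximal runs of `-`-oriented, consecutive-descending ids → inversion blocks
(an isolated `-` element is its own block). Gene impact combines event labels
with GFF3 coordinates; a gene may carry several labels at once (e.g. inverted
and duplicated). A deletion/inversion boundary — a reference lox site — lying
strictly inside a gene's annotated 3'UTR marks it `utr_disrupted`; when no
`three_prime_UTR` feature exists, a 200 bp downstream window is used and the
evidence string says "inferred". The genome fixture writes 3'UTRs extending
past the downstream lox site, as in real loxPsym constructs where the site
sits just after the stop codon.

## What the synthetic data does and does not emulate

Emulated: genotype mixtures at set frequencies, Poisson per-cell event
counts, reporter-gated subpopulations, fitness-weighted enrichment, PCR
length bias, substitution/indel read noise and truncation. Not emulated:
sequence-level reporter-plasmid recombination (loxP2272/5171 chemistry),
inducer dose-response, inter-molecular recombination between module copies,
homopolymer-context error structure, basecalling quality values, chimeric
reads, or flow-cytometry instrument effects. Passing tests therefore show
that the pipeline's logic is correct under the stated noise model, not that
real-run accuracy will match; thresholds (identity 0.70, coverage 0.80,
anchor tolerance 0.2) were chosen to tolerate ~10% read error and are flags.

## Numerical and scale choices

Acceptance-grade checks use fixed seeds and moderate sizes chosen once:
20,000-cell inductions, 2,000-read noisy recovery (built by exact
proportional allocation so the ±0.03 check measures caller error, not
fixture sampling noise), 500-read exact round trip, 400-read selection
sampling, 20 generations of selection, 3 iterative rounds. Degenerate inputs
are defined: the empty genotype is legal everywhere (renders to
flank·lox·flank, counts zero TUs); an empty FACS gate, an all-dead selection
and an empty read set raise errors rather than returning empty results.

## Known limitations

Segment annotation assumes cassettes are mutually dissimilar (true for the
random-sequence designs and for distinct natural genes; near-identical
cassettes would need unique-region logic). Very short segments (≲60 bp,
comparable to the lox site) would fall below the interval length cut-offs.
The fitness model reduces a growth curve to one exponential rate per
genotype; lag, density effects and epistasis between rearrangements are not
modelled. Event weights per cell do not depend on genotype length, whereas
real Cre kinetics likely scale with lox-site count.
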