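# Methods

## The problem and the approach

Alternative-splicing analysis of large RNA-seq collections usually starts
from transcript annotation and read alignment. This package instead takes
the lightest possible input: a **splice-junction count table** — one row
per intron inferred from split-read alignments (chromosome, first and
last intronic base, strand), one column per sample — and discovers binary
splicing events and their percent-spliced-in (PSI) values without any
annotation. Annotation is used only afterwards, to flag which discovered
exons are known, and for the baseline of the motif analysis.

### Junction walking

Junctions are grouped by shared start or end coordinate. Walking from a
coordinate through an alternating series of junctions (introns) and
junction-free gaps (exons) yields closed loops; a binary event is a pair
of independent loops sharing the same exclusion condition. Four patterns
are classified:

* **cassette** — inclusion loop (two junctions around one exon) vs. a
  single exclusion junction joining the flanks;
* **alt-ss group** — several exon variants sharing one splice site and
  differing at the other, all skipped by the same exclusion junction;
* **linked exons** — a chain of 2..`max_linked` exons included or
  excluded as one unit against one exclusion junction;
* **mutually exclusive (MXE)** — two non-overlapping exons between common
  flanks, each inclusion loop excluding the other; a direct flank-to-flank
  junction may be absent.

An "exon" here is purely junction-inferred: the gap between two
consecutive junctions of a path, required to be non-empty, at most
`max_exon_span` (default 10 kb) long, and free of any junction lying
wholly inside it (internal intron evidence disqualifies a putative exon).

### Non-binary regions

The method deliberately refuses to force complex splice graphs into the
four binary shapes. Concretely, a candidate is dropped (and recorded with
a reason code in the diagnostics report) when:

* `nested_flank` — a single-exon candidate under exclusion junction E is
  itself the flank of a nested event inside E's span (another junction in
  the span starts immediately after it, or ends immediately before it,
  and skips its own nested path);
* `mxe_multi` — more than two exons participate in mutually exclusive
  pairings between one flank pair;
* `alt_ss_complex` — exon variants connected by shared boundaries do not
  all share one common boundary;
* `mxe_precedence` — when an MXE pair is emitted, single-exon readings of
  the same loops (the MXE partners and any candidate overlapping them)
  are suppressed rather than reported as cassettes.

These rules are implemented twice, independently: once in the
coordinate-indexed walker (`discovery`) and once in a brute-force,
index-free enumerator (`reference`) used by the validation suite; the
test harness demands exact event-set equality between the two on hundreds
of random transcript structures.

### Presence filters

A junction participates in discovery when it has ≥ `min_reads` (default
5) counts in ≥ `min_samples` (default 1) samples. The MXE "no connecting
junction" condition is noise-tolerant: a connector counts as absent when
its total reads fall below `mxe_noise_frac` (default 0.01) of the mean
total of the four inclusion junctions. Junctions shorter than
`min_intron_length` (default 20 bases) are treated as alignment artifacts
and dropped at load time.

## PSI

For one event in one sample, with Ī the inclusion and X̄ the exclusion
evidence,

    PSI = 100 · Ī / (Ī + X̄),   informative = round(Ī + X̄).

Ī is the **mean** count along the inclusion path (default; `sum` and
`min` are available behind `psi_convention`), so a two-junction inclusion
path is commensurate with a one-junction exclusion loop. Per type:
alt-ss groups sum the per-variant path means; MXE uses the upstream
exon's path as inclusion and the partner path as exclusion, and only the
upstream exon's PSI is emitted (the partner's is 100 minus it). Cells
with informative < `min_informative` (default 15) are **missing**, never
zero — low coverage is absence of evidence, not evidence of skipping.

Properties the suite asserts: PSI ∈ [0, 100]; monotone in every
inclusion (and anti-monotone in every exclusion) count; invariant under
scaling all member counts; mean PSI over replicate samples recovers the
simulated inclusion rate within 2 points at depth 200 and exactly at the
boundaries ψ ∈ {0, 1}.

## Group specificity

PSI is summarized per sample group as the mean over informative cells
(groups with fewer than `min_group_n` = 2 informative samples get no
mean). A group is called **enriched** for an event when its mean exceeds
the *best* other group's mean by ≥ `threshold` (default 50 points);
**depleted** mirrors this against the others' minimum. The min-gap
contrast means one other cell type sharing the exon vetoes specificity.
Events with fewer than `min_groups_informative` = 3 informative groups
are skipped. Calls are descriptive threshold crossings; no p-values are
attached, and none are implied.

## Motif windows

For each event exon with known strand, four windows are read in
transcript orientation: ±`intronic_flank` (1000 bp) into the introns and
`exonic_flank` (50 bp) into the exon at both the donor (5'SS) and
acceptor (3'SS). Exonic windows are clipped at the exon midpoint so the
two splice sites never double-count short exons. Motif occurrences
(U ≡ T) are counted with overlap, each assigned to the bin of its first
base; bins are `bin_width` = 25 bp, positions negative in the intron and
positive in the exon, counted from the splice site. The per-bin per-exon
mean is compared to the same statistic over a baseline exon set — all
protein-coding annotation exons shorter than 400 bp, deduplicated — and
the ratio is reported as enrichment (undefined where the baseline is
zero). Both the raw totals and per-exon means are emitted, since either
normalization is defensible. A preset scans the CU/UC-repeat pair
{CUCU, UCUC} and sums the profiles. The proximal-enrichment summary is
the mean enrichment over the intronic bins within 200 bp of the 5'SS —
the window where UAG (Musashi-1 consensus) clustering is expected for
photoreceptor-regulated exons.

## Synthetic data

The generator's unit is the junction count, matching the method's input;
no reads or alignments are simulated. Per event per sample the
informative total n is negative-binomial with mean `depth` (default 200)
and dispersion α (default 0.2, variance μ + αμ²; Poisson at α = 0),
emulating cross-accession depth variability in public archives;
inclusion molecules are i ~ Binomial(n, ψ). Every junction of the chosen
inclusion path records i — each included molecule is split-read evidence
at each junction it spans — and the exclusion loop records n − i. For
alt-ss groups the included molecules are split uniformly across variants,
the shared-boundary junction seeing all of them; note that the summed
per-variant path means then overweight the shared junction slightly, a
known property of that PSI convention. Optional noise junctions (counts
~ Poisson(1) per sample) are placed at least 20 bases from every true
splice coordinate and never wholly inside a true exon, so they can add
spurious candidates but cannot silently redefine a planted event.

Default locus geometry: event exons 30–120 bp, flanking exons 80–300 bp
(under the 400 bp baseline cutoff), introns 250–600 bp (room for the
motif windows), loci spaced 15 kb apart — beyond `max_exon_span`, so
loci cannot bridge.

Synthetic genomes write canonical GT..AG dinucleotides (transcript
orientation) at every junction on an i.i.d. uniform background. For motif
experiments the background is rejection-resampled until the motif and its
reverse complement occur nowhere outside the requested plants; the base
immediately upstream of every acceptor AG is held off T so splice sites
cannot spell UAG. The GTF always contains the flanking exons and a
configurable subset of event exons, which is how the
annotated/unannotated flag is exercised: the flag is an exact
(chrom, start, end) match of every event exon interval against the
annotation, `unknown` when no annotation is supplied.

What the simulations do **not** emulate: coverage biases (GC content,
secondary structure — PSI here inherits any bias present in the counts),
read-level sampling correlation between the two junctions of a path
(path junctions are assigned identical counts, making PSI exactly
ψ-centered; real junction counts wobble independently around the
molecule count), overlapping genes, unannotated strand conflicts, and
intron retention (not one of the four patterns). Passing tests therefore
demonstrate correctness of the event logic, the estimator's calibration,
and the window arithmetic — not robustness to alignment artifacts beyond
the modeled noise junctions.

## Numerical and design choices

* Coordinates are 1-based, fully closed, denoting the first and last
  intronic base (STAR convention); BED output converts to 0-based
  half-open. Discovery ignores strand (coordinates suffice); strand is
  carried for motif orientation, and unknown-strand events are excluded
  from motif profiles only.
* Only unique-read counts are taken from STAR files; multi-mapped counts
  are discarded as non-conservative evidence.
* Event ids are `type|chrom|flankStart-flankEnd|exonIntervals` — stable,
  sortable, human-readable; events are deduplicated by id and sorted
  genomically.
* `informative` is rounded to the nearest integer so the missingness
  threshold is a read count, while PSI itself is kept at full precision
  and serialized with one decimal.
* Validation problem sizes: 500 random transcript loci (≤ 8 exons, ≤ 6
  transcripts) for the discovery/reference equality check; 100 replicate
  samples per ψ for estimator recovery; 10 groups × 20 samples at depth
  200 for specificity (40 planted + 200 null events); 50 events × 8
  planted motif copies against a 60-locus baseline. The full suite and
  the acceptance script each run in seconds.

## Known limitations

Complex (non-binary) splicing is reported only as diagnostics, never as
events; intron retention is out of scope, as is any coverage-based
evidence. The alt-ss PSI convention overweights the shared junction (see
above). Specificity calling is descriptive and threshold-based by
design; users needing error control should model counts directly.
Overlapping exclusion spans from different genes are treated as
independent events.
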