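"""Synthetic junction tables, genomes and annotations with known truth.

The unit of simulation is the junction count — matching what the method
consumes — not reads. A :class:`SyntheticTruth` describes planted loci
(flanking exons, event exons, implied junctions), per-group true inclusion
rates ψ, sequencing depth and overdispersion. From it,
:func:`simulate_table` draws a junction count table whose implied event
list is known exactly, and :func:`simulate_genome` writes a matching
genome (canonical GT..AG splice dinucleotides at every junction) and GTF,
optionally withholding event exons from the annotation and planting motif
copies at controlled positions for the positional motif analysis.

Count model per event per sample: the informative total n is
negative-binomial with the configured mean depth and dispersion α
(variance μ + αμ²; Poisson at α = 0); inclusion molecules i ~ Binomial(n, ψ).
Every junction on the chosen inclusion path records i (each included
molecule is evidence at each of its junctions) and the exclusion loop
records n − i; for alt-ss groups the included molecules are split
uniformly across variants, the shared-boundary junction seeing them all.
Optional noise junctions (counts ~ Poisson(1)) are placed at least 20
bases away from every true splice coordinate and never wholly inside a
true exon, so they cannot redefine a planted event.

All randomness flows from the single truth seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .discovery import SpliceEvent
from .junctions import Junction, JunctionTable

__all__ = [
    "Locus",
    "SyntheticTruth",
    "MotifPlant",
    "SimulatedGenome",
    "random_event_locus",
    "random_truth",
    "specificity_truth",
    "simulate_table",
    "simulate_genome",
    "TranscriptLocus",
    "random_transcript_locus",
    "junctions_of_transcripts",
    "uniform_count_table",
]

Interval = tuple[int, int]
Coord = tuple[int, int]

EVENT_TYPES = ("cassette", "alt_ss_group", "linked", "mutually_exclusive")

#: noise junctions keep this clearance from every true splice coordinate
NOISE_CLEARANCE = 20
#: spacing between loci; larger than the discovery walker's max exon span
LOCUS_SPACING = 15_000


def _event_id(event_type: str, chrom: str, flanks: Coord, exons: Sequence[Interval]) -> str:
    exon_str = ";".join(f"{a}-{b}" for a, b in exons)
    return f"{event_type}|{chrom}|{flanks[0]}-{flanks[1]}|{exon_str}"


@dataclass(frozen=True)
class Locus:
    """One planted event: two flanking exons and the alternative exon(s)."""

    chrom: str
    event_type: str
    flank_left: Interval
    flank_right: Interval
    exons: tuple[Interval, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        coords = [self.flank_left, *sorted(self.exons), self.flank_right]
        for a, b in coords:
            if a > b:
                raise ValueError(f"empty interval {a}-{b}")
        if self.event_type == "alt_ss_group":
            starts = {x for x, _ in self.exons}
            ends = {y for _, y in self.exons}
            if len(self.exons) < 2 or (len(starts) != 1 and len(ends) != 1):
                raise ValueError("alt-ss variants must share exactly one boundary")
        else:
            for (a1, b1), (a2, b2) in zip(coords, coords[1:]):
                if b1 + 1 >= a2:  # need a real intron between consecutive exons
                    raise ValueError("intervals must be separated by introns")
        if self.event_type == "mutually_exclusive" and len(self.exons) != 2:
            raise ValueError("MXE locus needs exactly two exons")
        if self.event_type == "linked" and len(self.exons) < 2:
            raise ValueError("linked locus needs at least two exons")

    @property
    def flanks(self) -> Coord:
        return (self.flank_left[1] + 1, self.flank_right[0] - 1)

    @property
    def sorted_exons(self) -> tuple[Interval, ...]:
        return tuple(sorted(self.exons))

    def inclusion_paths(self) -> tuple[tuple[Coord, ...], ...]:
        s, e = self.flanks
        exons = self.sorted_exons
        if self.event_type == "cassette":
            (x, y), = exons
            return (((s, x - 1), (y + 1, e)),)
        if self.event_type == "linked":
            path = [(s, exons[0][0] - 1)]
            for (_, y1), (x2, _) in zip(exons, exons[1:]):
                path.append((y1 + 1, x2 - 1))
            path.append((exons[-1][1] + 1, e))
            return (tuple(path),)
        if self.event_type == "alt_ss_group":
            return tuple(((s, x - 1), (y + 1, e)) for x, y in exons)
        # mutually exclusive: one two-junction path per exon
        return tuple(((s, x - 1), (y + 1, e)) for x, y in exons)

    def exclusion_junctions(self) -> tuple[Coord, ...]:
        if self.event_type == "mutually_exclusive":
            return ()
        return (self.flanks,)

    def all_junctions(self) -> list[Coord]:
        seen: dict[Coord, None] = {}
        for path in self.inclusion_paths():
            for j in path:
                seen.setdefault(j, None)
        for j in self.exclusion_junctions():
            seen.setdefault(j, None)
        return list(seen)

    def splice_coords(self) -> set[int]:
        out: set[int] = set()
        for u, v in self.all_junctions():
            out |= {u, v}
        return out

    def true_exons(self) -> list[Interval]:
        return [self.flank_left, self.flank_right, *self.exons]

    @property
    def span(self) -> Interval:
        return (self.flank_left[0], self.flank_right[1])

    def expected_event(self) -> SpliceEvent:
        exons = self.sorted_exons
        return SpliceEvent(
            event_id=_event_id(self.event_type, self.chrom, self.flanks, exons),
            event_type=self.event_type,
            chrom=self.chrom,
            strand=self.strand,
            inclusion_paths=self.inclusion_paths(),
            exclusion_junctions=self.exclusion_junctions(),
            exon_intervals=exons,
        )


@dataclass
class SyntheticTruth:
    """Ground truth: loci, per-group true ψ, depths and group sizes."""

    loci: list[Locus]
    true_psi: dict[tuple[str, str], float]  # (event_id, group) -> ψ in [0, 1]
    groups: dict[str, int]  # group -> number of samples
    depth: float = 200.0
    dispersion: float = 0.2
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0 or self.noise_rate < 0:
            raise ValueError("dispersion and noise_rate must be non-negative")
        for (event_id, group), psi in self.true_psi.items():
            if not (0.0 <= psi <= 1.0):
                raise ValueError(f"ψ for {event_id}/{group} outside [0, 1]")
        event_ids = {locus.expected_event().event_id for locus in self.loci}
        for event_id, group in self.true_psi:
            if event_id not in event_ids:
                raise ValueError(f"true_psi names unknown event {event_id}")
            if group not in self.groups:
                raise ValueError(f"true_psi names unknown group {group}")
        for locus in self.loci:
            for group in self.groups:
                key = (locus.expected_event().event_id, group)
                if key not in self.true_psi:
                    raise ValueError(f"missing ψ for {key}")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1:02d}" for g in self.groups for i in range(self.groups[g])]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {f"{g}_{i + 1:02d}": g for g in self.groups for i in range(self.groups[g])}

    def expected_events(self) -> list[SpliceEvent]:
        return [locus.expected_event() for locus in self.loci]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "depth": self.depth,
            "dispersion": self.dispersion,
            "noise_rate": self.noise_rate,
            "groups": self.groups,
            "loci": [
                {
                    "chrom": lc.chrom,
                    "event_type": lc.event_type,
                    "strand": lc.strand,
                    "flank_left": list(lc.flank_left),
                    "flank_right": list(lc.flank_right),
                    "exons": [list(x) for x in lc.exons],
                    "event_id": lc.expected_event().event_id,
                }
                for lc in self.loci
            ],
            "true_psi": [
                {"event_id": k[0], "group": k[1], "psi": v} for k, v in self.true_psi.items()
            ],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# locus construction


def random_event_locus(
    rng: np.random.Generator,
    chrom: str,
    offset: int,
    event_type: str,
    strand: str | None = None,
) -> Locus:
    """Build one locus of the requested type starting near ``offset``.

    Exon lengths 30-120 bp, flanking exons 80-300 bp, introns 250-600 bp —
    roomy enough for the default motif windows and well under the baseline
    exon-length cutoff.
    """

    def exon_len() -> int:
        return int(rng.integers(30, 121))

    def flank_len() -> int:
        return int(rng.integers(80, 301))

    def intron_len() -> int:
        return int(rng.integers(250, 601))

    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    pos = offset
    flank_left = (pos, pos + flank_len() - 1)
    pos = flank_left[1] + 1 + intron_len()

    if event_type == "cassette":
        exons = [(pos, pos + exon_len() - 1)]
        pos = exons[0][1] + 1 + intron_len()
    elif event_type == "linked":
        exons = []
        for _ in range(int(rng.integers(2, 4))):
            exons.append((pos, pos + exon_len() - 1))
            pos = exons[-1][1] + 1 + intron_len()
    elif event_type == "mutually_exclusive":
        a = (pos, pos + exon_len() - 1)
        pos = a[1] + 1 + intron_len()
        b = (pos, pos + exon_len() - 1)
        pos = b[1] + 1 + intron_len()
        exons = [a, b]
    elif event_type == "alt_ss_group":
        length = exon_len()
        shift = int(rng.integers(5, 25))
        if rng.random() < 0.5:  # share the downstream boundary
            y = pos + shift + length - 1
            exons = [(pos, y), (pos + shift, y)]
        else:  # share the upstream boundary
            exons = [(pos, pos + length - 1), (pos, pos + length + shift - 1)]
        pos = max(y for _, y in exons) + 1 + intron_len()
    else:
        raise ValueError(f"unknown event type {event_type!r}")

    flank_right = (pos, pos + flank_len() - 1)
    return Locus(
        chrom=chrom,
        event_type=event_type,
        flank_left=flank_left,
        flank_right=flank_right,
        exons=tuple(exons),
        strand=strand,
    )


def random_truth(
    n_loci: int,
    groups: dict[str, int],
    seed: int,
    event_types: Sequence[str] = EVENT_TYPES,
    depth: float = 200.0,
    dispersion: float = 0.2,
    noise_rate: float = 0.0,
    psi_range: tuple[float, float] = (0.05, 0.95),
    loci_per_chrom: int = 25,
    strand: str | None = None,
) -> SyntheticTruth:
    """Random loci with group-wise ψ drawn uniformly from ``psi_range``."""
    rng = np.random.default_rng(seed)
    loci: list[Locus] = []
    true_psi: dict[tuple[str, str], float] = {}
    for i in range(n_loci):
        chrom = f"chrS{i // loci_per_chrom + 1}"
        offset = 1000 + (i % loci_per_chrom) * LOCUS_SPACING
        event_type = event_types[int(rng.integers(0, len(event_types)))]
        locus = random_event_locus(rng, chrom, offset, event_type, strand=strand)
        loci.append(locus)
        event_id = locus.expected_event().event_id
        for g in groups:
            true_psi[(event_id, g)] = float(rng.uniform(*psi_range))
    return SyntheticTruth(
        loci=loci,
        true_psi=true_psi,
        groups=dict(groups),
        depth=depth,
        dispersion=dispersion,
        noise_rate=noise_rate,
        seed=seed,
    )


def specificity_truth(
    n_events: int,
    seed: int,
    n_groups: int = 10,
    samples_per_group: int = 20,
    depth: float = 200.0,
    target_psi: float = 0.9,
    other_psi: float = 0.05,
    dispersion: float = 0.2,
) -> tuple[SyntheticTruth, dict[str, str]]:
    """One target group at high ψ, the rest low (or all equal for a null).

    Returns the truth plus the planted event → target-group mapping (empty
    values when ``target_psi == other_psi``, i.e. a null simulation).
    """
    rng = np.random.default_rng(seed)
    groups = {f"g{k + 1:02d}": samples_per_group for k in range(n_groups)}
    labels = list(groups)
    loci: list[Locus] = []
    true_psi: dict[tuple[str, str], float] = {}
    planted: dict[str, str] = {}
    for i in range(n_events):
        chrom = f"chrT{i // 25 + 1}"
        offset = 1000 + (i % 25) * LOCUS_SPACING
        locus = random_event_locus(rng, chrom, offset, "cassette")
        loci.append(locus)
        event_id = locus.expected_event().event_id
        target = labels[int(rng.integers(0, n_groups))]
        for g in labels:
            true_psi[(event_id, g)] = target_psi if g == target else other_psi
        if target_psi != other_psi:
            planted[event_id] = target
    truth = SyntheticTruth(
        loci=loci,
        true_psi=true_psi,
        groups=groups,
        depth=depth,
        dispersion=dispersion,
        seed=seed,
    )
    return truth, planted


# ---------------------------------------------------------------------------
# count sampling


def _draw_total(rng: np.random.Generator, depth: float, dispersion: float) -> int:
    if dispersion == 0:
        return int(rng.poisson(depth))
    size = 1.0 / dispersion
    p = size / (size + depth)
    return int(rng.negative_binomial(size, p))


def simulate_table(truth: SyntheticTruth) -> tuple[JunctionTable, list[SpliceEvent]]:
    """Draw a junction count table from the truth; fully seed-reproducible.

    Returns the table together with the event list the truth implies.
    """
    rng = np.random.default_rng(truth.seed)
    samples = truth.samples
    sample_groups = truth.sample_groups
    n = len(samples)
    counts: dict[tuple[str, Coord, str], np.ndarray] = {}

    def add(chrom: str, j: Coord, strand: str, col: int, value: int) -> None:
        key = (chrom, j, strand)
        if key not in counts:
            counts[key] = np.zeros(n, dtype=np.int64)
        counts[key][col] += value

    for locus in truth.loci:
        event = locus.expected_event()
        paths = locus.inclusion_paths()
        exclusion = locus.exclusion_junctions()
        for col, sample in enumerate(samples):
            psi = truth.true_psi[(event.event_id, sample_groups[sample])]
            total = _draw_total(rng, truth.depth, truth.dispersion)
            included = int(rng.binomial(total, psi)) if total else 0
            skipped = total - included
            if locus.event_type == "mutually_exclusive":
                for j in paths[0]:
                    add(locus.chrom, j, locus.strand, col, included)
                for j in paths[1]:
                    add(locus.chrom, j, locus.strand, col, skipped)
                continue
            if locus.event_type == "alt_ss_group":
                k = len(paths)
                per_variant = rng.multinomial(included, np.full(k, 1.0 / k)) if included else np.zeros(k, dtype=int)
                starts = {p[0] for p in paths}
                shared_left = len(starts) == 1
                for v, path in enumerate(paths):
                    shared_j = path[0] if shared_left else path[1]
                    variant_j = path[1] if shared_left else path[0]
                    add(locus.chrom, shared_j, locus.strand, col, 0)  # ensure row exists
                    add(locus.chrom, variant_j, locus.strand, col, int(per_variant[v]))
                shared = paths[0][0] if shared_left else paths[0][1]
                add(locus.chrom, shared, locus.strand, col, included)
            else:  # cassette, linked: one inclusion path
                for j in paths[0]:
                    add(locus.chrom, j, locus.strand, col, included)
            for j in exclusion:
                add(locus.chrom, j, locus.strand, col, skipped)

        if truth.noise_rate > 0:
            n_noise = int(rng.poisson(truth.noise_rate))
            forbidden = locus.splice_coords()
            exon_list = locus.true_exons()
            span = locus.span
            for _ in range(n_noise):
                for _attempt in range(50):
                    u = int(rng.integers(span[0], span[1] - NOISE_CLEARANCE))
                    v = u + int(rng.integers(NOISE_CLEARANCE, 200))
                    clear = all(
                        abs(u - c) >= NOISE_CLEARANCE and abs(v - c) >= NOISE_CLEARANCE
                        for c in forbidden
                    )
                    inside_exon = any(a <= u and v <= b for a, b in exon_list)
                    if clear and not inside_exon:
                        vec = rng.poisson(1.0, size=n).astype(np.int64)
                        key = (locus.chrom, (u, v), locus.strand)
                        counts[key] = counts.get(key, np.zeros(n, dtype=np.int64)) + vec
                        break

    junctions = [
        Junction(chrom=chrom, start=j[0], end=j[1], strand=strand, counts=vec)
        for (chrom, j, strand), vec in counts.items()
    ]
    table = JunctionTable(junctions=junctions, samples=samples, groups=sample_groups)
    return table, truth.expected_events()


# ---------------------------------------------------------------------------
# genomes, annotations and motif planting


@dataclass(frozen=True)
class MotifPlant:
    """Plant ``copies`` motif occurrences in one splice-site window of one
    locus. Offsets are signed positions (intronic negative), the first
    base of each copy falling inside [offset_lo, offset_hi]."""

    locus_index: int
    anchor: str  # 5prime_ss | 3prime_ss
    offset_lo: int
    offset_hi: int
    copies: int
    exon_index: int = 0


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    gtf: str
    planted_positions: dict[int, list[int]] = field(default_factory=dict)

    def fasta(self) -> str:
        out = []
        for chrom in sorted(self.sequences):
            out.append(f">{chrom}")
            seq = self.sequences[chrom]
            out.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
        return "\n".join(out) + "\n"

    def write_fasta(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.fasta())

    def write_gtf(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.gtf)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(
    truth: SyntheticTruth,
    motif_plants: Sequence[MotifPlant] = (),
    motif: str = "TAG",
    scrub_motif: bool = True,
    annotate_event_exons: bool | Sequence[int] = True,
    margin: int = 1100,
) -> SimulatedGenome:
    """Random genome + GTF consistent with the truth's junctions.

    Every intron gets canonical GT..AG dinucleotides. With ``scrub_motif``
    the background is rejection-resampled so the motif (and its reverse
    complement) occurs nowhere except the requested plants. The GTF
    contains the flanking exons always and the event exons for the loci
    selected by ``annotate_event_exons`` (True = all, or an index list),
    all typed protein_coding.
    """
    motif = motif.upper().replace("U", "T")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    lengths: dict[str, int] = {}
    for locus in truth.loci:
        lengths[locus.chrom] = max(lengths.get(locus.chrom, 0), locus.span[1] + margin)
    seqs = {
        chrom: rng.choice(list("ACGT"), size=size).tolist()
        for chrom, size in sorted(lengths.items())
    }

    protected: dict[str, set[int]] = {chrom: set() for chrom in seqs}

    def write(chrom: str, pos1: int, text: str, protect: bool = True) -> None:
        seq = seqs[chrom]
        for k, base in enumerate(text):
            idx = pos1 - 1 + k
            if idx < 0 or idx >= len(seq):
                raise ValueError(f"write outside {chrom} at {pos1 + k}")
            seq[idx] = base
            if protect:
                protected[chrom].add(idx)

    for locus in truth.loci:
        for u, v in locus.all_junctions():
            # canonical GT..AG in transcript orientation: forward GT..AG on
            # the + strand, forward CT..AC on the - strand
            if locus.strand == "+":
                write(locus.chrom, u, "GT")
                write(locus.chrom, v - 1, "AG")
                guard = v - 2  # transcript base right before the acceptor AG
                guard_base = "C"
            else:
                write(locus.chrom, u, "CT")
                write(locus.chrom, v - 1, "AC")
                guard = u + 2
                guard_base = "G"  # complement of transcript C
            # keep that base off 'T' (transcript orientation) so splice
            # sites never spell the motif by accident
            if motif == "TAG":
                write(locus.chrom, guard, guard_base)

    planted_positions: dict[int, list[int]] = {}
    for plant in motif_plants:
        locus = truth.loci[plant.locus_index]
        exon = locus.sorted_exons[plant.exon_index]
        lo, hi = plant.offset_lo, plant.offset_hi
        if hi < lo:
            raise ValueError("empty plant offset range")
        chosen: list[int] = []
        for _ in range(plant.copies):
            for _attempt in range(200):
                off = int(rng.integers(lo, hi + 1))
                if all(abs(off - c) >= len(motif) for c in chosen):
                    chosen.append(off)
                    break
            else:
                raise ValueError("could not place non-overlapping motif copies")
        donor_side = plant.anchor == "5prime_ss"
        for off in sorted(chosen):
            depth = -off  # distance into the intron of the copy's first base
            if depth < 1:
                raise ValueError("plants must be intronic (negative offsets)")
            x, y = exon
            if locus.strand == "+":
                if donor_side:
                    start = y + depth  # first base, running deeper
                    text = motif
                else:
                    start = x - depth - len(motif) + 1
                    text = motif
            else:
                if donor_side:
                    start = x - depth - len(motif) + 1
                    text = _revcomp(motif)
                else:
                    start = y + depth
                    text = _revcomp(motif)
            idxs = range(start - 1, start - 1 + len(motif))
            if any(i in protected[locus.chrom] for i in idxs):
                raise ValueError(
                    f"motif plant at {locus.chrom}:{start} collides with a splice site"
                )
            write(locus.chrom, start, text)
        planted_positions[plant.locus_index] = sorted(chosen)

    if scrub_motif:
        targets = {motif, _revcomp(motif)}
        k = len(motif)

        def clean_around(seq: list[str], i: int) -> bool:
            lo = max(0, i - k + 1)
            window = "".join(seq[lo : i + k])
            return not any(t in window for t in targets)

        for chrom, seq in seqs.items():
            prot = protected[chrom]
            for _round in range(50):
                text = "".join(seq)
                dirty = False
                for target in targets:
                    start = text.find(target)
                    while start != -1:
                        free = [i for i in range(start, start + k) if i not in prot]
                        # pick a replacement base that removes every target
                        # occurrence touching this position (avoids cycles
                        # against protected neighbours)
                        for i in free:
                            original = seq[i]
                            done = False
                            for base in "CGAT":
                                if base == original:
                                    continue
                                seq[i] = base
                                if clean_around(seq, i):
                                    done = True
                                    break
                            if done:
                                dirty = True
                                break
                            seq[i] = original
                        start = text.find(target, start + 1)
                if not dirty:
                    break
            else:
                raise RuntimeError(f"could not scrub motif from {chrom}")

    gtf_lines = []
    if annotate_event_exons is True:
        annotated = set(range(len(truth.loci)))
    elif annotate_event_exons is False:
        annotated = set()
    else:
        annotated = set(annotate_event_exons)
    for i, locus in enumerate(truth.loci):
        gene = f"locus{i + 1}"
        exons = [locus.flank_left, locus.flank_right]
        if i in annotated:
            exons += list(locus.exons)
        attrs = (
            f'gene_id "{gene}"; transcript_id "{gene}.t1"; gene_type "protein_coding";'
        )
        for a, b in sorted(set(exons)):
            gtf_lines.append(
                f"{locus.chrom}\tascotwalk_sim\texon\t{a}\t{b}\t.\t{locus.strand}\t.\t{attrs}"
            )
    gtf = "\n".join(gtf_lines) + ("\n" if gtf_lines else "")
    sequences = {chrom: "".join(seq) for chrom, seq in seqs.items()}
    return SimulatedGenome(sequences=sequences, gtf=gtf, planted_positions=planted_positions)


# ---------------------------------------------------------------------------
# random transcript structures (for validating discovery against a
# brute-force reference)


@dataclass(frozen=True)
class TranscriptLocus:
    """A chain of exon intervals plus transcripts as exon-index tuples."""

    chrom: str
    exons: tuple[Interval, ...]
    transcripts: tuple[tuple[int, ...], ...]

    def junctions(self) -> set[Coord]:
        return junctions_of_transcripts(self.exons, self.transcripts)


def junctions_of_transcripts(
    exons: Sequence[Interval], transcripts: Sequence[Sequence[int]]
) -> set[Coord]:
    out: set[Coord] = set()
    for tx in transcripts:
        for i, j in zip(tx, tx[1:]):
            out.add((exons[i][1] + 1, exons[j][0] - 1))
    return out


def random_transcript_locus(
    rng: np.random.Generator,
    chrom: str = "chrO1",
    offset: int = 1000,
    max_exons: int = 8,
    max_transcripts: int = 6,
) -> TranscriptLocus:
    """A random exon chain with random transcripts through it.

    Transcripts always contain the terminal exons (shared flanks) and a
    random subset of the middle ones, so any combination of cassette,
    alt-ss-like, linked and mutually exclusive evidence can arise.
    """
    n_exons = int(rng.integers(3, max_exons + 1))
    pos = offset
    exons: list[Interval] = []
    for _ in range(n_exons):
        length = int(rng.integers(5, 200))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(30, 400))
    n_tx = int(rng.integers(2, max_transcripts + 1))
    transcripts: set[tuple[int, ...]] = set()
    for _ in range(n_tx):
        keep = [0] + [i for i in range(1, n_exons - 1) if rng.random() < 0.5] + [n_exons - 1]
        transcripts.add(tuple(keep))
    return TranscriptLocus(chrom=chrom, exons=tuple(exons), transcripts=tuple(sorted(transcripts)))


def uniform_count_table(
    junction_sets: dict[str, set[Coord]],
    count: int = 50,
    samples: Sequence[str] = ("s1", "s2"),
) -> JunctionTable:
    """Table with one constant count for every junction — evidence that
    passes any reasonable presence filter uniformly."""
    junctions = [
        Junction(chrom=chrom, start=u, end=v, strand="+", counts=np.full(len(samples), count, dtype=np.int64))
        for chrom, coords in junction_sets.items()
        for (u, v) in sorted(coords)
    ]
    return JunctionTable(junctions=junctions, samples=list(samples))
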