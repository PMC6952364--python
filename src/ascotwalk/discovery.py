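"""Junction-walking discovery of binary alternative-splicing events.

The method is exon-centric and annotation-free: junctions are grouped by
shared start or end coordinates, and closed loops are traced through
alternating introns (junctions) and exons (junction-free gaps). A binary
event is a pair of independent loops that share the same exclusion
condition. Four binary patterns are classified:

* ``cassette`` — one exon either included (two inclusion junctions) or
  skipped by a single exclusion junction;
* ``alt_ss_group`` — exon variants sharing one splice site, differing at
  the other, all skipped by the same exclusion junction;
* ``linked`` — a chain of two or more exons included or excluded as a unit
  against one exclusion junction;
* ``mutually_exclusive`` — two non-overlapping exons between common flanks
  with no junction connecting them, each loop excluding the other.

Candidates whose local splice graph is not binary (an exon that is also the
flank of a nested event, more than two mutually exclusive paths, exon
variants without a single shared boundary) are dropped and recorded in a
diagnostics report rather than forced into one of the four patterns.

All coordinates are 1-based fully closed intron coordinates; discovery is
strand-agnostic (strand is carried through for downstream orientation
only).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .junctions import Junction, JunctionTable

__all__ = [
    "DiscoveryConfig",
    "CoordinateIndex",
    "SpliceEvent",
    "DiscoveryResult",
    "build_index",
    "discover_events",
    "discover",
    "annotate_events",
    "validate_event",
]

Coord = tuple[int, int]  # (start, end) of one junction on a fixed chromosome
Interval = tuple[int, int]  # 1-based closed exon interval


@dataclass(frozen=True)
class DiscoveryConfig:
    """Tunables for event discovery.

    min_reads / min_samples: a junction participates in discovery if it has
    at least ``min_reads`` counts in at least ``min_samples`` samples.
    mxe_noise_frac: a junction connecting two candidate MXE exons counts as
    absent when its total reads fall below this fraction of the mean total
    of the four inclusion junctions.
    max_linked: maximum number of exons in a linked-exon chain.
    max_exon_span: longest candidate exon considered, in bases; bounds the
    walk so unrelated distant junctions are never bridged.
    """

    min_reads: int = 5
    min_samples: int = 1
    mxe_noise_frac: float = 0.01
    max_linked: int = 3
    max_exon_span: int = 10_000

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.min_samples < 0:
            raise ValueError("min_reads and min_samples must be non-negative")
        if not (0 <= self.mxe_noise_frac < 1):
            raise ValueError("mxe_noise_frac must be in [0, 1)")
        if self.max_linked < 2:
            raise ValueError("max_linked must be at least 2")
        if self.max_exon_span < 1:
            raise ValueError("max_exon_span must be positive")


@dataclass(frozen=True)
class SpliceEvent:
    """One classified binary splicing event.

    ``inclusion_paths`` holds one junction path per inclusion variant: a
    single path for cassette and linked events, one path per exon variant
    for an alt-ss group, and exactly two paths (upstream exon first) for a
    mutually exclusive pair. ``exon_intervals`` are the junction-inferred
    1-based closed exon coordinates, ordered genomically.
    """

    event_id: str
    event_type: str
    chrom: str
    strand: str
    inclusion_paths: tuple[tuple[Coord, ...], ...]
    exclusion_junctions: tuple[Coord, ...]
    exon_intervals: tuple[Interval, ...]
    annotated: str = "unknown"

    @property
    def inclusion_junctions(self) -> tuple[Coord, ...]:
        seen: dict[Coord, None] = {}
        for path in self.inclusion_paths:
            for j in path:
                seen.setdefault(j, None)
        return tuple(seen)

    @property
    def span(self) -> Interval:
        left = min(j[0] for p in self.inclusion_paths for j in p)
        right = max(j[1] for p in self.inclusion_paths for j in p)
        return (left, right)


@dataclass
class CoordinateIndex:
    """Two-way junction index: shared left (start) and right (end) coords."""

    by_left: dict[tuple[str, int], list[Coord]]
    by_right: dict[tuple[str, int], list[Coord]]


@dataclass
class DiscoveryResult:
    events: list[SpliceEvent]
    diagnostics: list[dict] = field(default_factory=list)


def build_index(table: JunctionTable) -> CoordinateIndex:
    by_left: dict[tuple[str, int], list[Coord]] = {}
    by_right: dict[tuple[str, int], list[Coord]] = {}
    for j in table.junctions:
        by_left.setdefault((j.chrom, j.start), []).append((j.start, j.end))
        by_right.setdefault((j.chrom, j.end), []).append((j.start, j.end))
    for bucket in by_left.values():
        bucket.sort(key=lambda c: c[1])
    for bucket in by_right.values():
        bucket.sort(key=lambda c: c[0])
    return CoordinateIndex(by_left=by_left, by_right=by_right)


def passes_presence(j: Junction, config: DiscoveryConfig) -> bool:
    return int((j.counts >= config.min_reads).sum()) >= config.min_samples


def _event_id(event_type: str, chrom: str, flanks: Coord, exons: Sequence[Interval]) -> str:
    exon_str = ";".join(f"{a}-{b}" for a, b in exons)
    return f"{event_type}|{chrom}|{flanks[0]}-{flanks[1]}|{exon_str}"


class _ChromGraph:
    """Per-chromosome junction evidence used by the walker.

    ``present``: junctions passing the presence filter (the discovery
    graph). ``totals``: total read counts for *all* junctions, used only by
    the MXE noise rule.
    """

    def __init__(
        self,
        present: set[Coord],
        totals: Mapping[Coord, float],
        config: DiscoveryConfig,
    ):
        self.present = present
        self.totals = totals
        self.config = config
        self.sorted_by_start = sorted(present)
        self._starts = [c[0] for c in self.sorted_by_start]
        self.by_left: dict[int, list[Coord]] = {}
        for c in self.sorted_by_start:
            self.by_left.setdefault(c[0], []).append(c)

    def exon_is_valid(self, x: int, y: int) -> bool:
        """True when [x, y] is non-empty and no junction lies wholly inside
        it (no intron evidence within the putative exon)."""
        if x > y:
            return False
        i = bisect_left(self._starts, x)
        while i < len(self.sorted_by_start):
            u, v = self.sorted_by_start[i]
            if u > y:
                break
            if v <= y:
                return False
            i += 1
        return True

    def junctions_starting_in(self, lo: int, hi: int) -> Iterable[Coord]:
        i = bisect_left(self._starts, lo)
        while i < len(self.sorted_by_start):
            c = self.sorted_by_start[i]
            if c[0] > hi:
                break
            yield c
            i += 1

    def enumerate_paths(self) -> dict[Coord, list[tuple[tuple[Coord, ...], tuple[Interval, ...]]]]:
        """All inclusion paths, grouped by flank pair (s, e).

        A path is an alternating chain junction/exon/junction/... from s to
        e with 1..max_linked junction-free, non-empty exons. Each prefix of
        a longer chain that ends on a junction is itself a path for its own
        flank pair.
        """
        out: dict[Coord, list[tuple[tuple[Coord, ...], tuple[Interval, ...]]]] = {}

        def extend(s: int, a: int, js: tuple[Coord, ...], exons: tuple[Interval, ...]) -> None:
            # previous junction ended at a; next junction (d, b) needs
            # d >= a + 2 and a junction-free exon [a + 1, d - 1] no longer
            # than max_exon_span
            for d, b in self.junctions_starting_in(a + 2, a + 1 + self.config.max_exon_span):
                exon = (a + 1, d - 1)
                if not self.exon_is_valid(*exon):
                    continue
                path = (js + ((d, b),), exons + (exon,))
                out.setdefault((s, b), []).append(path)
                if len(path[1]) < self.config.max_linked:
                    extend(s, b, *path)

        for s, bucket in self.by_left.items():
            for s0, a1 in bucket:
                extend(s, a1, ((s0, a1),), ())
        return out

    def mxe_connector_absent(self, exon_a: Interval, exon_b: Interval, incl: Sequence[Coord]) -> bool:
        connector = (exon_a[1] + 1, exon_b[0] - 1)
        total = float(self.totals.get(connector, 0.0))
        mean_incl = float(np.mean([self.totals.get(j, 0.0) for j in incl]))
        return total < self.config.mxe_noise_frac * mean_incl


def _components_by_boundary(exons: list[Interval]) -> list[list[Interval]]:
    """Group exon intervals into connected components under the
    shares-a-boundary relation (same start or same end)."""
    parent = {e: e for e in exons}

    def find(e):
        while parent[e] != e:
            parent[e] = parent[parent[e]]
            e = parent[e]
        return e

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i, a in enumerate(exons):
        for b in exons[i + 1 :]:
            if a[0] == b[0] or a[1] == b[1]:
                union(a, b)
    groups: dict[Interval, list[Interval]] = {}
    for e in exons:
        groups.setdefault(find(e), []).append(e)
    return [sorted(g) for g in groups.values()]


def _discover_chrom(
    chrom: str,
    graph: _ChromGraph,
    strand_of: Mapping[Coord, str],
    diagnostics: list[dict],
) -> list[SpliceEvent]:
    config = graph.config
    paths_by_flanks = graph.enumerate_paths()
    events: list[SpliceEvent] = []

    def member_strand(junctions: Iterable[Coord]) -> str:
        strands = {strand_of.get(j, ".") for j in junctions} - {"."}
        return strands.pop() if len(strands) == 1 else "."

    def diag(reason: str, flanks: Coord, exons) -> None:
        diagnostics.append(
            {"reason": reason, "chrom": chrom, "flanks": flanks, "exons": exons}
        )

    def has_nested_event(s2: int, e2: int) -> bool:
        return bool(paths_by_flanks.get((s2, e2)))

    def nested_flank(exon: Interval, s: int, e: int) -> bool:
        """True when this candidate exon is the flank of a nested event
        inside the exclusion span (s, e): some *other* junction within the
        span starts right after the exon (exon = left flank) or ends right
        before it (exon = right flank) and itself skips a nested path."""
        x, y = exon
        for s2, e2 in graph.junctions_starting_in(y + 1, y + 1):
            if (s2, e2) != (s, e) and e2 <= e and has_nested_event(s2, e2):
                return True
        for s2, e2 in graph.junctions_starting_in(s, e):
            if e2 == x - 1 and (s2, e2) != (s, e) and has_nested_event(s2, e2):
                return True
        return False

    for (s, e), paths in sorted(paths_by_flanks.items()):
        singles = [(p, exs[0]) for p, exs in paths if len(exs) == 1]
        multis = [(p, exs) for p, exs in paths if len(exs) >= 2]
        path_of = {exon: p for p, exon in singles}
        excl_present = (s, e) in graph.present

        # --- mutually exclusive pairs across this flank pair -------------
        mxe_pairs: list[tuple[Interval, Interval]] = []
        for i, (_, ex_a) in enumerate(singles):
            for _, ex_b in singles[i + 1 :]:
                a, b = sorted((ex_a, ex_b))
                if a[1] >= b[0]:
                    continue  # overlapping -> not mutually exclusive
                incl = path_of[a] + path_of[b]
                if graph.mxe_connector_absent(a, b, incl):
                    mxe_pairs.append((a, b))
        def overlaps(u: Interval, v: Interval) -> bool:
            return u[0] <= v[1] and v[0] <= u[1]

        suppressed: set[Interval] = set()
        if len(mxe_pairs) == 1:
            a, b = mxe_pairs[0]
            members = path_of[a] + path_of[b]
            excl = ((s, e),) if excl_present else ()
            events.append(
                SpliceEvent(
                    event_id=_event_id("mutually_exclusive", chrom, (s, e), (a, b)),
                    event_type="mutually_exclusive",
                    chrom=chrom,
                    strand=member_strand(members + excl),
                    inclusion_paths=(path_of[a], path_of[b]),
                    exclusion_junctions=excl,
                    exon_intervals=(a, b),
                )
            )
            # alternative single-exon readings of the same loops (the MXE
            # exons themselves and anything overlapping them) are not
            # independent binary events under these flanks
            suppressed |= {x for _, x in singles if overlaps(x, a) or overlaps(x, b)}
            if excl_present:
                diag("mxe_precedence", (s, e), [a, b])
        elif mxe_pairs:
            involved = sorted({x for pair in mxe_pairs for x in pair})
            diag("mxe_multi", (s, e), involved)
            suppressed |= {
                x
                for _, x in singles
                if any(overlaps(x, inv) for inv in involved)
            }

        if not excl_present:
            continue

        # --- cassette / alt-ss / linked under exclusion junction (s, e) --
        kept: list[Interval] = []
        for _, exon in singles:
            if exon in suppressed:
                continue
            if nested_flank(exon, s, e):
                diag("nested_flank", (s, e), [exon])
                continue
            kept.append(exon)

        for component in _components_by_boundary(kept):
            if len(component) == 1:
                exon = component[0]
                events.append(
                    SpliceEvent(
                        event_id=_event_id("cassette", chrom, (s, e), [exon]),
                        event_type="cassette",
                        chrom=chrom,
                        strand=member_strand(path_of[exon] + ((s, e),)),
                        inclusion_paths=(path_of[exon],),
                        exclusion_junctions=((s, e),),
                        exon_intervals=(exon,),
                    )
                )
            elif len({x for x, _ in component}) == 1 or len({y for _, y in component}) == 1:
                members = tuple(j for exon in component for j in path_of[exon])
                events.append(
                    SpliceEvent(
                        event_id=_event_id("alt_ss_group", chrom, (s, e), component),
                        event_type="alt_ss_group",
                        chrom=chrom,
                        strand=member_strand(members + ((s, e),)),
                        inclusion_paths=tuple(path_of[exon] for exon in component),
                        exclusion_junctions=((s, e),),
                        exon_intervals=tuple(component),
                    )
                )
            else:
                diag("alt_ss_complex", (s, e), component)

        for path, exons in multis:
            events.append(
                SpliceEvent(
                    event_id=_event_id("linked", chrom, (s, e), exons),
                    event_type="linked",
                    chrom=chrom,
                    strand=member_strand(path + ((s, e),)),
                    inclusion_paths=(path,),
                    exclusion_junctions=((s, e),),
                    exon_intervals=exons,
                )
            )

    return events


def discover(table: JunctionTable, config: DiscoveryConfig | None = None) -> DiscoveryResult:
    """Run junction-walking discovery; returns events plus diagnostics on
    candidates dropped as non-binary."""
    config = config or DiscoveryConfig()
    by_chrom: dict[str, list[Junction]] = {}
    for j in table.junctions:
        by_chrom.setdefault(j.chrom, []).append(j)

    events: list[SpliceEvent] = []
    diagnostics: list[dict] = []
    for chrom in sorted(by_chrom):
        junctions = by_chrom[chrom]
        present = {(j.start, j.end) for j in junctions if passes_presence(j, config)}
        totals: dict[Coord, float] = {}
        strand_of: dict[Coord, str] = {}
        for j in junctions:
            coord = (j.start, j.end)
            totals[coord] = totals.get(coord, 0.0) + float(j.counts.sum())
            prev = strand_of.get(coord)
            if prev is None or prev == ".":
                strand_of[coord] = j.strand
            elif j.strand not in (".", prev):
                strand_of[coord] = "."
        if not present:
            continue
        graph = _ChromGraph(present, totals, config)
        events.extend(_discover_chrom(chrom, graph, strand_of, diagnostics))

    unique: dict[str, SpliceEvent] = {}
    for event in events:
        unique.setdefault(event.event_id, event)
    ordered = sorted(
        unique.values(),
        key=lambda ev: (ev.chrom, ev.exon_intervals[0][0], ev.exon_intervals[-1][1], ev.event_id),
    )
    for event in ordered:
        validate_event(event)
    return DiscoveryResult(events=ordered, diagnostics=diagnostics)


def discover_events(table: JunctionTable, config: DiscoveryConfig | None = None) -> list[SpliceEvent]:
    return discover(table, config).events


def validate_event(event: SpliceEvent) -> None:
    """Check the per-type structural invariants; raises on violation."""
    incl = set(event.inclusion_junctions)
    excl = set(event.exclusion_junctions)
    if incl & excl:
        raise ValueError(f"{event.event_id}: inclusion and exclusion junctions overlap")
    intervals = sorted(event.exon_intervals)
    for a, b in intervals:
        if a > b:
            raise ValueError(f"{event.event_id}: empty exon interval {a}-{b}")
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if event.event_type != "alt_ss_group" and b1 >= a2:
            raise ValueError(f"{event.event_id}: overlapping exon intervals")
    span = event.span
    for a, b in intervals:
        if not (span[0] < a and b < span[1]):
            raise ValueError(f"{event.event_id}: exon outside the event span")
    t = event.event_type
    n_paths = len(event.inclusion_paths)
    if t == "cassette":
        ok = n_paths == 1 and len(event.inclusion_paths[0]) == 2 and len(excl) == 1 and len(intervals) == 1
    elif t == "linked":
        k = len(event.exon_intervals)
        ok = n_paths == 1 and k >= 2 and len(event.inclusion_paths[0]) == k + 1 and len(excl) == 1
    elif t == "alt_ss_group":
        ok = n_paths >= 2 and len(excl) == 1 and len(event.exon_intervals) == n_paths
    elif t == "mutually_exclusive":
        ok = (
            n_paths == 2
            and all(len(p) == 2 for p in event.inclusion_paths)
            and len(excl) <= 1
        )
    else:
        ok = False
    if not ok:
        raise ValueError(f"{event.event_id}: violates {t} structure")


def write_events_tsv(events: Sequence[SpliceEvent], path, header_comment: str | None = None) -> None:
    """Serialize events to TSV (round-trips with :func:`read_events_tsv`)."""
    with open(path, "w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        handle.write(
            "event_id\tevent_type\tchrom\tstrand\tannotated\t"
            "exon_intervals\tinclusion_paths\texclusion_junctions\n"
        )
        for ev in events:
            exons = ";".join(f"{a}-{b}" for a, b in ev.exon_intervals)
            paths = "|".join(
                ",".join(f"{u}-{v}" for u, v in path) for path in ev.inclusion_paths
            )
            excl = ";".join(f"{u}-{v}" for u, v in ev.exclusion_junctions)
            handle.write(
                f"{ev.event_id}\t{ev.event_type}\t{ev.chrom}\t{ev.strand}\t"
                f"{ev.annotated}\t{exons}\t{paths}\t{excl}\n"
            )


def _parse_pairs(text: str) -> tuple[Coord, ...]:
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        a, b = token.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def read_events_tsv(path) -> list[SpliceEvent]:
    events = []
    with open(path) as handle:
        header: list[str] | None = None
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            try:
                paths = tuple(
                    tuple((int(u), int(v)) for u, v in (t.split("-") for t in p.split(",")))
                    for p in rec["inclusion_paths"].split("|")
                )
                events.append(
                    SpliceEvent(
                        event_id=rec["event_id"],
                        event_type=rec["event_type"],
                        chrom=rec["chrom"],
                        strand=rec["strand"],
                        annotated=rec["annotated"],
                        inclusion_paths=paths,
                        exon_intervals=_parse_pairs(rec["exon_intervals"]),
                        exclusion_junctions=_parse_pairs(rec["exclusion_junctions"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed event row ({exc})") from None
    return events


def annotate_events(
    events: Sequence[SpliceEvent],
    annotation_exons: set[tuple[str, int, int]] | None,
) -> list[SpliceEvent]:
    """Flag events against an annotation exon set.

    An event is ``annotated`` iff *every* exon interval matches an
    annotation exon exactly (chrom, start and end); otherwise
    ``unannotated``. With no annotation supplied the flag is ``unknown``.
    """
    if annotation_exons is None:
        return [replace(ev, annotated="unknown") for ev in events]
    out = []
    for ev in events:
        hit = all((ev.chrom, a, b) in annotation_exons for a, b in ev.exon_intervals)
        out.append(replace(ev, annotated="annotated" if hit else "unannotated"))
    return out
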