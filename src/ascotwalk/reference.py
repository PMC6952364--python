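"""Brute-force reference enumeration of binary splicing events.

A deliberately slow, index-free second route to the event definitions,
used to validate the junction-walking implementation: paths are found by
exhaustive recursion over the whole junction list, exon validity by a full
scan, and the classification rules are applied literally per flank pair.
Intended for small loci (unit of validation: one synthetic locus derived
from known transcript structures); never use it on real tables.

The enumeration assumes every junction in the input set carries evidence
comfortably above the presence and MXE-noise thresholds, as is the case
for the uniform-count tables the validation harness builds.
"""

from __future__ import annotations

from itertools import combinations

from .discovery import DiscoveryConfig

Coord = tuple[int, int]
Interval = tuple[int, int]

__all__ = ["bruteforce_event_ids"]


def bruteforce_event_ids(
    chrom: str,
    junctions: set[Coord],
    config: DiscoveryConfig | None = None,
) -> set[str]:
    """Enumerate event ids implied by a junction set, by brute force."""
    config = config or DiscoveryConfig()
    J = sorted(junctions)

    def exon_ok(x: int, y: int) -> bool:
        if x > y or (y - x + 1) > config.max_exon_span:
            return False
        return not any(x <= u and v <= y for u, v in J)

    # every alternating junction/exon chain, keyed by (first start, last end)
    chains: dict[Coord, list[tuple[tuple[Coord, ...], tuple[Interval, ...]]]] = {}

    def grow(chain: list[Coord], exons: list[Interval]) -> None:
        a = chain[-1][1]
        for d, b in J:
            if d < a + 2:
                continue
            exon = (a + 1, d - 1)
            if not exon_ok(*exon):
                continue
            nxt_chain, nxt_exons = chain + [(d, b)], exons + [exon]
            chains.setdefault((nxt_chain[0][0], b), []).append(
                (tuple(nxt_chain), tuple(nxt_exons))
            )
            if len(nxt_exons) < config.max_linked:
                grow(nxt_chain, nxt_exons)

    for j in J:
        grow([j], [])

    def eid(event_type: str, flanks: Coord, exons) -> str:
        exon_str = ";".join(f"{a}-{b}" for a, b in exons)
        return f"{event_type}|{chrom}|{flanks[0]}-{flanks[1]}|{exon_str}"

    def nested_event_between(s2: int, e2: int) -> bool:
        return bool(chains.get((s2, e2)))

    ids: set[str] = set()
    for (s, e), paths in chains.items():
        singles = sorted({exs[0] for _, exs in paths if len(exs) == 1})
        multis = [exs for _, exs in paths if len(exs) >= 2]
        excl_present = (s, e) in junctions

        mxe_pairs = [
            (a, b)
            for a, b in combinations(singles, 2)
            if a[1] < b[0] and (a[1] + 1, b[0] - 1) not in junctions
        ]
        def overlaps(u, v):
            return u[0] <= v[1] and v[0] <= u[1]

        suppressed: set[Interval] = set()
        if len(mxe_pairs) == 1:
            a, b = mxe_pairs[0]
            ids.add(eid("mutually_exclusive", (s, e), (a, b)))
            suppressed |= {x for x in singles if overlaps(x, a) or overlaps(x, b)}
        elif mxe_pairs:
            involved = {x for pair in mxe_pairs for x in pair}
            suppressed |= {
                x for x in singles if any(overlaps(x, inv) for inv in involved)
            }

        if not excl_present:
            continue

        kept = []
        for x, y in singles:
            if (x, y) in suppressed:
                continue
            flank_of_nested = any(
                (s2, e2) != (s, e)
                and s <= s2
                and e2 <= e
                and (s2 == y + 1 or e2 == x - 1)
                and nested_event_between(s2, e2)
                for s2, e2 in J
            )
            if not flank_of_nested:
                kept.append((x, y))

        # connected components under the shares-a-boundary relation
        remaining = set(kept)
        while remaining:
            component = {remaining.pop()}
            changed = True
            while changed:
                changed = False
                for cand in list(remaining):
                    if any(cand[0] == m[0] or cand[1] == m[1] for m in component):
                        component.add(cand)
                        remaining.discard(cand)
                        changed = True
            members = sorted(component)
            if len(members) == 1:
                ids.add(eid("cassette", (s, e), members))
            elif len({x for x, _ in members}) == 1 or len({y for _, y in members}) == 1:
                ids.add(eid("alt_ss_group", (s, e), members))
            # else: non-binary alt-ss complex, not an event

        for exons in multis:
            ids.add(eid("linked", (s, e), exons))

    return ids
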