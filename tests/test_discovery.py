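"""Junction-walking discovery: hand-built loops, invariances, reference
agreement, annotation flags, event serialization."""

import numpy as np
import pytest

from ascotwalk.annotation import exon_key_set, load_gtf_exons
from ascotwalk.discovery import (
    DiscoveryConfig,
    annotate_events,
    build_index,
    discover,
    discover_events,
    read_events_tsv,
    validate_event,
    write_events_tsv,
)
from ascotwalk.junctions import JunctionTable
from ascotwalk.reference import bruteforce_event_ids
from ascotwalk.simulate import (
    random_transcript_locus,
    random_truth,
    simulate_table,
    uniform_count_table,
)


def table_of(coords, **kw):
    return uniform_count_table({"chr1": set(coords)}, **kw)


class TestIndex:
    def test_shared_start_bucket(self, make_table):
        table = make_table({"chr1": [(1000, 2000), (1000, 3000)]})
        index = build_index(table)
        assert [c for c in index.by_left[("chr1", 1000)]] == [(1000, 2000), (1000, 3000)]

    def test_empty_table(self):
        index = build_index(JunctionTable(junctions=[], samples=["s1"]))
        assert not index.by_left and not index.by_right

    def test_every_junction_retrievable_both_ways(self):
        rng = np.random.default_rng(0)
        coords = {(int(a), int(a) + int(b)) for a, b in zip(rng.integers(1, 9999, 60), rng.integers(25, 900, 60))}
        table = table_of(coords)
        index = build_index(table)
        for j in table.junctions:
            assert (j.start, j.end) in index.by_left[(j.chrom, j.start)]
            assert (j.start, j.end) in index.by_right[(j.chrom, j.end)]


class TestWalkingPatterns:
    def test_cassette_loop(self):
        events = discover_events(table_of([(100, 199), (100, 149), (160, 199)]))
        (ev,) = events
        assert ev.event_type == "cassette"
        assert ev.exon_intervals == ((150, 159),)
        assert ev.inclusion_paths == (((100, 149), (160, 199)),)
        assert ev.exclusion_junctions == ((100, 199),)

    def test_alt_ss_group_merges_variants_sharing_a_boundary(self):
        events = discover_events(table_of([(100, 199), (100, 149), (160, 199), (100, 144)]))
        (ev,) = events
        assert ev.event_type == "alt_ss_group"
        assert ev.exon_intervals == ((145, 159), (150, 159))
        assert ev.exclusion_junctions == ((100, 199),)

    def test_mutually_exclusive_pair_without_direct_junction(self):
        events = discover_events(table_of([(100, 149), (160, 199), (100, 169), (180, 199)]))
        (ev,) = events
        assert ev.event_type == "mutually_exclusive"
        assert ev.exon_intervals == ((150, 159), (170, 179))
        assert ev.exclusion_junctions == ()

    def test_mxe_suppresses_cassette_reading_of_its_exons(self):
        # same pair plus the direct exclusion junction: still one MXE, the
        # two lone-cassette interpretations are suppressed into diagnostics
        result = discover(table_of([(100, 149), (160, 199), (100, 169), (180, 199), (100, 199)]))
        assert [e.event_type for e in result.events] == ["mutually_exclusive"]
        assert result.events[0].exclusion_junctions == ((100, 199),)
        assert any(d["reason"] == "mxe_precedence" for d in result.diagnostics)

    def test_connected_mxe_candidates_become_linked_chain(self):
        # a junction joining the two exons means they are not mutually
        # exclusive: the chain through both is a linked unit, and each
        # exon is separately a cassette against its own local exclusion
        events = discover_events(
            table_of([(100, 149), (160, 199), (100, 169), (180, 199), (160, 169), (100, 199)])
        )
        by_type = {}
        for ev in events:
            by_type.setdefault(ev.event_type, []).append(ev)
        (linked,) = by_type["linked"]
        assert linked.exon_intervals == ((150, 159), (170, 179))
        assert linked.exclusion_junctions == ((100, 199),)
        assert sorted(
            (c.exon_intervals, c.exclusion_junctions) for c in by_type["cassette"]
        ) == [
            (((150, 159),), ((100, 169),)),
            (((170, 179),), ((160, 199),)),
        ]
        assert set(by_type) == {"linked", "cassette"}

    def test_linked_chain_of_three(self):
        junctions = [(100, 149), (160, 209), (220, 269), (280, 329), (100, 329)]
        (ev,) = discover_events(table_of(junctions))
        assert ev.event_type == "linked"
        assert ev.exon_intervals == ((150, 159), (210, 219), (270, 279))
        assert len(ev.inclusion_paths[0]) == 4

    def test_presence_filter_excludes_weak_junctions(self, make_table):
        coords = [(100, 199), (100, 149), (160, 199)]
        table = make_table(
            {"chr1": coords}, counts_by_coord={(160, 199): [2, 2]}, default=30
        )
        assert discover_events(table, DiscoveryConfig(min_reads=5)) == []
        assert len(discover_events(table, DiscoveryConfig(min_reads=1))) == 1

    def test_candidate_exon_with_internal_junction_rejected(self):
        # the skipped region contains its own intron -> not a single exon
        events = discover_events(table_of([(100, 299), (100, 149), (260, 299), (180, 219)]))
        assert all(ev.exon_intervals != ((150, 259),) for ev in events)


class TestInvariances:
    def test_row_and_column_order_invariance(self, toy_table):
        base = discover_events(toy_table)
        shuffled = JunctionTable(
            junctions=list(reversed(toy_table.junctions)),
            samples=list(reversed(toy_table.samples)),
        )
        assert discover_events(shuffled) == base

    def test_locality_across_chromosomes(self):
        chr1 = {(100, 199), (100, 149), (160, 199)}
        alone = discover_events(uniform_count_table({"chr1": chr1}))
        with_more = discover_events(
            uniform_count_table({"chr1": chr1, "chr9": {(100, 199), (100, 149), (160, 199), (50, 500)}})
        )
        assert [e for e in with_more if e.chrom == "chr1"] == alone

    def test_emitted_events_satisfy_type_invariants(self):
        rng = np.random.default_rng(5)
        for i in range(60):
            locus = random_transcript_locus(rng, chrom=f"c{i}")
            for ev in discover_events(uniform_count_table({locus.chrom: locus.junctions()})):
                validate_event(ev)


class TestReferenceAgreement:
    def test_discovery_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(123)
        for i in range(150):
            locus = random_transcript_locus(rng, chrom=f"c{i}")
            junctions = locus.junctions()
            got = {e.event_id for e in discover_events(uniform_count_table({locus.chrom: junctions}))}
            want = bruteforce_event_ids(locus.chrom, junctions)
            assert got == want, f"locus {i}: {locus.transcripts}"


class TestAnnotationFlag:
    GTF = (
        'chr1\tx\texon\t150\t159\t.\t+\t.\tgene_id "g"; transcript_id "t"; gene_type "protein_coding";\n'
    )

    def exon_keys(self, tmp_path, text):
        p = tmp_path / "a.gtf"
        p.write_text(text)
        return exon_key_set(load_gtf_exons(p))

    def test_exact_match_is_annotated(self, tmp_path, toy_table):
        events = discover_events(toy_table)
        flagged = annotate_events(events, self.exon_keys(tmp_path, self.GTF))
        assert flagged[0].annotated == "annotated"

    def test_boundary_mismatch_is_unannotated(self, tmp_path, toy_table):
        events = discover_events(toy_table)
        keys = self.exon_keys(tmp_path, self.GTF.replace("\t159\t", "\t160\t"))
        assert annotate_events(events, keys)[0].annotated == "unannotated"

    def test_no_annotation_is_unknown(self, toy_table):
        events = discover_events(toy_table)
        assert annotate_events(events, None)[0].annotated == "unknown"

    def test_unparseable_gtf_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(self.GTF + "chr1\tbroken\n")
        with pytest.raises(ValueError, match=r"bad\.gtf:2"):
            load_gtf_exons(p)


class TestEventsTsv:
    def test_round_trip(self, tmp_path):
        truth = random_truth(10, {"g": 2}, seed=17)
        table, _ = simulate_table(truth)
        events = discover_events(table)
        path = tmp_path / "events.tsv"
        write_events_tsv(events, path)
        assert read_events_tsv(path) == events
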