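"""Junction-table I/O: STAR SJ dialect, matrix round-trips, PSI serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ascotwalk.discovery import discover_events
from ascotwalk.junctions import (
    Junction,
    JunctionTable,
    read_junction_matrix,
    read_sample_metadata,
    read_star_sj,
    write_junction_matrix,
    write_psi_matrix,
)
from ascotwalk.psi import psi_matrix


def sj_line(chrom, start, end, strand_code, unique, multi=3):
    return f"{chrom}\t{start}\t{end}\t{strand_code}\t2\t1\t{unique}\t{multi}\n"


class TestStarSJ:
    def test_union_of_identical_keys_merges_counts(self, tmp_path):
        a = tmp_path / "a.tab"
        b = tmp_path / "b.tab"
        a.write_text(sj_line("chr1", 1000, 2000, 1, 10))
        b.write_text(sj_line("chr1", 1000, 2000, 1, 4))
        table = read_star_sj([a, b], ["s1", "s2"])
        assert len(table) == 1
        assert table.junctions[0].counts.tolist() == [10, 4]
        assert table.junctions[0].strand == "+"

    def test_zero_fill_for_absent_junction(self, tmp_path):
        a = tmp_path / "a.tab"
        b = tmp_path / "b.tab"
        a.write_text(sj_line("chr1", 1000, 2000, 1, 7))
        b.write_text(sj_line("chr1", 1000, 3000, 1, 5))
        table = read_star_sj([a, b], ["s1", "s2"])
        counts = {(j.start, j.end): j.counts.tolist() for j in table.junctions}
        assert counts == {(1000, 2000): [7, 0], (1000, 3000): [0, 5]}

    def test_unknown_strand_code_retained(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text(sj_line("chr1", 500, 900, 0, 6))
        table = read_star_sj([p], ["s1"])
        assert table.junctions[0].strand == "."

    def test_multimapped_counts_discarded(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text(sj_line("chr1", 500, 900, 1, 6, multi=99))
        table = read_star_sj([p], ["s1"])
        assert table.junctions[0].counts.tolist() == [6]

    def test_short_intron_filtered(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text(sj_line("chr1", 500, 510, 1, 6) + sj_line("chr1", 500, 519, 1, 6))
        table = read_star_sj([p], ["s1"])
        # 500-519 is exactly 20 bases long and survives; 500-510 does not
        assert [(j.start, j.end) for j in table.junctions] == [(500, 519)]

    def test_malformed_line_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text(sj_line("chr1", 500, 900, 1, 6) + "chr1\toops\n")
        with pytest.raises(ValueError, match=r"bad\.tab:2"):
            read_star_sj([p], ["s1"])

    def test_duplicate_or_mismatched_sample_ids_rejected(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text(sj_line("chr1", 500, 900, 1, 6))
        with pytest.raises(ValueError, match="duplicate"):
            read_star_sj([p, p], ["s1", "s1"])
        with pytest.raises(ValueError, match="sample ids"):
            read_star_sj([p], ["s1", "s2"])

    def test_union_load_order_invariant(self, tmp_path, make_table):
        files = []
        for i, coords in enumerate([{(100, 300)}, {(100, 300), (400, 600)}, {(400, 600)}]):
            p = tmp_path / f"f{i}.tab"
            p.write_text("".join(sj_line("chr1", u, v, 1, 5 + i) for u, v in sorted(coords)))
            files.append(p)
        fwd = read_star_sj(files, ["a", "b", "c"])
        rev = read_star_sj(files[::-1], ["c", "b", "a"])
        for j in fwd.junctions:
            k = next(x for x in rev.junctions if x.key == j.key)
            assert {s: c for s, c in zip(fwd.samples, j.counts)} == {
                s: c for s, c in zip(rev.samples, k.counts)
            }


junction_tables = st.builds(
    lambda coords, n_samples, counts_seed: _random_table(coords, n_samples, counts_seed),
    st.sets(
        st.tuples(st.integers(1, 5000), st.integers(30, 800)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=0,
        max_size=12,
    ),
    st.integers(1, 4),
    st.integers(0, 10_000),
)


def _random_table(coords, n_samples, counts_seed):
    rng = np.random.default_rng(counts_seed)
    junctions = [
        Junction(
            chrom="chr1",
            start=u,
            end=v,
            strand=rng.choice(["+", "-", "."]),
            counts=rng.integers(0, 500, size=n_samples),
        )
        for u, v in sorted(coords)
    ]
    return JunctionTable(junctions=junctions, samples=[f"s{i}" for i in range(n_samples)])


class TestMatrixRoundTrip:
    @settings(max_examples=40, derandomize=True)
    @given(table=junction_tables)
    def test_write_read_identity(self, tmp_path_factory, table):
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_junction_matrix(table, path)
        back = read_junction_matrix(path)
        assert back.samples == table.samples
        assert [j.key for j in back.junctions] == [j.key for j in table.junctions]
        for a, b in zip(back.junctions, table.junctions):
            assert a.counts.tolist() == b.counts.tolist()

    def test_metadata_groups(self, tmp_path, toy_table):
        mat = tmp_path / "m.tsv"
        meta = tmp_path / "meta.tsv"
        write_junction_matrix(toy_table, mat)
        meta.write_text("sample_id\tgroup\ns1\trod\ns2\trod\n")
        table = read_junction_matrix(mat, meta)
        assert table.groups == {"s1": "rod", "s2": "rod"}

    def test_metadata_unknown_sample_errors_and_missing_is_ungrouped(self, tmp_path, toy_table):
        mat = tmp_path / "m.tsv"
        write_junction_matrix(toy_table, mat)
        meta = tmp_path / "meta.tsv"
        meta.write_text("sample_id\tgroup\ns1\trod\nzz\tbrain\n")
        with pytest.raises(ValueError, match="zz"):
            read_junction_matrix(mat, meta)
        meta.write_text("sample_id\tgroup\ns1\trod\n")
        table = read_junction_matrix(mat, meta)
        assert table.groups["s2"] == "ungrouped"

    def test_non_integer_count_errors_with_coordinates(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tstart\tend\tstrand\ts1\nchr1\t100\t300\t+\t3.7\n")
        with pytest.raises(ValueError, match="chr1:100-300"):
            read_junction_matrix(p)

    def test_missing_header_columns_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tstart\ts1\nchr1\t100\t5\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_junction_matrix(p)

    def test_duplicate_metadata_sample_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\tgroup\ns1\ta\ns1\tb\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_metadata(p)


class TestPsiSerialization:
    def test_values_missing_and_empty(self, tmp_path, toy_table):
        events = discover_events(toy_table)
        psi = psi_matrix(events, toy_table, min_informative=15)
        out = tmp_path / "psi.tsv"
        write_psi_matrix(psi, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t")[-2:] == ["s1", "s2"]
        assert lines[1].split("\t")[-2:] == ["50.0", "50.0"]

        psi.psi[0, 1] = np.nan
        write_psi_matrix(psi, out)
        assert out.read_text().splitlines()[1].split("\t")[-2:] == ["50.0", "NA"]

        empty = psi_matrix([], toy_table)
        write_psi_matrix(empty, out)
        assert len(out.read_text().splitlines()) == 1
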