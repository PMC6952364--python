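"""Positional motif windows: extraction, counting, baselines, enrichment."""

import numpy as np
import pytest

from ascotwalk.discovery import SpliceEvent
from ascotwalk.motifs import (
    MOTIF_PRESETS,
    attach_baseline,
    baseline_profile,
    extract_windows,
    positional_profile,
    proximal_enrichment,
)
from ascotwalk.simulate import (
    MotifPlant,
    random_truth,
    simulate_genome,
    simulate_table,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def make_event(chrom, exon, strand, flank=500):
    x, y = exon
    return SpliceEvent(
        event_id=f"cassette|{chrom}|{x - flank}-{y + flank}|{x}-{y}",
        event_type="cassette",
        chrom=chrom,
        strand=strand,
        inclusion_paths=(((x - flank, x - 1), (y + 1, y + flank)),),
        exclusion_junctions=((x - flank, y + flank),),
        exon_intervals=((x, y),),
    )


class TestExtractWindows:
    def test_short_exon_clips_exonic_windows_at_midpoint(self):
        genome = {"chr1": "A" * 400}
        w = extract_windows("chr1", (150, 159), "+", genome)
        seq, positions = w[("5prime_ss", "exonic")]
        assert len(seq) == 5 and positions == [5, 4, 3, 2, 1]
        seq, positions = w[("3prime_ss", "exonic")]
        assert len(seq) == 5 and positions == [1, 2, 3, 4, 5]

    def test_minus_strand_is_reverse_complement_of_mirror(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        genome = {"chr1": seq}
        exon = (1400, 1479)
        plus = extract_windows("chr1", exon, "+", genome)
        minus = extract_windows("chr1", exon, "-", genome)
        # the minus 5'SS intron is the revcomp of the plus 3'SS intron
        assert minus[("5prime_ss", "intronic")][0] == revcomp(plus[("3prime_ss", "intronic")][0])
        assert minus[("3prime_ss", "intronic")][0] == revcomp(plus[("5prime_ss", "intronic")][0])

    def test_window_truncated_at_chromosome_start(self):
        genome = {"chr1": "A" * 400}
        w = extract_windows("chr1", (120, 179), "+", genome)
        seq, positions = w[("3prime_ss", "intronic")]
        assert len(seq) == 119 and positions[0] == -119 and positions[-1] == -1

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            extract_windows("chr1", (120, 179), ".", {"chr1": "A" * 300})


class TestCounting:
    def count(self, seq, motif="TAG"):
        genome = {"chr1": seq + "X" * 0}
        # put the sequence as a 5'SS intron: exon ends right before it
        pad = "C" * 60
        genome = {"chr1": pad + seq + "C" * 1100}
        event = make_event("chr1", (11, 60), "+", flank=10)
        prof = positional_profile([event], genome, motif, intronic_flank=1000)
        return int(prof["5prime_ss"].counts.sum())

    def test_overlapping_occurrences_counted(self):
        assert self.count("TAGTAG" + "C" * 1000) == 2
        assert self.count("TATAG" + "C" * 1000) == 1

    def test_u_equals_t(self):
        genome = {"chr1": "C" * 60 + "TAG" + "C" * 1100}
        event = make_event("chr1", (11, 60), "+", flank=10)
        a = positional_profile([event], genome, "UAG")["5prime_ss"].counts.sum()
        b = positional_profile([event], genome, "TAG")["5prime_ss"].counts.sum()
        assert a == b == 1

    def test_bad_motifs_rejected(self):
        genome = {"chr1": "A" * 3000}
        event = make_event("chr1", (1400, 1459), "+")
        with pytest.raises(ValueError, match="characters"):
            positional_profile([event], genome, "TAX")
        with pytest.raises(ValueError, match="length"):
            positional_profile([event], genome, "TA")

    def test_total_count_equals_bin_sum(self):
        truth = random_truth(10, {"g": 2}, seed=51, event_types=("cassette",))
        genome = simulate_genome(truth, scrub_motif=False)
        _, events = simulate_table(truth)
        prof = positional_profile(events, genome, "TAG")
        for anchor in prof:
            assert prof[anchor].counts.sum() == sum(prof[anchor].counts)


class TestStrandSymmetry:
    def test_profile_invariant_under_full_reverse_complement(self):
        truth = random_truth(8, {"g": 2}, seed=52, event_types=("cassette",), strand="+")
        genome = simulate_genome(truth, scrub_motif=False)
        _, events = simulate_table(truth)
        forward = positional_profile(events, genome, "TAG")

        mirrored_sequences = {c: revcomp(s) for c, s in genome.sequences.items()}
        lengths = {c: len(s) for c, s in genome.sequences.items()}
        mirrored_events = []
        for ev in events:
            L = lengths[ev.chrom]
            exons = tuple(sorted((L - b + 1, L - a + 1) for a, b in ev.exon_intervals))
            mirrored_events.append(
                SpliceEvent(
                    event_id=ev.event_id,
                    event_type=ev.event_type,
                    chrom=ev.chrom,
                    strand="-",
                    inclusion_paths=ev.inclusion_paths,
                    exclusion_junctions=ev.exclusion_junctions,
                    exon_intervals=exons,
                )
            )
        mirrored = positional_profile(mirrored_events, mirrored_sequences, "TAG")
        for anchor in forward:
            np.testing.assert_array_equal(forward[anchor].counts, mirrored[anchor].counts)


class TestBaseline:
    def gtf_and_genome(self, truth):
        genome = simulate_genome(truth, scrub_motif=False)
        return genome

    def test_duplicate_annotation_exons_counted_once(self, tmp_path):
        truth = random_truth(3, {"g": 2}, seed=53, event_types=("cassette",))
        genome = self.gtf_and_genome(truth)
        gtf = tmp_path / "a.gtf"
        gtf.write_text(genome.gtf + genome.gtf)  # every record duplicated
        single = tmp_path / "b.gtf"
        single.write_text(genome.gtf)
        a = baseline_profile(gtf, genome, "TAG")
        b = baseline_profile(single, genome, "TAG")
        for anchor in a:
            assert a[anchor].n_exons == b[anchor].n_exons
            np.testing.assert_array_equal(a[anchor].counts, b[anchor].counts)

    def test_max_exon_len_strict(self, tmp_path):
        attrs = 'gene_id "g"; transcript_id "t"; gene_type "protein_coding";'
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            f"chr1\tx\texon\t1001\t1400\t.\t+\t.\t{attrs}\n"  # exactly 400 -> dropped
            f"chr1\tx\texon\t2001\t2399\t.\t+\t.\t{attrs}\n"  # 399 -> kept
        )
        rng = np.random.default_rng(1)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=5000))}
        prof = baseline_profile(gtf, genome, "TAG")
        assert prof["5prime_ss"].n_exons == 1

    def test_no_protein_coding_exons_rejected(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "g"; gene_type "lncRNA";\n')
        with pytest.raises(ValueError, match="protein-coding"):
            baseline_profile(gtf, {"chr1": "A" * 3000}, "TAG")

    def test_uniform_background_is_flat_at_analytic_rate(self, tmp_path):
        # expected per-bin per-exon mean for a 3-mer on i.i.d. uniform
        # bases: 25 start positions x 1/64 (edge effects excluded by
        # comparing interior intronic bins only)
        truth = random_truth(150, {"g": 1}, seed=54, event_types=("cassette",))
        genome = self.gtf_and_genome(truth)
        gtf = tmp_path / "a.gtf"
        gtf.write_text(genome.gtf)
        prof = baseline_profile(gtf, genome, "TAG")["3prime_ss"]
        interior = prof.per_exon_mean[1:38]
        expect = 25 / 64
        se = np.sqrt(expect / prof.n_exons)  # Poisson-ish per-bin SE
        assert np.all(np.abs(interior - expect) < 4 * se)
        assert abs(interior.mean() - expect) < 3 * se / np.sqrt(interior.size)


class TestPlantedRecovery:
    def test_planted_motifs_recovered_with_enrichment(self, tmp_path):
        truth = random_truth(30, {"g": 2}, seed=55, event_types=("cassette",), strand="+")
        plants = [MotifPlant(i, "5prime_ss", -200, -3, 8) for i in range(30)]
        genome = simulate_genome(truth, plants, motif="TAG", scrub_motif=True)
        _, events = simulate_table(truth)
        prof = positional_profile(events, genome, "TAG")
        p5 = prof["5prime_ss"]
        assert p5.counts.sum() == 30 * 8
        assert p5.counts[: p5.n_intronic_bins - 8].sum() == 0
        assert p5.counts[p5.n_intronic_bins :].sum() == 0
        assert prof["3prime_ss"].counts.sum() == 0

        btruth = random_truth(40, {"g": 2}, seed=56, event_types=("cassette",))
        bgenome = simulate_genome(btruth, scrub_motif=False)
        gtf = tmp_path / "b.gtf"
        gtf.write_text(bgenome.gtf)
        baselines = baseline_profile(gtf, bgenome, "TAG")
        enriched = attach_baseline(prof, baselines)
        assert proximal_enrichment(enriched["5prime_ss"]) >= 2.0

    def test_ptbp1_preset_sums_motif_set(self):
        genome = {"chr1": "C" * 60 + "CTCTC" + "C" * 1100}
        event = make_event("chr1", (11, 60), "+", flank=10)
        prof = positional_profile([event], genome, "ptbp1")
        # CTCTC holds one CTCT and one TCTC occurrence
        assert prof["5prime_ss"].counts.sum() == 2
        assert set(MOTIF_PRESETS["ptbp1"]) == {"CUCU", "UCUC"}
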