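"""Read filtering, translation and peptide frequency tables."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagetup._util import DomainError
from phagetup.ngs_pipeline import (
    FilterReport,
    FrequencyTable,
    ReadLayout,
    build_frequency_table,
    process_read,
    relative_abundance,
    translate_codons,
)
from phagetup.synthetic import CANONICAL_LINKER_NT, SimConfig, generate_fastq, reverse_translate

LAYOUT = ReadLayout(peptide_offset=4)


def _read(peptide_nt, linker_nt=CANONICAL_LINKER_NT, prefix="ACGT", suffix="TTAACC"):
    return prefix + peptide_nt + linker_nt + suffix


class TestTranslateCodons:
    @pytest.mark.parametrize(
        "nt, aa",
        [
            ("TGGTCTCTGGGTTATACTGGT", "WSLGYTG"),
            ("TAGGGTGGTGGTGGTGGTGGT", "*GGGGGG"),
            ("GGTGGAGGTTCG", "GGGS"),
            ("GGTNGAGGTTCG", "GXGS"),  # N-containing codon is an invalid marker
        ],
    )
    def test_standard_code(self, nt, aa):
        assert translate_codons(nt) == aa

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(DomainError):
            translate_codons("ACGTA")


class TestProcessRead:
    def test_valid_read_yields_peptide(self):
        seq = _read(reverse_translate("WSLGYTG"))
        assert process_read(seq, LAYOUT) == ("WSLGYTG", None)

    def test_synonymous_linker_codons_accepted(self):
        seq = _read(reverse_translate("WSLGYTG"), linker_nt="GGCGGGGGCAGC")
        assert process_read(seq, LAYOUT)[0] == "WSLGYTG"

    def test_stop_in_peptide_rejected(self):
        nt = reverse_translate("WSLGYTG")
        seq = _read(nt[:9] + "TAA" + nt[12:])
        assert process_read(seq, LAYOUT) == (None, "stop_in_peptide")

    def test_bad_linker_rejected(self):
        seq = _read(reverse_translate("WSLGYTG"), linker_nt="GGTGGAGGTCGT")  # GGGR
        assert process_read(seq, LAYOUT) == (None, "bad_linker")

    def test_n_in_peptide_is_invalid_aa(self):
        nt = reverse_translate("WSLGYTG")
        seq = _read("N" + nt[1:])
        assert process_read(seq, LAYOUT) == (None, "invalid_aa_in_peptide")

    def test_short_read_rejected(self):
        assert process_read("ACGT", LAYOUT) == (None, "too_short")

    def test_strict_nucleotide_linker_mode(self):
        layout = ReadLayout(peptide_offset=4, strict_linker_nt=CANONICAL_LINKER_NT)
        ok = _read(reverse_translate("WSLGYTG"))
        synonymous = _read(reverse_translate("WSLGYTG"), linker_nt="GGCGGGGGCAGC")
        assert process_read(ok, layout)[0] == "WSLGYTG"
        assert process_read(synonymous, layout) == (None, "bad_linker")


class TestFilterReport:
    @pytest.mark.parametrize(
        "total, removed, removed_pct, retained_pct",
        [
            (879_645, 42_367, 4.8, 95.2),
            (1_141_980, 36_299, 3.2, 96.8),
            (1_261_717, 26_236, 2.1, 97.9),
        ],
    )
    def test_percent_arithmetic(self, total, removed, removed_pct, retained_pct):
        report = FilterReport.from_counts(total, removed)
        assert report.clean_reads + report.removed_reads == report.total_reads
        assert report.removed_percent == removed_pct
        assert report.retained_percent == retained_pct


class TestBuildFrequencyTable:
    def test_error_free_input(self):
        reads = [_read(reverse_translate("WSLGYTG"))] * 100
        table, report = build_frequency_table(reads, LAYOUT)
        assert report.removed_percent == 0.0
        assert table.counts["WSLGYTG"] == 100

    def test_exact_corruption_counts_match_generator(self):
        """Generator bookkeeping is the oracle for the filter report."""
        cfg = SimConfig(seed=3, n_reads=1000, stop_rate=0.0, linker_error_rate=0.1,
                        time_points=(0.0,), focal_fractions=(0.5,), exact_corruption=True)
        sim = generate_fastq(cfg)
        _, report = build_frequency_table(sim.reads[0.0], cfg.layout)
        assert report.removed_percent == 10.0
        assert report.removal_reasons == {"bad_linker": 100}

    def test_reason_counts_equal_truth_labels(self):
        cfg = SimConfig(seed=9, n_reads=2000, stop_rate=0.02, linker_error_rate=0.05,
                        time_points=(0.0,), focal_fractions=(0.4,))
        sim = generate_fastq(cfg)
        _, report = build_frequency_table(sim.reads[0.0], cfg.layout)
        truth_counts = sim.truth.category_counts(0.0)
        assert report.clean_reads == truth_counts.get("clean", 0)
        for reason in ("stop_in_peptide", "bad_linker"):
            assert report.removal_reasons.get(reason, 0) == truth_counts.get(reason, 0)

    def test_empty_stream_rejected(self):
        with pytest.raises(DomainError):
            build_frequency_table([], LAYOUT)

    def test_descending_count_order_with_lexicographic_ties(self):
        reads = (
            [_read(reverse_translate("AAAAAAA"))] * 2
            + [_read(reverse_translate("CCCCCCC"))] * 5
            + [_read(reverse_translate("AAAAAAC"))] * 2
        )
        table, _ = build_frequency_table(reads, LAYOUT)
        assert [p for p, _ in table.items()] == ["CCCCCCC", "AAAAAAA", "AAAAAAC"]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        n=st.integers(10, 300),
        stop=st.floats(0, 0.3),
        link=st.floats(0, 0.3),
        seed=st.integers(0, 2**20),
    )
    def test_conservation_on_random_corrupted_streams(self, n, stop, link, seed):
        cfg = SimConfig(seed=seed, n_reads=n, stop_rate=stop, linker_error_rate=link,
                        time_points=(0.0,), focal_fractions=(0.5,))
        sim = generate_fastq(cfg)
        _, report = build_frequency_table(sim.reads[0.0], cfg.layout)
        assert report.clean_reads + report.removed_reads == report.total_reads == n

    def test_removed_percent_monotone_in_corruption_rate(self):
        """More corruption never lowers the removal rate (exact planting)."""
        pcts = []
        for rate in (0.0, 0.02, 0.05, 0.1, 0.2):
            cfg = SimConfig(seed=7, n_reads=2000, stop_rate=0.0, linker_error_rate=rate,
                            time_points=(0.0,), focal_fractions=(0.5,), exact_corruption=True)
            _, report = build_frequency_table(generate_fastq(cfg).reads[0.0], cfg.layout)
            pcts.append(report.removed_percent)
        assert pcts == sorted(pcts)


class TestRelativeAbundance:
    def test_percent_of_clean_reads(self):
        table = FrequencyTable("s", counts={"WSLGYTG": 541, "AAAAAAA": 459}, clean_total=1000)
        assert relative_abundance(table, "WSLGYTG") == 54.1

    def test_absent_peptide_is_zero(self):
        table = FrequencyTable("s", counts={"AAAAAAA": 10}, clean_total=10)
        assert relative_abundance(table, "WSLGYTG") == 0.0

    def test_single_clone_pool_is_100(self):
        table = FrequencyTable("s", counts={"AAAAAAA": 1}, clean_total=1)
        assert relative_abundance(table, "AAAAAAA") == 100.0

    def test_zero_clean_total_rejected(self):
        with pytest.raises(DomainError):
            relative_abundance(FrequencyTable("s", counts={}, clean_total=0), "WSLGYTG")
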