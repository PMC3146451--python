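"""Flank consensus, degenerate att motif, and insertion-site inference."""
import pytest

from islandmob import att_analysis as aa
from islandmob import pipeline
from islandmob import synthetic_data as sd
from islandmob.seqio import GenomeRecord, MultipleAlignment


def make_flanks(rows, kinds, upstream=4, repeat=4):
    sources = [aa.FlankSource(f"g{i}", k, f"g{i}_{k}", 0)
               for i, k in enumerate(kinds)]
    return aa.FlankSet(MultipleAlignment(
        [s.label for s in sources], rows), sources, upstream, repeat)


@pytest.fixture(scope="module")
def multi_genome_flanks():
    """Flank set pooled over several simulated genomes (2 islands each)."""
    entries = []
    cfg = pipeline.RunConfig(out_dir="scratch/att_tests")
    for s in range(6):
        spec = sd.IslandSimSpec(
            seed=100 + s, genome_length=45_000,
            islands=[sd.IslandSpec(length=12_000),
                     sd.IslandSpec(length=9_000, has_module=False, cargo=None,
                                   repeat_mismatches=1)])
        genome, _ = sd.generate_island_genome(spec)
        g2, locus, hits, _ = pipeline.scan_genome(genome, cfg)
        entries.extend(aa.flank_sources_from_scan(g2, locus, hits))
    return aa.extract_flanks(entries)


class TestExtractFlanks:
    def test_window_geometry_matches_planted_boundaries(
            self, multi_genome_flanks):
        fl = multi_genome_flanks
        assert fl.width == 84
        assert fl.windows.n_rows == 18          # 6 ssrA + 12 DR rows
        assert [s.kind for s in fl.sources].count("ssrA") == 6

    def test_boundary_at_contig_end_dropped(self):
        g = GenomeRecord("g", "ACGT" * 30)
        entries = [(g, aa.FlankSource("g", "DR", "g_02", 10)),   # off contig
                   (g, aa.FlankSource("g", "ssrA", "g_01", 60)),
                   (g, aa.FlankSource("g", "DR", "g_03", 60))]
        with pytest.warns(UserWarning, match="dropped"):
            fl = aa.extract_flanks(entries, width=20, upstream=5,
                                   repeat_length=10)
        assert fl.windows.n_rows == 2

    def test_flank_rows_end_with_planted_repeat(self, scanned_two_island):
        (genome, locus, hits, _), truth = scanned_two_island
        entries = aa.flank_sources_from_scan(genome, locus, hits)
        fl = aa.extract_flanks(entries)
        for row, src in zip(fl.windows.rows, fl.sources):
            repeat = row[fl.upstream:fl.upstream + fl.repeat_length]
            expected = genome.sequence[src.boundary_end - 20:src.boundary_end]
            assert repeat == expected


class TestConsensus:
    def test_identical_rows_full_consensus(self):
        fl = make_flanks(["ACGTACGT"] * 4, ["ssrA", "DR", "DR", "DR"])
        res = aa.consensus(fl)
        assert res.consensus == "ACGTACGT"
        assert res.disagreement_columns == []

    def test_unanimity_threshold_blanks_split_column(self):
        rows = ["ACGTACGT", "ACGTACGT", "ACGTTCGT"]
        res = aa.consensus(MultipleAlignment(list("abc"), rows), threshold=1.0)
        assert res.consensus == "ACGT.CGT"

    def test_six_of_eight_column_straddles_threshold(self):
        rows = ["AAG" + "A" * 5] * 6 + ["AAA" + "A" * 5] * 2
        msa = MultipleAlignment([f"r{i}" for i in range(8)], rows)
        assert aa.consensus(msa, threshold=0.75).consensus[2] == "G"
        assert aa.consensus(msa, threshold=0.80).consensus[2] == "."

    def test_gap_and_n_excluded_from_denominator(self):
        rows = ["ACGT", "-CGT", "NCGT", "ACGT"]
        res = aa.consensus(MultipleAlignment(list("abcd"), rows), 0.75)
        assert res.consensus == "ACGT"   # col 0: 2/2 A among countable rows

    def test_raising_threshold_never_adds_consensus_columns(
            self, multi_genome_flanks):
        counts = [aa.consensus(multi_genome_flanks, t).n_consensus_columns()
                  for t in (0.5, 0.6, 0.75, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestAttMotif:
    def test_unanimous_columns_give_literal_motif(self):
        rows = ["TTCAGGGG"] * 3
        fl = make_flanks(rows, ["DR"] * 3, upstream=8, repeat=0)
        assert aa.derive_att_motif(fl, motif_length=8).motif == "TTCAGGGG"

    def test_iupac_two_and_three_base_codes(self):
        # col 0: A/A/C/C -> M; col 1: A/A/G/T at 50/45/5% style mix
        rows = ["AA", "AA", "CA", "CG"]
        fl = make_flanks(rows, ["DR"] * 4, upstream=2, repeat=0)
        motif = aa.derive_att_motif(fl, motif_length=2,
                                    inclusion_fraction=0.10)
        assert motif.motif == "MR"
        # at inclusion 0 every observed base is included
        motif0 = aa.derive_att_motif(fl, motif_length=2,
                                     inclusion_fraction=0.0)
        assert motif0.motif == "MR"

    def test_rare_base_excluded_at_inclusion_fraction(self):
        rows = ["A"] * 10 + ["G"] * 9 + ["T"]
        fl = make_flanks(rows, ["DR"] * 20, upstream=1, repeat=0)
        assert aa.derive_att_motif(fl, motif_length=1).motif == "R"
        assert aa.derive_att_motif(fl, motif_length=1,
                                   inclusion_fraction=0.01).motif == "D"

    def test_planted_degenerate_motif_recovered(self, multi_genome_flanks):
        motif = aa.derive_att_motif(multi_genome_flanks)
        assert motif.motif == sd.DEFAULT_ATT_MOTIF

    def test_too_few_dr_rows_rejected(self):
        fl = make_flanks(["ACGT"] * 2, ["DR", "DR"], upstream=2, repeat=2)
        with pytest.raises(ValueError):
            aa.derive_att_motif(fl, motif_length=2)


class TestInsertionSite:
    def test_planted_tag_boundary_recovered(self, multi_genome_flanks):
        site = aa.infer_insertion_site(multi_genome_flanks, ssra_length=353)
        assert site.five_prime_pos == 333
        assert site.repeat_span == (334, 353)
        assert not site.degenerate

    def test_diagnostic_column_adjacent_to_repeat(self, multi_genome_flanks):
        site = aa.infer_insertion_site(multi_genome_flanks, ssra_length=353)
        # 34 upstream columns => the conserved disagreement at ssrA 333 is
        # the last upstream column
        assert site.diagnostic_column == 34

    def test_identical_groups_flagged_degenerate(self):
        rows = ["ACGTACGTA"] * 4
        fl = make_flanks(rows, ["ssrA", "ssrA", "DR", "DR"],
                         upstream=4, repeat=5)
        site = aa.infer_insertion_site(fl, ssra_length=100)
        assert site.degenerate
        assert site.five_prime_pos == 100 - 9

    def test_no_repeat_structure_raises(self):
        fl = make_flanks(["AAAAAAAA", "AAAAAAAA", "CCCCCCCC", "CCCCCCCC"],
                         ["ssrA", "ssrA", "DR", "DR"], upstream=2, repeat=6)
        with pytest.raises(ValueError, match="no repeat structure"):
            aa.infer_insertion_site(fl, ssra_length=50)

    def test_recovery_tolerates_mismatch_rate_below_threshold(self):
        # DR rows differ from ssrA at 5% of repeat columns (< 1 - 0.9)
        msa, _ = None, None
        import numpy as np
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 30))
        # motif column adjacent to the repeat must disagree with ssrA (the
        # documented conserved-disagreement boundary)
        motif = "".join(rng.choice(list("ACGT"), 9)) + \
            {"A": "G", "G": "A", "C": "T", "T": "C"}[base[9]]
        rows, kinds = [], []
        for i in range(5):
            rows.append(base[:10] + base[10:])      # ssrA row
            kinds.append("ssrA")
        for i in range(10):
            suffix = list(base[10:])
            for j in range(len(suffix)):
                if rng.random() < 0.05:
                    suffix[j] = rng.choice([b for b in "ACGT"
                                            if b != suffix[j]])
            rows.append(motif + "".join(suffix))
            kinds.append("DR")
        fl = make_flanks(rows, kinds, upstream=10, repeat=20)
        site = aa.infer_insertion_site(fl, ssra_length=353)
        assert site.repeat_span == (334, 353)
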