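"""Repeat scanning, island delineation and module detection."""
import numpy as np
import pytest

from islandmob import island_scanner as isc
from islandmob import pipeline
from islandmob import synthetic_data as sd
from islandmob.seqio import FeatureAnnotation, GenomeRecord, revcomp


def naive_hamming_scan(seq, pattern, max_mm, start, end):
    """Independent O(n*m) oracle for the repeat scan."""
    out = []
    for p in range(start, min(end, len(seq)) - len(pattern) + 1):
        mm = sum(1 for a, b in zip(seq[p:p + len(pattern)], pattern)
                 if a != b or a == "N")
        if mm <= max_mm:
            out.append((p, mm))
    return out


class TestLocateSsrA:
    def test_annotated_tmrna_wins(self):
        seq = "A" * 100 + sd.packaged_ssra() + "A" * 100
        g = GenomeRecord("g", seq, [FeatureAnnotation(
            "ssrA", "tmRNA", 100, 453, "+")])
        locus = isc.locate_ssrA(g)
        assert (locus.start, locus.end) == (100, 453)
        assert locus.three_prime_tag == seq[433:453]

    def test_reverse_strand_normalization(self):
        ssra = sd.packaged_ssra()
        seq = "C" * 50 + revcomp(ssra) + "C" * 200
        g = GenomeRecord("g", seq, [FeatureAnnotation(
            "ssrA", "tmRNA", 50, 403, "-")])
        locus = isc.locate_ssrA(g)
        assert locus.sequence == ssra
        g2, locus2 = isc.normalize_orientation(g, locus)
        assert locus2.strand == "+"
        assert g2.sequence[locus2.start:locus2.end] == ssra

    def test_unannotated_genome_located_by_reference(self, island_genome):
        genome, truth = island_genome
        bare = GenomeRecord(genome.id, genome.sequence, [])
        locus = isc.locate_ssrA(bare, reference_ssrA=sd.packaged_ssra())
        assert (locus.start, locus.end) == truth.ssra_interval

    def test_missing_ssra_raises(self):
        rng = np.random.default_rng(9)
        g = GenomeRecord("g", "".join(rng.choice(list("ACGT"), 2000)), [])
        with pytest.raises(isc.SsrANotFoundError):
            isc.locate_ssrA(g, reference_ssrA=sd.packaged_ssra())


class TestExtractTag:
    def test_tag_is_three_prime_terminal(self, island_genome):
        genome, truth = island_genome
        locus = isc.locate_ssrA(genome)
        assert isc.extract_tag(locus, 20) == truth.tag
        assert isc.extract_tag(locus, len(locus.sequence)) == locus.sequence

    def test_tag_longer_than_gene_rejected(self, island_genome):
        genome, _ = island_genome
        locus = isc.locate_ssrA(genome)
        with pytest.raises(ValueError):
            isc.extract_tag(locus, len(locus.sequence) + 1)


class TestScanDirectRepeats:
    def test_no_occurrence_yields_empty(self):
        rng = np.random.default_rng(0)
        ssra = sd.packaged_ssra()
        seq = ssra + "".join(rng.choice(list("ACGT"), 3000))
        g = GenomeRecord("g", seq,
                         [FeatureAnnotation("ssrA", "tmRNA", 0, 353, "+")])
        locus = isc.locate_ssrA(g)
        tag = isc.extract_tag(locus)
        hits = [h for h in isc.scan_direct_repeats(g, locus, tag)
                if h.mismatches <= 3]
        oracle = naive_hamming_scan(seq, tag, 3, locus.end + 1, len(seq))
        assert [(h.start, h.mismatches) for h in hits] == oracle

    def test_agrees_with_naive_oracle_on_random_genomes(self):
        # low-complexity alphabet makes spurious near-matches common
        rng = np.random.default_rng(42)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACG"), 2000))
            tag = "".join(rng.choice(list("ACG"), 20))
            genome = GenomeRecord("g", "A" * 30 + tag + seq)
            locus = isc.TmRNALocus("g", 0, 50, "+", genome.sequence[:50], tag)
            hits = isc.scan_direct_repeats(genome, locus, tag,
                                           scan_window=5000,
                                           merge_overlapping=False)
            oracle = naive_hamming_scan(genome.sequence, tag, 3,
                                        locus.end + 1, len(genome))
            assert [(h.start, h.mismatches) for h in hits] == oracle

    def test_mismatch_threshold_boundary(self):
        tag = "ACGGTCAATGCCTAGGTTAC"
        four_off = "TTTTTCAATGCCTAGGTTAC"
        seq = "A" * 30 + tag + "C" * 500 + four_off + "C" * 500
        genome = GenomeRecord("g", seq)
        locus = isc.TmRNALocus("g", 0, 50, "+", seq[:50], tag)
        assert isc.scan_direct_repeats(genome, locus, tag,
                                       scan_window=2000) == []
        hits = isc.scan_direct_repeats(genome, locus, tag, scan_window=2000,
                                       max_mismatches=4)
        assert [(h.start, h.mismatches) for h in hits] == [(550, 4)]

    def test_close_hits_merge_keeps_lower_mismatch(self):
        tag = "ACGGTCAATGCCTAGGTTAC"
        # two overlapping degenerate placements 4 bp apart
        seq = "T" * 30 + tag + "T" * 100 + "ACGT" + tag + "T" * 300
        genome = GenomeRecord("g", seq)
        locus = isc.TmRNALocus("g", 0, 50, "+", seq[:50], tag)
        merged = isc.scan_direct_repeats(genome, locus, tag, scan_window=1000)
        raw = isc.scan_direct_repeats(genome, locus, tag, scan_window=1000,
                                      merge_overlapping=False)
        assert len(raw) >= len(merged)
        assert all(h.mismatches == 0 for h in merged)

    def test_window_truncated_at_contig_end_with_warning(self, island_genome):
        genome, _ = island_genome
        locus = isc.locate_ssrA(genome)
        with pytest.warns(UserWarning, match="truncated"):
            isc.scan_direct_repeats(genome, locus, isc.extract_tag(locus))


class TestDelineateIslands:
    def test_interval_arithmetic(self):
        seq = "A" * 40000
        genome = GenomeRecord("g", seq)
        locus = isc.TmRNALocus("g", 0, 353, "+", "G" * 353, "G" * 20)
        hits = [isc.RepeatHit(353 + 12000 - 20, "G" * 20, 0, 12000 - 20),
                isc.RepeatHit(353 + 30000 - 20, "G" * 20, 0, 30000 - 20)]
        islands = isc.delineate_islands(genome, locus, hits, genes=[])
        assert [(i.attL, i.attR) for i in islands] == [
            (353, 353 + 12000), (353 + 12000, 353 + 30000)]
        assert [i.order_index for i in islands] == [1, 2]

    def test_zero_hits_no_islands(self):
        genome = GenomeRecord("g", "A" * 1000)
        locus = isc.TmRNALocus("g", 0, 353, "+", "G" * 353, "G" * 20)
        assert isc.delineate_islands(genome, locus, [], genes=[]) == []

    def test_boundaries_match_planted_truth(self, scanned_two_island):
        (genome, locus, hits, islands), truth = scanned_two_island
        assert [(i.attL, i.attR) for i in islands] == truth.island_boundaries
        assert [i.order_index for i in islands] == [1, 2]

    def test_islands_tile_spanned_interval(self, scanned_two_island):
        (genome, locus, hits, islands), _ = scanned_two_island
        assert islands[0].attL == locus.end
        for a, b in zip(islands, islands[1:]):
            assert a.attR == b.attL
        assert islands[-1].attR == hits[-1].end

    def test_strand_symmetry(self, two_island_genome, tmp_path):
        genome, truth = two_island_genome
        cfg = pipeline.RunConfig(out_dir=str(tmp_path))
        _, _, _, islands_fwd = pipeline.scan_genome(genome, cfg)
        _, _, _, islands_rev = pipeline.scan_genome(
            genome.reverse_complement(), cfg)
        assert [(i.attL, i.attR, i.has_integration_module)
                for i in islands_fwd] == \
            [(i.attL, i.attR, i.has_integration_module) for i in islands_rev]


class TestIntegrationModule:
    def test_planted_module_detected_with_all_roles(self, scanned_two_island):
        (genome, locus, hits, islands), truth = scanned_two_island
        module = islands[0].module
        assert module is not None
        assert module.gene_roles == list(isc.MODULE_ROLE_ORDER)
        planted = [(r, s, e) for r, s, e in truth.module_genes[0]]
        detected = [(m.role, m.feature.start, m.feature.end)
                    for m in module.matches]
        assert detected == planted
        assert module.rubredoxin_gene is not None

    def test_island_without_module_reports_none(self, scanned_two_island):
        (genome, locus, hits, islands), _ = scanned_two_island
        assert islands[1].module is None
        assert not islands[1].has_integration_module

    def test_empty_island_no_module(self):
        genome = GenomeRecord("g", "A" * 5000)
        island = isc.GenomicIsland("g", 1, 100, 4000, [])
        assert isc.detect_integration_module(genome, island) is None

    def test_detection_from_orfs_without_annotation(self, two_island_genome):
        genome, truth = two_island_genome
        bare = GenomeRecord(genome.id, genome.sequence, [])
        locus = isc.locate_ssrA(bare, reference_ssrA=sd.packaged_ssra())
        tag = isc.extract_tag(locus)
        hits = isc.scan_direct_repeats(bare, locus, tag, scan_window=40_000)
        islands = isc.delineate_islands(bare, locus, hits)
        module = isc.detect_integration_module(bare, islands[0])
        assert module is not None
        assert module.gene_roles[0] == "dsiB"
        assert len(module.gene_roles) >= 5

    def test_trna_found_at_canonical_offset(self, scanned_two_island):
        (genome, locus, hits, islands), truth = scanned_two_island
        module = islands[0].module
        assert module.trna_locus == truth.trna_positions[0]
        assert module.trna_canonical_position

    def test_trna_absent_when_not_planted(self, two_island_genome):
        genome, truth = two_island_genome
        # rebuild the module gene list but point the fifth gene elsewhere
        cfg = pipeline.RunConfig(out_dir="scratch/trna")
        g2, _, _, islands = pipeline.scan_genome(genome, cfg)
        module = islands[0].module
        res = isc.locate_module_trna(g2, islands[0], module,
                                     trna_consensus="A" * 76)
        assert res is None


class TestOrfCaller:
    def test_orfs_have_valid_structure(self, island_genome):
        genome, truth = island_genome
        attL, attR = truth.island_boundaries[0]
        orfs = isc.call_orfs(genome, attL, attR)
        assert orfs, "planted genes should be recovered as ORFs"
        for f in orfs:
            assert f.length % 3 == 0 and f.length >= 150
            seq = genome.feature_seq(f)
            assert seq[:3] in ("ATG", "GTG", "TTG")
            assert seq[-3:] in ("TAA", "TAG", "TGA")
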