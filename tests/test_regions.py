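"""Annotation parsing, region extraction and the undefined-base filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treexpress.regions import (AnnotationParseError, EmptyRegionError,
                                GeneModel, GenomeStore, RegionSequenceSet,
                                Transcript, extract_region, filter_undefined,
                                parse_annotations, reverse_complement,
                                summarize_region_lengths, REGION_TYPES)

GTF_PLUS = """\
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "gA";
chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\tsrc\tCDS\t151\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\tsrc\tCDS\t301\t350\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
"""


def _rng_genome(n=6000, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestParsing:
    def test_plus_strand_coordinates(self):
        (gene,) = parse_annotations(GTF_PLUS, "human")
        assert gene.strand == "+"
        assert gene.tss == 100          # 0-based half-open
        t = gene.transcripts[0]
        assert t.cds[0][0] == 150       # translation start
        assert t.cds[-1][1] == 350      # translation end
        assert gene.end == 400          # transcription end

    def test_empty_stream(self):
        assert parse_annotations("", "human") == []

    def test_minus_strand_tss_rightmost(self):
        gtf = GTF_PLUS.replace("\t+\t", "\t-\t")
        (gene,) = parse_annotations(gtf, "human")
        assert gene.tss == 400

    def test_malformed_record_names_line(self):
        bad = GTF_PLUS + "chr1\tbroken line\n"
        with pytest.raises(AnnotationParseError, match="line 7"):
            parse_annotations(bad, "human")

    def test_noncoding_transcript_flagged(self):
        gtf = GTF_PLUS + (
            'chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "gA"; '
            'transcript_id "gA.t2";\n'
            'chr1\tsrc\texon\t101\t400\t.\t+\t.\tgene_id "gA"; '
            'transcript_id "gA.t2";\n'
        )
        (gene,) = parse_annotations(gtf, "human")
        assert len(gene.transcripts) == 2
        assert len(gene.coding_transcripts) == 1

    def test_bed12_matches_gtf(self):
        bed = ("chr1\t100\t400\tgA.t1\t0\t+\t150\t350\t0\t2\t100,100\t0,200\n")
        (gene_bed,) = parse_annotations(bed, "human", fmt="bed12")
        (gene_gtf,) = parse_annotations(GTF_PLUS, "human")
        t_bed, t_gtf = gene_bed.transcripts[0], gene_gtf.transcripts[0]
        assert t_bed.exons == t_gtf.exons
        assert t_bed.cds == t_gtf.cds


class TestExtraction:
    def _gene(self, tss, strand="+", cds=None, end=None):
        end = end if end is not None else tss + 900
        cds = cds or [(tss + 200, tss + 700)]
        return GeneModel("g", "human", "chr1", strand,
                         [Transcript("g.t1", [(tss, end)], cds)])

    def test_promoter_window_arithmetic(self):
        genome = GenomeStore({"chr1": _rng_genome()})
        gene = self._gene(5000)
        full = extract_region(gene, genome, "promoter_full")
        w3 = extract_region(gene, genome, "promoter_w3")
        assert full.sequence == genome.fetch("chr1", 3500, 5000)
        assert w3.sequence == genome.fetch("chr1", 4500, 5000)
        assert not full.truncated

    def test_windows_tile_the_promoter(self):
        genome = GenomeStore({"chr1": _rng_genome()})
        for strand in "+-":
            gene = self._gene(4000, strand=strand,
                              cds=[(4200, 4700)], end=4900) if strand == "+" \
                else GeneModel("g", "human", "chr1", "-",
                               [Transcript("g.t1", [(1000, 2000)],
                                           [(1200, 1800)])])
            parts = [extract_region(gene, genome, f"promoter_w{i}").sequence
                     for i in (1, 2, 3)]
            full = extract_region(gene, genome, "promoter_full").sequence
            assert "".join(parts) == full
            assert len(full) == 1500

    def test_chromosome_edge_truncation(self):
        genome = GenomeStore({"chr1": _rng_genome()})
        gene = self._gene(800, cds=[(900, 1500)], end=1700)
        full = extract_region(gene, genome, "promoter_full")
        assert len(full.sequence) == 800
        assert full.truncated

    def test_multi_transcript_cds_union(self):
        genome = GenomeStore({"chr1": _rng_genome(100)})
        gene = GeneModel("g", "human", "chr1", "+", [
            Transcript("t1", [(5, 25)], [(10, 20)]),
            Transcript("t2", [(5, 35)], [(15, 30)]),
        ])
        cds = extract_region(gene, genome, "cds")
        assert cds.sequence == genome.fetch("chr1", 10, 30)

    def test_no_coding_transcript_signals(self):
        genome = GenomeStore({"chr1": _rng_genome(100)})
        gene = GeneModel("g", "human", "chr1", "+",
                         [Transcript("t1", [(5, 50)], [])])
        with pytest.raises(EmptyRegionError):
            extract_region(gene, genome, "utr3")

    def test_strand_round_trip(self):
        """A minus-strand mirror image of a plus-strand gene yields the
        same region sequences."""
        genome_fwd = _rng_genome(7000, seed=3)
        genome = GenomeStore({"chr1": genome_fwd})
        mirror = GenomeStore({"chr1": reverse_complement(genome_fwd)})
        L = 7000
        tss, cds_a, cds_b, end = 4000, 4200, 4700, 4900
        plus = GeneModel("g", "human", "chr1", "+",
                         [Transcript("t", [(tss, end)], [(cds_a, cds_b)])])
        minus = GeneModel("g", "human", "chr1", "-",
                          [Transcript("t", [(L - end, L - tss)],
                                      [(L - cds_b, L - cds_a)])])
        for region in REGION_TYPES:
            fwd = extract_region(plus, genome, region)
            rev = extract_region(minus, mirror, region)
            assert fwd.sequence == rev.sequence, region

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(0, 900), st.integers(5, 90)),
        min_size=1, max_size=5,
    ))
    def test_interval_union_brute_force(self, spans):
        """Unified multi-transcript CDS equals the per-base set union."""
        genome_seq = _rng_genome(1000, seed=9)
        genome = GenomeStore({"chr1": genome_seq})
        txs = [Transcript(f"t{i}", [(0, 1000)], [(a, min(1000, a + w))])
               for i, (a, w) in enumerate(spans)]
        gene = GeneModel("g", "human", "chr1", "+", txs)
        got = extract_region(gene, genome, "cds").sequence
        covered = sorted({p for a, w in spans for p in range(a, min(1000, a + w))})
        assert got == "".join(genome_seq[p] for p in covered)


class TestFilter:
    def _sets(self, six):
        def mk(gid, region, bad_species=None):
            seqs = {sp: "ACGTACGT" for sp in six.labels}
            if bad_species:
                seqs[bad_species] = "ACGNACGT"
            return RegionSequenceSet(gid, region, seqs)

        promoter = [mk("g1", "promoter_full", "marmoset"),
                    mk("g2", "promoter_full"), mk("g3", "promoter_full")]
        cds = [mk("g1", "cds"), mk("g2", "cds"), mk("g3", "cds")]
        return promoter, cds

    def test_per_region_independence(self, six):
        promoter, cds = self._sets(six)
        kept_prom = filter_undefined(promoter, six)
        kept_cds = filter_undefined(cds, six)
        assert [s.gene_id for s in kept_prom] == ["g2", "g3"]
        assert [s.gene_id for s in kept_cds] == ["g1", "g2", "g3"]

    def test_idempotent_and_order_independent(self, six):
        promoter, _ = self._sets(six)
        once = filter_undefined(promoter, six)
        assert filter_undefined(once, six) == once
        reversed_in = filter_undefined(list(reversed(promoter)), six)
        assert {s.gene_id for s in reversed_in} == {s.gene_id for s in once}

    def test_all_contaminated(self, six):
        sets = [RegionSequenceSet("g", "cds",
                                  {sp: "NNNN" for sp in six.labels})]
        assert filter_undefined(sets, six) == []

    def test_no_n_identity(self, six):
        _, cds = self._sets(six)
        assert filter_undefined(cds, six) == cds


class TestLengthSummary:
    def test_single_gene(self, six):
        rs = RegionSequenceSet("g", "utr3", {sp: "ACGT" * 5 for sp in six.labels})
        out = summarize_region_lengths([rs])
        assert (out["mean"] == 20).all() and (out["median"] == 20).all()
        assert (out["n"] == 1).all()

    def test_identical_species_symmetric(self, six):
        sets = [RegionSequenceSet(f"g{i}", "cds",
                                  {sp: "A" * (10 + i) for sp in six.labels})
                for i in range(4)]
        out = summarize_region_lengths(sets)
        assert out.groupby("region")["mean"].nunique().eq(1).all()

    def test_human_longer_utr3(self, small_config):
        """The generator draws human 3'UTRs twice as long; the summary
        must rank the human mean highest."""
        from treexpress.simulate import simulate_regions

        sim = simulate_regions(small_config)
        sets = sim.region_sets(("utr3",))["utr3"]
        out = summarize_region_lengths(sets).set_index("species")
        assert out["mean"].idxmax() == "human"
        assert out.loc["human", "mean"] > 1.8 * out.loc["macaque", "mean"]
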