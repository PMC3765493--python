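"""Pileup tallies, depth filters, gene annotation and window merging."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aeikit import (
    AllelicCount,
    GeneInterval,
    SiteObservation,
    VariantSite,
    annotate_sites,
    exonic_only,
    filter_sites,
    merge_windows,
    pileup_counts,
)

SITE = VariantSite("chr1", 50, "A", "G", site_id="s1")


def _read_at_50(name, allele, start=45, length=10, mapq=60, qual=None):
    # length-10 read covering pos 50; offset of site within read = 50 - start
    seq = list("C" * length)
    seq[50 - start] = allele
    return (name, start, f"{length}M", "".join(seq), mapq,
            qual if qual is not None else "I" * length)


class TestPileup:
    def test_direct_tally(self, sam_factory):
        reads = [_read_at_50(f"r{i}", "A") for i in range(5)]
        reads += [_read_at_50(f"v{i}", "G") for i in range(3)]
        sam = sam_factory(reads)
        (c,) = pileup_counts(sam, [SITE], "S1")
        assert (c.ref_count, c.var_count, c.other_count) == (5, 3, 0)
        assert c.sample_id == "S1"

    def test_third_allele_goes_to_other(self, sam_factory):
        reads = [_read_at_50(f"r{i}", "A") for i in range(4)]
        reads += [_read_at_50(f"v{i}", "G") for i in range(4)]
        reads += [_read_at_50("t0", "T")]
        (c,) = pileup_counts(sam_factory(reads), [SITE], "S1")
        assert (c.ref_count, c.var_count, c.other_count) == (4, 4, 1)
        assert c.ref_count + c.var_count + c.other_count == 9

    def test_deletion_and_clip_contribute_nothing(self, sam_factory):
        reads = [
            _read_at_50("r0", "A"),
            # deletion spanning pos 50 (ref 46-49 matched, 50-51 deleted)
            ("del0", 46, "4M2D6M", "CCCCCCCCCC"),
            # soft-clipped at the site: aligned part ends at ref pos 49
            ("clip0", 45, "5M5S", "CCCCCACCCC"),
        ]
        (c,) = pileup_counts(sam_factory(reads), [SITE], "S1")
        assert (c.ref_count, c.var_count, c.other_count) == (1, 0, 0)

    def test_quality_thresholds(self, sam_factory):
        lowq = "I" * 5 + "#" + "I" * 4  # base at the site below Q13
        reads = [
            _read_at_50("r0", "A"),
            _read_at_50("r1", "A", mapq=0),
            _read_at_50("r2", "G", qual=lowq),
        ]
        (c,) = pileup_counts(sam_factory(reads), [SITE], "S1")
        assert (c.ref_count, c.var_count, c.other_count) == (1, 0, 0)

    def test_uncovered_and_missing_chromosome(self, sam_factory):
        sam = sam_factory([_read_at_50("r0", "A")])
        far = VariantSite("chr1", 150, "C", "T")
        other = VariantSite("chr9", 50, "A", "G")
        counts = pileup_counts(sam, [far, other], "S1")
        assert all((c.ref_count, c.var_count, c.other_count) == (0, 0, 0) for c in counts)


class TestFilterSites:
    @pytest.mark.parametrize(
        "ref, var, kept",
        [(3, 3, True), (10, 0, False), (0, 10, False), (100, 4, False),
         (100, 6, True), (2, 50, False), (19, 1, False)],
    )
    def test_boundaries(self, ref, var, kept):
        c = AllelicCount(SITE, "S1", ref, var)
        assert (filter_sites([c]) == [c]) is kept

    def test_idempotent_subset_order_preserved(self):
        counts = [
            AllelicCount(SITE, "S1", r, v)
            for r, v in [(3, 3), (10, 0), (8, 9), (100, 4), (5, 5)]
        ]
        once = filter_sites(counts)
        assert filter_sites(once) == once
        assert all(c in counts for c in once)
        assert [counts.index(c) for c in once] == sorted(counts.index(c) for c in once)


GENE1 = GeneInterval("chr1", 100, 200, "GENE1", "exonic")


class TestAnnotate:
    def test_exonic_hit(self):
        (s,) = annotate_sites([VariantSite("chr1", 150, "A", "G")], [GENE1])
        assert (s.gene, s.region_class) == ("GENE1", "exonic")

    def test_no_hit_is_intergenic_and_excluded(self):
        (s,) = annotate_sites([VariantSite("chr1", 50, "A", "G")], [GENE1])
        assert s.region_class == "intergenic"
        assert exonic_only([s]) == []

    def test_utr_label(self):
        utr = GeneInterval("chr1", 100, 200, "GENE1", "UTR")
        (s,) = annotate_sites([VariantSite("chr1", 150, "A", "G")], [utr])
        assert s.region_class == "UTR"
        assert exonic_only([s]) == [s]

    def test_overlapping_genes_emit_one_copy_each(self):
        gene2 = GeneInterval("chr1", 140, 240, "GENE2", "exonic")
        out = annotate_sites([VariantSite("chr1", 150, "A", "G")], [GENE1, gene2])
        assert sorted(s.gene for s in out) == ["GENE1", "GENE2"]

    def test_interval_endpoints_inclusive(self):
        hits = annotate_sites(
            [VariantSite("chr1", 100, "A", "G"), VariantSite("chr1", 200, "A", "G"),
             VariantSite("chr1", 201, "A", "G")],
            [GENE1],
        )
        assert [s.region_class for s in hits] == ["exonic", "exonic", "intergenic"]


def _obs(pos, ratio):
    return SiteObservation("chr1", pos, ratio)


class TestMergeWindows:
    def test_two_close_sites_average(self):
        merged = merge_windows([_obs(10, 2.0), _obs(50, 3.0)])
        assert len(merged) == 1
        assert merged[0].folded_ratio == pytest.approx(2.5)
        assert merged[0].n_sites == 2

    def test_distant_sites_stay_separate(self):
        merged = merge_windows([_obs(10, 2.0), _obs(200, 3.0)])
        assert [m.folded_ratio for m in merged] == [2.0, 3.0]

    def test_first_site_anchor_hand_trace(self):
        # 90 is within 100 of the anchor at 10; 180 is 170 away -> new cluster
        merged = merge_windows([_obs(10, 2.0), _obs(90, 4.0), _obs(180, 6.0)])
        assert [m.pos for m in merged] == [10, 180]
        assert merged[0].folded_ratio == pytest.approx(3.0)
        assert merged[1].folded_ratio == pytest.approx(6.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            merge_windows([_obs(50, 2.0), _obs(10, 3.0)])

    @given(
        st.lists(
            st.tuples(st.integers(1, 2000), st.floats(1.0, 50.0)),
            min_size=1, max_size=30, unique_by=lambda t: t[0],
        )
    )
    def test_never_increases_observations(self, raw):
        obs = [_obs(p, r) for p, r in sorted(raw)]
        merged = merge_windows(obs)
        assert 1 <= len(merged) <= len(obs)
        assert sum(m.n_sites for m in merged) == len(obs)

    def test_grand_mean_preserved_with_equal_cluster_sizes(self):
        obs = [_obs(10, 2.0), _obs(20, 4.0), _obs(300, 1.0), _obs(310, 5.0)]
        merged = merge_windows(obs)
        assert len(merged) == 2
        grand = sum(m.folded_ratio for m in merged) / len(merged)
        assert grand == pytest.approx(sum(o.folded_ratio for o in obs) / len(obs))


def test_gff_intervals_match_bed_semantics(tmp_path):
    from aeikit.counts import read_gene_intervals

    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t100\t300\t.\t+\t.\tID=g1;gene_id=GENE1\n"
        "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;Parent=g1;gene_id=GENE1\n"
        "chr1\tsrc\tthree_prime_UTR\t201\t300\t.\t+\t.\tID=u1;Parent=g1;gene_id=GENE1\n"
    )
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t99\t200\tGENE1|exonic\nchr1\t200\t300\tGENE1|UTR\n")
    from_gff = sorted(read_gene_intervals(gff), key=lambda i: i.start)
    from_bed = sorted(read_gene_intervals(bed), key=lambda i: i.start)
    assert [(i.start, i.end, i.gene, i.feature) for i in from_gff] == \
           [(i.start, i.end, i.gene, i.feature) for i in from_bed]
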