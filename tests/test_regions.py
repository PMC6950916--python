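import numpy as np
import pytest
from hypothesis import given, strategies as st

from cncc import (
    GeneModel,
    GenomeBuild,
    NEGATIVE,
    POSITIVE,
    break_density_bpmm,
    build_regions,
    compare_densities,
    kruskal_dunn,
    window_densities,
)
from cncc.regions import LABELS, read_genes_gtf, read_genes_tsv

from conftest import make_profile


def labels_by_base(regions, chrom, length):
    """Per-base label sweep oracle."""
    out = np.full(length, "", dtype=object)
    for label, per_chrom in regions.intervals.items():
        for s, e in per_chrom.get(chrom, []):
            for i in range(s, e):
                assert out[i] == "", f"double label at {i}: {out[i]} and {label}"
                out[i] = label
    return out


class TestBuildRegions:
    def test_plus_strand_gene_worked_example(self):
        genome = GenomeBuild({"chr1": 30_000})
        regions = build_regions([GeneModel("chr1", "+", 10_000, 20_000)], genome)
        assert regions.intervals["promoter"]["chr1"] == [(9_000, 9_750)]
        assert regions.intervals["TSS"]["chr1"] == [(9_750, 10_250)]
        assert regions.intervals["TTS"]["chr1"] == [(19_750, 20_250)]
        assert regions.intervals["gene_body"]["chr1"] == [(10_250, 19_750)]
        inter = regions.intervals["intergenic"]["chr1"]
        assert inter == [(0, 9_000), (20_250, 30_000)]

    def test_no_genes_whole_genome_intergenic(self, genome):
        regions = build_regions([], genome)
        assert regions.total_bp() == {
            "promoter": 0, "TSS": 0, "TTS": 0, "gene_body": 0,
            "intergenic": genome.total_length,
        }

    def test_minus_strand_gene_mirrors_plus(self):
        genome = GenomeBuild({"chr1": 30_000})
        regions = build_regions([GeneModel("chr1", "-", 20_000, 10_000)], genome)
        assert regions.intervals["promoter"]["chr1"] == [(20_250, 21_000)]
        assert regions.intervals["TSS"]["chr1"] == [(19_750, 20_250)]
        assert regions.intervals["TTS"]["chr1"] == [(9_750, 10_250)]
        assert regions.intervals["gene_body"]["chr1"] == [(10_250, 19_750)]

    def test_overlapping_promoters_resolved_by_precedence(self):
        # two close genes: the second gene's promoter overlaps the first
        # gene's TSS window; TSS wins
        genome = GenomeBuild({"chr1": 10_000})
        genes = [
            GeneModel("chr1", "+", 3_000, 6_000),
            GeneModel("chr1", "+", 3_500, 7_000),
        ]
        regions = build_regions(genes, genome)
        sweep = labels_by_base(regions, "chr1", 10_000)
        assert set(sweep[3_000:3_250]) == {"TSS"}  # not the 2nd promoter
        assert np.all(sweep != "")  # partition covers every base

    def test_short_gene_has_empty_body(self):
        genome = GenomeBuild({"chr1": 10_000})
        regions = build_regions([GeneModel("chr1", "+", 5_000, 5_400)], genome)
        assert regions.total_bp()["gene_body"] == 0

    @given(
        tss=st.integers(300, 7_000),
        gene_len=st.integers(50, 2_500),
        strand=st.sampled_from("+-"),
    )
    def test_partition_is_exact(self, tss, gene_len, strand):
        genome = GenomeBuild({"chr1": 10_000})
        tts = tss + gene_len if strand == "+" else tss - min(gene_len, tss - 1)
        regions = build_regions([GeneModel("chr1", strand, tss, tts)], genome)
        assert sum(regions.total_bp().values()) == 10_000
        labels_by_base(regions, "chr1", 10_000)  # asserts no double labels


class TestGeneReaders:
    def test_tsv_reader(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("chrom\tstrand\ttss\ttts\nchr1\t+\t100\t900\nchr1\t-\t800\t200\n")
        genes = read_genes_tsv(f)
        assert genes == [GeneModel("chr1", "+", 100, 900), GeneModel("chr1", "-", 800, 200)]

    def test_gtf_reader_gene_lines_only(self, tmp_path):
        f = tmp_path / "genes.gtf"
        f.write_text(
            "# comment\n"
            'chr1\tsrc\tgene\t101\t900\t.\t+\t.\tgene_id "a";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "a";\n'
            'chr1\tsrc\tgene\t201\t801\t.\t-\t.\tgene_id "b";\n'
        )
        genes = read_genes_gtf(f)
        assert genes == [GeneModel("chr1", "+", 100, 899), GeneModel("chr1", "-", 800, 200)]


class TestBPMM:
    def test_worked_example_one_mb_hundred_breaks(self):
        # 100 breaks in a 1-Mb class out of 1e6 total -> BPMM = 100
        genome = GenomeBuild({"chr1": 2_000_000})
        regions = build_regions([GeneModel("chr1", "+", 400_000, 1_399_500)], genome)
        assert regions.total_bp()["gene_body"] == 999_000
        # place 100 breaks in the body, the rest elsewhere, total 1e6
        pos = make_profile(genome, POSITIVE, {"chr1": {500_000: 100, 10: 999_900}})
        neg = make_profile(genome, NEGATIVE, {})
        neg.add("chr1", 11, 1)  # satisfy non-emptiness without moving totals much
        pos.data["chr1"][10] -= 1
        densities = break_density_bpmm(pos, neg, regions)
        assert densities["gene_body"] == pytest.approx(100 / 0.999, rel=1e-9)

    def test_all_breaks_in_tss_leaves_other_labels_zero(self):
        genome = GenomeBuild({"chr1": 100_000})
        regions = build_regions([GeneModel("chr1", "+", 50_000, 60_000)], genome)
        pos = make_profile(genome, POSITIVE, {"chr1": {50_000: 10}})
        neg = make_profile(genome, NEGATIVE, {"chr1": {49_999: 10}})
        densities = break_density_bpmm(pos, neg, regions)
        assert densities["TSS"] > 0
        for label in ("promoter", "TTS", "gene_body", "intergenic"):
            assert densities[label] == 0

    def test_uniform_breaks_give_equal_densities(self):
        genome = GenomeBuild({"chr1": 1_000_000})
        regions = build_regions(
            [GeneModel("chr1", "+", 200_000, 500_000),
             GeneModel("chr1", "-", 800_000, 600_000)],
            genome,
        )
        rng = np.random.default_rng(12)
        pos = make_profile(
            genome, POSITIVE,
            {"chr1": {int(p): 1 for p in rng.choice(1_000_000, 200_000, replace=False)}},
        )
        neg = make_profile(
            genome, NEGATIVE,
            {"chr1": {int(p): 1 for p in rng.choice(1_000_000, 200_000, replace=False)}},
        )
        densities = break_density_bpmm(pos, neg, regions)
        # uniform expectation: (total * bp_L / G / (bp_L/1e6)) / (total/1e6)
        # = 1e12 / G, independent of the label
        for label, val in densities.items():
            assert val == pytest.approx(1e12 / 1_000_000, rel=0.1), label

    def test_invariant_to_duplicating_the_dataset(self, genome):
        regions = build_regions([GeneModel("chr1", "+", 300, 900)], genome)
        pos = make_profile(genome, POSITIVE, {"chr1": {100: 3, 310: 2}})
        neg = make_profile(genome, NEGATIVE, {"chr1": {500: 4}})
        base = break_density_bpmm(pos, neg, regions)
        pos2 = make_profile(genome, POSITIVE, {"chr1": {100: 6, 310: 4}})
        neg2 = make_profile(genome, NEGATIVE, {"chr1": {500: 8}})
        doubled = break_density_bpmm(pos2, neg2, regions)
        for label in base:
            assert doubled[label] == pytest.approx(base[label])

    def test_break_conservation_across_labels(self):
        genome = GenomeBuild({"chr1": 100_000})
        regions = build_regions([GeneModel("chr1", "+", 30_000, 70_000)], genome)
        rng = np.random.default_rng(5)
        pos = make_profile(
            genome, POSITIVE,
            {"chr1": {int(p): 1 for p in rng.choice(100_000, 5_000, replace=False)}},
        )
        neg = make_profile(genome, NEGATIVE, {"chr1": {7: 3}})
        total = pos.total() + neg.total()
        densities = break_density_bpmm(pos, neg, regions)
        bp = regions.total_bp()
        recovered = sum(
            densities[l] * (bp[l] / 1e6) * (total / 1e6) for l in densities
        )
        assert recovered == pytest.approx(total)


class TestGroupComparison:
    def test_identical_groups_give_h_near_zero(self):
        res = kruskal_dunn({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res["H"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] > 0.9

    def test_disjoint_supports_match_hand_computed_toy(self):
        # groups [1,2,3] vs [4,5,6]: mean ranks 2 and 5, no ties;
        # H = 12/(6*7) * (3*4 + 3*25) - 3*7 = 27/7; Dunn z = -3/sqrt(3.5*(2/3))
        res = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res["H"] == pytest.approx(27 / 7)
        z = res["dunn"].z.iloc[0]
        assert z == pytest.approx(-3 / np.sqrt(3.5 * (2 / 3)))
        assert res["dunn"].p.iloc[0] == pytest.approx(0.0495346, abs=1e-5)

    def test_constant_data_reports_p_one_without_crashing(self):
        res = kruskal_dunn({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res == {"H": 0.0, "p": 1.0, "dunn": res["dunn"]}
        assert (res["dunn"].p_adj == 1.0).all()

    def test_bh_adjustment_preserves_p_value_order(self):
        rng = np.random.default_rng(8)
        groups = {
            "low": rng.normal(0, 1, 30).tolist(),
            "mid": rng.normal(0.5, 1, 30).tolist(),
            "high": rng.normal(2, 1, 30).tolist(),
        }
        dunn = kruskal_dunn(groups)["dunn"].sort_values("p")
        assert dunn.p_adj.is_monotonic_increasing
        assert (dunn.p_adj >= dunn.p).all()

    def test_compare_densities_over_regions(self):
        genome = GenomeBuild({"chr1": 200_000})
        regions = build_regions([GeneModel("chr1", "+", 50_000, 150_000)], genome)
        rng = np.random.default_rng(4)
        per_region = {}
        for label in LABELS:
            per_region[label] = {
                "ctrl": rng.poisson(5, 20).astype(float).tolist(),
                "treat": rng.poisson(9, 20).astype(float).tolist(),
            }
        report = compare_densities(per_region)
        assert set(report.region) == set(LABELS)
        assert {"kruskal", "dunn"} == set(report.test)

    def test_window_densities_feed_the_test(self):
        genome = GenomeBuild({"chr1": 200_000})
        regions = build_regions([GeneModel("chr1", "+", 50_000, 150_000)], genome)
        rng = np.random.default_rng(4)
        pos = make_profile(
            genome, POSITIVE,
            {"chr1": {int(p): 1 for p in rng.choice(200_000, 10_000, replace=False)}},
        )
        neg = make_profile(genome, NEGATIVE, {"chr1": {3: 1}})
        dens = window_densities(pos, neg, regions, window_bp=1000)
        assert len(dens["gene_body"]) == 99  # 99,000 nt of body -> 99 full windows
        # uniform data: body and intergenic windows have similar medians
        assert np.median(dens["gene_body"]) == pytest.approx(
            np.median(dens["intergenic"]), rel=0.25
        )
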