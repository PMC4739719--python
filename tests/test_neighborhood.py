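import numpy as np
import pandas as pd
import pytest

from flankscan import neighborhood as nb
from flankscan.annotation_io import gene_centrum
from flankscan.models import DEL, GeneModel, NeighborGene, NeighborhoodSummary

from conftest import random_gene


def _gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, chrom, start, end, strand, exons=((start, end),))


class TestStrandAdjustedDistance:
    def test_plus_strand_downstream_is_positive(self):
        t = _gene("t", "chr1", 950_000, 1_050_000, "+")  # centrum 1,000,000
        n = _gene("n", "chr1", 1_000_000, 1_100_000)  # centrum 1,050,000
        assert nb.strand_adjusted_distance(t, n) == 50_000

    def test_minus_strand_flips_sign(self):
        t = _gene("t", "chr1", 950_000, 1_050_000, "-")
        n = _gene("n", "chr1", 1_000_000, 1_100_000)
        assert nb.strand_adjusted_distance(t, n) == -50_000

    def test_different_chromosomes_error(self):
        t = _gene("t", "chr1", 1, 100)
        n = _gene("n", "chr2", 1, 100)
        with pytest.raises(ValueError):
            nb.strand_adjusted_distance(t, n)

    def test_matches_case_enumeration(self):
        """Random configurations against an explicit sign-by-cases oracle."""
        rng = np.random.default_rng(21)
        for _ in range(300):
            t = random_gene(rng, gene_id="t")
            n = random_gene(rng, gene_id="n")
            ct, cn = gene_centrum(t), gene_centrum(n)
            if t.strand == "+":
                expected = cn - ct
            else:
                expected = ct - cn
            assert nb.strand_adjusted_distance(t, n) == expected


class TestExtractNeighborhood:
    def test_lone_target_has_empty_neighborhood(self):
        t = _gene("t", "chr1", 1, 1000)
        assert nb.extract_neighborhood(t, [t]) == []

    def test_target_absent_is_an_error(self):
        t = _gene("t", "chr1", 1, 1000)
        other = _gene("o", "chr1", 2000, 3000)
        with pytest.raises(ValueError, match="absent"):
            nb.extract_neighborhood(t, [other])

    def test_matches_brute_force_scan(self):
        """Window membership identical to an exhaustive all-genes scan."""
        rng = np.random.default_rng(22)
        for _ in range(40):
            genes = [
                random_gene(rng, chromosome=f"chr{rng.integers(1, 3)}", gene_id=f"g{i}")
                for i in range(60)
            ]
            t = genes[int(rng.integers(0, 60))]
            got = {n.gene_id for n in nb.extract_neighborhood(t, genes)}
            expected = set()
            for g in genes:
                if g.gene_id == t.gene_id or g.chromosome != t.chromosome:
                    continue
                if abs(gene_centrum(g) - gene_centrum(t)) <= 500_000:
                    expected.add(g.gene_id)
            assert got == expected

    def test_window_boundary_inclusive(self):
        t = _gene("t", "chr1", 1_000_000, 1_000_000)
        n = _gene("n", "chr1", 1_500_000, 1_500_000)
        assert [x.gene_id for x in nb.extract_neighborhood(t, [t, n])] == ["n"]

    def test_minus_strand_target_gene_family_layout(self):
        """A minus-strand target flanked like the thiosulfate
        sulfurtransferase locus: genes downstream in genomic coordinates are
        5' (negative) and upstream ones 3' (positive)."""
        tst = _gene("Tst", "chr15", 78_399_000, 78_405_000, "-")
        mpst = _gene("Mpst", "chr15", 78_406_000, 78_412_000, "+")
        kctd17 = _gene("Kctd17", "chr15", 78_429_000, 78_440_000, "+")
        tex33 = _gene("Tex33", "chr15", 78_367_000, 78_380_000, "+")
        far = _gene("Far", "chr15", 80_000_000, 80_010_000, "+")
        hood = nb.extract_neighborhood(tst, [tst, mpst, kctd17, tex33, far])
        d = {n.gene_id: n.centrum_distance for n in hood}
        assert set(d) == {"Mpst", "Kctd17", "Tex33"}
        assert d["Mpst"] < 0 and d["Kctd17"] < 0  # 5' of the target
        assert d["Tex33"] > 0  # 3' of the target


def _summary(target, allele_class, n_genes, flags, dysregulated):
    return NeighborhoodSummary(
        target=target,
        allele_class=allele_class,
        n_genes_in_window=n_genes,
        library_flags=flags,
        dysregulated=dysregulated,
    )


class TestSummarizeTarget:
    def _setup(self):
        t = _gene("t", "chr1", 1_000_000, 1_100_000)
        n1 = _gene("n1", "chr1", 1_200_000, 1_300_000)
        n2 = _gene("n2", "chr1", 800_000, 900_000)
        genes = [t, n1, n2]
        neighbors = nb.extract_neighborhood(t, genes)
        return t, neighbors

    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "hom_library", "wt_library", "direction"]
        )

    def test_no_significant_neighbors_all_flags_false(self):
        t, neighbors = self._setup()
        calls = self._calls(
            [["n1", "h1", "w1", "ns"], ["n2", "h1", "w1", "ns"]]
        )
        s = nb.summarize_target(t, DEL, neighbors, calls, [("h1", "w1")])
        assert not s.has_up and not s.has_down
        assert s.n_genes_in_window == 2
        assert s.dysregulated == []

    def test_single_library_down_sets_target_flag(self):
        """One neighbor down in one of four libraries flips the target-level
        OR flag."""
        t, neighbors = self._setup()
        pairs = [(f"h{i}", f"w{i}") for i in range(4)]
        rows = [["n1", f"h{i}", f"w{i}", "ns"] for i in range(4)]
        rows += [["n2", f"h{i}", f"w{i}", "ns"] for i in range(3)]
        rows += [["n2", "h3", "w3", "down"]]
        s = nb.summarize_target(t, DEL, neighbors, self._calls(rows), pairs)
        assert s.has_down and not s.has_up
        assert sum(f["has_down"] for f in s.library_flags.values()) == 1


class TestCohortFrequencies:
    def test_constructed_thirty_percent(self):
        """10 targets, exactly 3 with a planted up neighbor -> 30%."""
        summaries = []
        for i in range(10):
            has = i < 3
            dys = [
                {"gene_id": "n", "tissue": "t", "direction": "up", "centrum_distance": 1000}
            ] if has else []
            summaries.append(
                _summary(f"T{i}", DEL, 5,
                         {"t": {"has_up": has, "has_down": False}}, dys)
            )
        f = nb.cohort_frequencies(summaries, by="target")
        assert f["pct_up"] == pytest.approx(30.0)
        assert f["pct_down"] == 0.0

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            nb.cohort_frequencies([], by="target")


class TestTopography:
    def test_single_down_neighbor_at_minus_34kb(self):
        s = _summary(
            "T", DEL, 3, {"t": {"has_up": False, "has_down": True}},
            [{"gene_id": "n", "tissue": "t", "direction": "down",
              "centrum_distance": -34_000}],
        )
        bins, med = nb.topography([s])
        row = bins[(bins.lo_kb == -50)].iloc[0]
        assert row.count_down == 1 and bins.count_down.sum() == 1
        assert med["median_abs_down_kb"] == pytest.approx(34.0)

    def test_bins_tile_window_and_match_brute_force(self):
        rng = np.random.default_rng(23)
        dys = [
            {"gene_id": f"n{i}", "tissue": "t",
             "direction": "up" if rng.random() < 0.5 else "down",
             "centrum_distance": int(rng.integers(-500_000, 500_001))}
            for i in range(200)
        ]
        s = _summary("T", DEL, 300, {"t": {"has_up": True, "has_down": True}}, dys)
        bins, med = nb.topography([s], dedupe="instance")
        assert len(bins) == 20
        assert bins.lo_kb.iloc[0] == -500 and bins.hi_kb.iloc[-1] == 500
        # brute-force histogram
        for _, row in bins.iterrows():
            lo, hi = row.lo_kb * 1000, row.hi_kb * 1000
            exp_up = sum(
                1 for d in dys
                if d["direction"] == "up"
                and (lo <= d["centrum_distance"] < hi
                     or (d["centrum_distance"] == 500_000 and hi == 500_000))
            )
            assert row.count_up == exp_up
        assert bins.count_up.sum() + bins.count_down.sum() == len(dys)

    def test_pair_dedupe_counts_unique_pairs(self):
        dys = [
            {"gene_id": "n", "tissue": t, "direction": "down", "centrum_distance": -10_000}
            for t in ("liver", "lung", "spleen")
        ]
        s = _summary("T", DEL, 5, {}, dys)
        _, med_pair = nb.topography([s], dedupe="pair")
        _, med_inst = nb.topography([s], dedupe="instance")
        assert med_pair["n_dysregulated"] == 1
        assert med_inst["n_dysregulated"] == 3

    def test_strand_flip_mirrors_topography(self):
        """Negating every distance mirrors the histogram exactly."""
        rng = np.random.default_rng(24)
        dist = []
        while len(dist) < 100:
            d = int(rng.integers(-499_999, 500_000))
            if d % 50_000 != 0:  # bin-boundary values mirror into other bins
                dist.append(d)
        dys = [
            {"gene_id": f"n{i}", "tissue": "t",
             "direction": "up" if rng.random() < 0.5 else "down",
             "centrum_distance": d}
            for i, d in enumerate(dist)
        ]
        mirrored = [dict(d, centrum_distance=-d["centrum_distance"]) for d in dys]
        s1 = _summary("T", DEL, 200, {}, dys)
        s2 = _summary("T", DEL, 200, {}, mirrored)
        b1, _ = nb.topography([s1], dedupe="instance")
        b2, _ = nb.topography([s2], dedupe="instance")
        for _, row in b1.iterrows():  # bin [lo, hi) maps to [-hi, -lo)
            m = b2[(b2.lo_kb == -row.hi_kb)].iloc[0]
            assert (m.count_up, m.count_down) == (row.count_up, row.count_down)

    def test_zero_distance_goes_to_first_positive_bin(self):
        s = _summary(
            "T", DEL, 2, {},
            [{"gene_id": "n", "tissue": "t", "direction": "up", "centrum_distance": 0}],
        )
        bins, _ = nb.topography([s])
        assert bins[(bins.lo_kb == 0)].iloc[0].count_up == 1


class TestGeneDensity:
    def test_two_group_means(self):
        s1 = _summary("A", DEL, 10, {"t": {"has_up": True, "has_down": False}},
                      [{"gene_id": "n", "tissue": "t", "direction": "up",
                        "centrum_distance": 1}])
        s2 = _summary("B", DEL, 20, {"t": {"has_up": False, "has_down": False}}, [])
        d = nb.gene_density_contrast([s1, s2])
        assert d["mean_with_effects"] == 10 and d["mean_without_effects"] == 20

    def test_empty_group_reported_absent(self):
        s2 = _summary("B", DEL, 20, {"t": {"has_up": False, "has_down": False}}, [])
        d = nb.gene_density_contrast([s2])
        assert d["mean_with_effects"] is None and d["n_with_effects"] == 0
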