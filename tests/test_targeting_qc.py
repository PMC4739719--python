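import numpy as np
import pytest

from flankscan import targeting_qc as qc
from flankscan.models import DEL, TRAP, ExonProfile, GeneModel, TargetAllele
from flankscan.synthetic import (
    QC_SCENARIOS,
    SyntheticConfig,
    generate_annotation,
    generate_exon_profiles,
    scenario_compatible,
)


def _model(n_exons=8, strand="+"):
    exons = tuple((1000 * i + 1, 1000 * i + 500) for i in range(n_exons))
    return GeneModel("gT", "chr1", exons[0][0], exons[-1][1], strand, exons=exons)


def _profile(counts, lib="gT:HOM", intronic=0.0):
    return ExonProfile("gT", lib, tuple(float(c) for c in counts), intronic)


class TestFlagForInspection:
    @pytest.mark.parametrize(
        "hom,wt,expected",
        [
            (0, 10_000, False),  # clean knockout: no HOM signal
            (50, 200, True),  # 50 >= 20% of 200 and gene expressed
            (19, 100, False),  # below the 20% criterion
            (20, 100, True),  # boundary-inclusive 20%
            (150, 0, True),  # expressed in HOM only
            (10, 40, False),  # gene below the 100-read floor
        ],
    )
    def test_flag_cases(self, hom, wt, expected):
        assert qc.flag_for_inspection(hom, wt) is expected

    def test_matches_direct_predicate_on_grid(self):
        rng = np.random.default_rng(41)
        for _ in range(2000):
            hom = int(rng.integers(0, 301))
            wt = int(rng.integers(0, 301))
            expected = max(hom, wt) >= 100 and hom >= 0.20 * wt
            assert qc.flag_for_inspection(hom, wt) is expected


class TestClassifyExonPattern:
    def test_all_zero_profiles_are_indeterminate(self):
        m = _model()
        allele = TargetAllele("gT", DEL, deleted_exons=(1, 8))
        c = qc.classify_exon_pattern(
            _profile([0] * 8), _profile([0] * 8, "gT:WT"), allele, m
        )
        assert c.verdict == "indeterminate"

    def test_trap_splice_around_pattern(self):
        """Post-trap exons skipped, then reads resume in the distal half at a
        reduced level (the gene-trap read-through pattern)."""
        m = _model(n_exons=8)
        allele = TargetAllele("gT", TRAP, trap_insertion_intron=4)
        wt = _profile([500] * 8, "gT:WT")
        hom = _profile([300, 300, 300, 300, 0, 0, 200, 200])
        c = qc.classify_exon_pattern(hom, wt, allele, m)
        assert c.verdict == "splice_around"

    def test_trap_complete_pattern(self):
        m = _model(n_exons=8)
        allele = TargetAllele("gT", TRAP, trap_insertion_intron=4)
        wt = _profile([500] * 8, "gT:WT")
        hom = _profile([300, 300, 300, 300, 0, 0, 0, 0])
        c = qc.classify_exon_pattern(hom, wt, allele, m)
        assert c.verdict == "trap_complete"

    def test_del_distal_retention_pattern(self):
        """Deleted proximal exons silent; retained distal exons above WT
        (compensatory over-expression of the remaining exons)."""
        m = _model(n_exons=13)
        allele = TargetAllele("gT", DEL, deleted_exons=(1, 8))
        wt = _profile([100] * 13, "gT:WT")
        hom = _profile([0] * 8 + [300] * 5)
        c = qc.classify_exon_pattern(hom, wt, allele, m)
        assert c.verdict == "distal_retention"

    def test_del_reads_on_deleted_exons_fail_targeting(self):
        m = _model(n_exons=6)
        allele = TargetAllele("gT", DEL, deleted_exons=(1, 6))
        wt = _profile([200] * 6, "gT:WT")
        hom = _profile([180] * 6)
        c = qc.classify_exon_pattern(hom, wt, allele, m)
        assert c.verdict == "failed_targeting"

    def test_del_intronic_only_pattern(self):
        m = _model(n_exons=6)
        allele = TargetAllele("gT", DEL, deleted_exons=(1, 6))
        wt = _profile([200] * 6, "gT:WT")
        hom = _profile([0] * 6, intronic=800.0)
        c = qc.classify_exon_pattern(hom, wt, allele, m)
        assert c.verdict == "intronic_only"

    def test_uniform_hypomorph_pattern(self):
        m = _model(n_exons=8)
        allele = TargetAllele("gT", TRAP, trap_insertion_intron=1)
        wt = _profile([400] * 8, "gT:WT")
        hom = _profile([120] * 8)
        c = qc.classify_exon_pattern(hom, wt, allele, m)
        assert c.verdict == "uniform_hypomorph"

    def test_scale_invariance_above_floor(self):
        """Away from the expression floor the rules are pure ratios, so
        multiplying both profiles by a common factor keeps the verdict."""
        m = _model(n_exons=8)
        allele = TargetAllele("gT", TRAP, trap_insertion_intron=4)
        rng = np.random.default_rng(42)
        for _ in range(50):
            w = rng.integers(200, 600, size=8).astype(float)
            h = (w * rng.uniform(0.25, 1.2, size=8)).round()
            base = qc.classify_exon_pattern(
                _profile(h), _profile(w, "gT:WT"), allele, m
            ).verdict
            scaled = qc.classify_exon_pattern(
                _profile(h * 3), _profile(w * 3, "gT:WT"), allele, m
            ).verdict
            assert scaled == base

    def test_total_function_over_random_profiles(self):
        """Every non-negative profile pair gets exactly one verdict."""
        m = _model(n_exons=6)
        alleles = [
            TargetAllele("gT", DEL, deleted_exons=(1, 4)),
            TargetAllele("gT", TRAP, trap_insertion_intron=2),
        ]
        rng = np.random.default_rng(43)
        for _ in range(300):
            h = rng.integers(0, 500, size=6).astype(float)
            w = rng.integers(0, 500, size=6).astype(float)
            allele = alleles[int(rng.integers(0, 2))]
            c = qc.classify_exon_pattern(
                _profile(h, intronic=float(rng.integers(0, 300))),
                _profile(w, "gT:WT"),
                allele, m,
            )
            assert c.verdict in qc.CONFIRMED_VERDICTS | {"failed_targeting", "indeterminate"}

    def test_mismatched_exon_count_is_an_error(self):
        m = _model(n_exons=6)
        allele = TargetAllele("gT", DEL, deleted_exons=(1, 6))
        with pytest.raises(ValueError, match="exon"):
            qc.classify_exon_pattern(
                _profile([0] * 5), _profile([0] * 6, "gT:WT"), allele, m
            )


@pytest.fixture(scope="module")
def cohort():
    """Generated genes with hand-assigned alleles so every scenario has a
    compatible (model, allele) pair."""
    cfg = SyntheticConfig(seed=5, n_chromosomes=2, chromosome_length=6_000_000,
                          n_targets_del=2, n_targets_trap=2)
    genes, _ = generate_annotation(cfg)
    by_id = {g.gene_id: g for g in genes}
    big = [g for g in genes if g.n_exons >= 6][:6]
    alleles = [
        TargetAllele(big[0].gene_id, TRAP, trap_insertion_intron=2),
        TargetAllele(big[1].gene_id, TRAP,
                     trap_insertion_intron=big[1].n_exons - 2),
        TargetAllele(big[2].gene_id, DEL, deleted_exons=(1, big[2].n_exons)),
        TargetAllele(big[3].gene_id, DEL,
                     deleted_exons=(1, big[3].n_exons - 2)),
    ]
    return cfg, by_id, alleles


class TestScenarioRecovery:

    def test_noise_free_profiles_recover_every_scenario(self, cohort):
        """The classifier inverts the generator exactly when Poisson noise is
        switched off, for every verdict scenario."""
        cfg, by_id, alleles = cohort
        covered = set()
        for scenario in QC_SCENARIOS:
            for allele in alleles:
                model = by_id[allele.gene_id]
                if not scenario_compatible(scenario, allele, model):
                    continue
                hom, wt = generate_exon_profiles(cfg, model, allele, scenario,
                                                 noise=False)
                c = qc.classify_exon_pattern(hom, wt, allele, model)
                assert c.verdict == scenario, (scenario, allele.gene_id, c.evidence)
                covered.add(scenario)
        assert covered == set(QC_SCENARIOS)

    def test_incompatible_scenario_is_an_error(self, cohort):
        cfg, by_id, alleles = cohort
        trap = next(a for a in alleles if a.allele_class == TRAP)
        with pytest.raises(ValueError, match="incompatible"):
            generate_exon_profiles(cfg, by_id[trap.gene_id], trap, "distal_retention")


class TestCohortQc:
    def test_silent_homs_all_confirmed_none_flagged(self):
        mutants = [
            {"target": f"T{i}", "allele_class": DEL,
             "library_flags": [False, False],
             "verdicts": ["confirmed_null", "confirmed_null"]}
            for i in range(5)
        ]
        df = qc.cohort_qc(mutants)
        row = df.iloc[0]
        assert row["pct_flagged"] == 0.0
        assert row["pct_confirmed"] == 100.0
        assert row["pct_confirmed_null"] == 100.0

    def test_failed_anywhere_fails_the_mutant(self):
        v = qc.aggregate_verdicts(["confirmed_null", "failed_targeting"])
        assert v == "failed_targeting"

    def test_flag_aggregation_is_or(self):
        mutants = [
            {"target": "T", "allele_class": TRAP,
             "library_flags": [False, True, False],
             "verdicts": ["trap_complete"] * 3}
        ]
        assert qc.cohort_qc(mutants).iloc[0]["pct_flagged"] == 100.0
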