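"""Component rules: expected state, PLOH/PCNA/PTCNA filters, GIS, HRD calls."""

import numpy as np
import pytest

from hrdgis.profiles_io import (
    AlleleSpecificSegment,
    BRCAStatus,
    CopyNumberProfile,
)
from hrdgis.score import (
    GISResult,
    ScoreParams,
    call_hrd,
    compute_gis,
    compute_pcna,
    compute_ploh,
    compute_ptcna,
    expected_state,
)

from conftest import MB, SMALL_PARAMS, make_toy_profile, random_toy_case
from oracle import oracle_components


def seg(chrom, s_mb, e_mb, t, m):
    return AlleleSpecificSegment(chrom, int(s_mb * MB), int(e_mb * MB), t, m)


class TestExpectedState:
    def test_majority_state_wins(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 15, 2, 0),
            seg("chrA", 15, 100, 2, 1),
        ))
        st = expected_state(prof, toy_build, "chrA")
        assert st.state == (2, 1)

    def test_uniform_chromosome_defines_its_own_expectation(self, toy_build):
        prof = CopyNumberProfile("S", (seg("chrA", 0, 100, 3, 1),))
        st = expected_state(prof, toy_build, "chrA")
        assert st.state == (3, 1)
        pcna, regions = compute_pcna(prof, toy_build)
        assert pcna == 0.0 and regions == []

    def test_tie_breaks_toward_smaller_total_then_minor(self, toy_build):
        # 49.5 Mb observed at each state on chrA (centromere splits the (3,1) run)
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 40, 2, 1),
            seg("chrA", 40, 50.5, 2, 1),   # 9.5 Mb on q arm + 1 Mb centromere
            seg("chrA", 50.5, 100, 3, 1),  # 49.5 Mb on q arm
        ))
        st = expected_state(prof, toy_build, "chrA")
        assert st.covered_bp == int(49.5 * MB)
        assert st.state == (2, 1)

    def test_unobserved_chromosome_has_no_expected_state(self, toy_build):
        prof = CopyNumberProfile("S", (seg("chrB", 0, 60, 2, 1),))
        assert expected_state(prof, toy_build, "chrA") is None


class TestWorkedToyExample:
    """The 15 Mb terminal copy-neutral LOH fixture, hand- and oracle-computed."""

    def test_component_values(self, toy_build, toy_profile):
        ploh, _ = compute_ploh(toy_profile, toy_build)
        pcna, _ = compute_pcna(toy_profile, toy_build)
        ptcna, verdicts = compute_ptcna(toy_profile, toy_build)
        assert ploh == pytest.approx(100 * 15 / 158, rel=1e-12)
        assert pcna == pytest.approx(100 * 15 / 158, rel=1e-12)
        assert ptcna == pytest.approx(25.0, rel=1e-12)
        assert sum(v.evaluable for v in verdicts) == 4
        assert sum(v.altered for v in verdicts) == 1

    def test_gis_is_exact_component_sum(self, toy_build, toy_profile):
        r = compute_gis(toy_profile, toy_build)
        assert r.evaluable
        assert r.gis == r.ploh_pct + r.pcna_pct + r.ptcna_pct
        assert r.gis == pytest.approx(100 * 30 / 158 + 25.0, rel=1e-12)
        assert r.gi_positive is False
        assert r.observed_genome_bp == 158 * MB

    def test_matches_per_base_oracle(self):
        # the same fixture at 1 bp per Mb: per-base painting is cheap and
        # the strict inequalities are scale-invariant under exact division
        from hrdgis.genome import ChromosomeArm, GenomeBuild

        build = GenomeBuild(
            name="toy-mb",
            chromosomes=(("chrA", 100), ("chrB", 60)),
            arms=(
                ChromosomeArm("chrA", "p", 0, 40),
                ChromosomeArm("chrA", "q", 41, 100),
                ChromosomeArm("chrB", "p", 0, 30),
                ChromosomeArm("chrB", "q", 31, 60),
            ),
            included_chromosomes=frozenset({"chrA", "chrB"}),
        )
        prof = CopyNumberProfile("S1", (
            AlleleSpecificSegment("chrA", 0, 15, 2, 0),
            AlleleSpecificSegment("chrA", 15, 100, 2, 1),
            AlleleSpecificSegment("chrB", 0, 60, 2, 1),
        ))
        params = ScoreParams(
            max_gap_bp=1, min_observed_fraction=0.0, telomere_window_bp=5,
            min_region_bp=10, min_telomeric_segment_bp=1,
        )
        o = oracle_components(prof, build, params)
        assert o.ploh == pytest.approx(100 * 15 / 158, rel=1e-9)
        assert o.pcna == pytest.approx(100 * 15 / 158, rel=1e-9)
        assert o.ptcna == pytest.approx(25.0, rel=1e-9)
        assert compute_ploh(prof, build, params)[0] == pytest.approx(o.ploh, rel=1e-12)


class TestSizeAndArmFilters:
    def test_9mb_loh_run_contributes_nothing(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 9, 2, 0),
            seg("chrA", 9, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        ploh, _ = compute_ploh(prof, toy_build)
        assert ploh == 0.0

    def test_exactly_10mb_excluded_strict_inequality(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 10, 2, 0),
            seg("chrA", 10, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        assert compute_ploh(prof, toy_build)[0] == 0.0
        prof2 = CopyNumberProfile("S", (
            AlleleSpecificSegment("chrA", 0, 10 * MB + 1, 2, 0),
            AlleleSpecificSegment("chrA", 10 * MB + 1, 100 * MB, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        assert compute_ploh(prof2, toy_build)[0] > 0.0

    def test_whole_arm_loh_excluded(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 40, 2, 0),   # exactly chrA-p
            seg("chrA", 41, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        ploh, regions = compute_ploh(prof, toy_build)
        assert ploh == 0.0 and regions == []

    def test_whole_arm_deviation_excluded_from_pcna(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 40, 3, 1),
            seg("chrA", 41, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        assert compute_pcna(prof, toy_build)[0] == 0.0

    def test_sub_arm_fraction_of_arm_still_counts(self, toy_build):
        # 15/40 of chrA-p observed < 0.9 -> not a whole-arm event
        ploh, regions = compute_ploh(make_toy_profile(), toy_build)
        assert len(regions) == 1
        assert regions[0].observed_bp == 15 * MB

    def test_loh_run_fuses_across_total_cn_change(self, toy_build):
        """Allele loss with an internal total-CN step is one region."""
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 6, 2, 0),
            seg("chrA", 6, 12, 1, 0),
            seg("chrA", 12, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        ploh, regions = compute_ploh(prof, toy_build)
        assert len(regions) == 1
        assert regions[0].span_bp == 12 * MB
        assert ploh == pytest.approx(100 * 12 / 158)

    def test_homozygous_deletion_flagged_and_configurable(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 6, 2, 0),
            seg("chrA", 6, 8, 0, 0),
            seg("chrA", 8, 12, 2, 0),
            seg("chrA", 12, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        ploh, regions = compute_ploh(prof, toy_build)
        assert regions[0].contains_homozygous_deletion
        assert ploh == pytest.approx(100 * 12 / 158)
        strict = ScoreParams(count_homdel_as_loh=False)
        ploh2, regions2 = compute_ploh(prof, toy_build, strict)
        # the homozygous segment now splits the run into 6 + 4 Mb: both fail >10 Mb
        assert ploh2 == 0.0 and regions2 == []


class TestTelomereRules:
    def test_sub_1mb_terminal_segment_not_altered(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 0.8, 3, 1),
            seg("chrA", 0.8, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        ptcna, verdicts = compute_ptcna(prof, toy_build)
        assert ptcna == 0.0
        v = next(v for v in verdicts if v.chromosome == "chrA" and v.arm == "p")
        assert v.evaluable and not v.altered

    def test_segment_starting_beyond_window_is_not_telomeric(self, toy_build):
        prof = CopyNumberProfile("S", (
            AlleleSpecificSegment("chrA", 5 * MB + 1, 20 * MB, 3, 1),
            AlleleSpecificSegment("chrA", 20 * MB, 100 * MB, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        _, verdicts = compute_ptcna(prof, toy_build)
        v = next(v for v in verdicts if v.chromosome == "chrA" and v.arm == "p")
        assert not v.evaluable
        # one base earlier the segment is telomeric (distance strictly < 5 Mb)
        prof2 = CopyNumberProfile("S", (
            AlleleSpecificSegment("chrA", 5 * MB - 1, 20 * MB, 3, 1),
            AlleleSpecificSegment("chrA", 20 * MB, 100 * MB, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        _, verdicts2 = compute_ptcna(prof2, toy_build)
        v2 = next(v for v in verdicts2 if v.chromosome == "chrA" and v.arm == "p")
        assert v2.evaluable and v2.altered

    def test_unassembled_telomere_leaves_denominator(self):
        from hrdgis.genome import ChromosomeArm, GenomeBuild

        build = GenomeBuild(
            name="toy2",
            chromosomes=(("chrA", 100 * MB),),
            arms=(
                ChromosomeArm("chrA", "p", 0, 40 * MB, telomere_assembled=False),
                ChromosomeArm("chrA", "q", 41 * MB, 100 * MB),
            ),
            included_chromosomes=frozenset({"chrA"}),
        )
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 15, 2, 0),
            seg("chrA", 15, 100, 2, 1),
        ))
        ptcna, verdicts = compute_ptcna(prof, build)
        assert sum(v.evaluable for v in verdicts) == 1  # only chrA-q
        assert ptcna == 0.0

    def test_whole_arm_telomeric_alteration_not_counted(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 40, 3, 1),    # whole p arm gained
            seg("chrA", 41, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        _, verdicts = compute_ptcna(prof, toy_build)
        v = next(v for v in verdicts if v.chromosome == "chrA" and v.arm == "p")
        assert v.evaluable and not v.altered
        assert "whole-arm" in v.reason

    def test_no_evaluable_telomere_means_unevaluable_profile(self, toy_build):
        # interstitial-only coverage: nothing within 5 Mb of any end, but
        # enough observed territory to pass the observed-fraction floor
        prof = CopyNumberProfile("S", (
            seg("chrA", 6, 95, 2, 1),
            seg("chrB", 6, 55, 2, 1),
        ))
        ptcna, _ = compute_ptcna(prof, toy_build)
        assert ptcna is None
        r = compute_gis(prof, toy_build, ScoreParams(min_observed_fraction=0.1))
        assert not r.evaluable and r.gis is None and r.gi_positive is None


class TestGISClassification:
    def test_fully_heterozygous_diploid_scores_zero(self, toy_build):
        prof = CopyNumberProfile("S", (
            seg("chrA", 0, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        r = compute_gis(prof, toy_build)
        assert r.gis == 0.0 and r.gi_positive is False

    def test_gi_flips_exactly_at_cutoff(self, toy_build, toy_profile):
        r = compute_gis(toy_profile, toy_build)
        at = compute_gis(toy_profile, toy_build, ScoreParams(cutoff=r.gis))
        above = compute_gis(
            toy_profile, toy_build, ScoreParams(cutoff=r.gis + 1e-9)
        )
        assert at.gi_positive is True
        assert above.gi_positive is False

    def test_low_observed_fraction_is_unevaluable(self, toy_build):
        prof = CopyNumberProfile("S", (seg("chrA", 0, 30, 2, 1),))
        r = compute_gis(prof, toy_build)  # 30/158 < 0.4
        assert not r.evaluable and r.gis is None

    @pytest.mark.parametrize(
        "gi,brca,expected",
        [
            (True, BRCAStatus.WILDTYPE, "positive"),
            (False, BRCAStatus.PATHOGENIC, "positive"),
            (False, BRCAStatus.WILDTYPE, "negative"),
            (False, BRCAStatus.UNKNOWN, "negative"),
            (None, BRCAStatus.WILDTYPE, "unevaluable"),
            (None, BRCAStatus.PATHOGENIC, "positive"),
        ],
    )
    def test_hrd_call_truth_table(self, gi, brca, expected):
        r = GISResult(
            sample_id="S", ploh_pct=None, pcna_pct=None, ptcna_pct=None,
            gis=None, observed_genome_bp=0, observed_fraction=0.0,
            evaluable=gi is not None, gi_positive=gi,
        )
        assert call_hrd(r, brca).hrd_status == expected


class TestStructuralInvariances:
    def test_whole_genome_duplication_leaves_score_unchanged(self, toy_build):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            build, prof = random_toy_case(rng)
            if not prof.segments:
                continue
            doubled = CopyNumberProfile(
                prof.sample_id,
                tuple(
                    AlleleSpecificSegment(
                        s.chromosome, s.start, s.end, 2 * s.total_cn, 2 * s.minor_cn
                    )
                    for s in prof.segments
                ),
            )
            r1 = compute_gis(prof, build, SMALL_PARAMS)
            r2 = compute_gis(doubled, build, SMALL_PARAMS)
            assert r1.evaluable == r2.evaluable
            if r1.evaluable:
                assert r1.gis == pytest.approx(r2.gis, rel=1e-12, abs=1e-12)
            checked += 1

    def test_added_qualifying_loh_region_never_decreases_ploh(self, toy_build):
        base = CopyNumberProfile("S", (
            seg("chrA", 0, 15, 2, 0),
            seg("chrA", 15, 100, 2, 1),
            seg("chrB", 0, 60, 2, 1),
        ))
        with_extra = CopyNumberProfile("S", (
            seg("chrA", 0, 15, 2, 0),
            seg("chrA", 15, 100, 2, 1),
            seg("chrB", 0, 10, 2, 1),
            seg("chrB", 10, 22, 2, 0),  # 12 Mb interstitial qualifying LOH
            seg("chrB", 22, 60, 2, 1),
        ))
        p0, _ = compute_ploh(base, toy_build)
        p1, _ = compute_ploh(with_extra, toy_build)
        assert p1 > p0
        g0 = compute_gis(base, toy_build).gis
        g1 = compute_gis(with_extra, toy_build).gis
        assert g1 >= g0

    def test_components_bounded_by_observed_genome(self, toy_build):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 25:
            build, prof = random_toy_case(rng)
            if not prof.segments:
                continue
            obs = prof.observed_genome_bp(build)
            if obs == 0:
                continue
            ploh, lregs = compute_ploh(prof, build, SMALL_PARAMS)
            pcna, cregs = compute_pcna(prof, build, SMALL_PARAMS)
            assert 0.0 <= ploh <= 100.0 and 0.0 <= pcna <= 100.0
            assert sum(r.observed_bp for r in lregs) <= obs
            assert sum(r.observed_bp for r in cregs) <= obs
            checked += 1


class TestPerBaseOracleEquivalence:
    def test_interval_and_per_base_implementations_agree(self):
        """Randomized toy genomes: both implementations match to 1e-9."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 40:
            build, prof = random_toy_case(rng)
            if not prof.segments or prof.observed_genome_bp(build) == 0:
                continue
            o = oracle_components(prof, build, SMALL_PARAMS)
            ploh, _ = compute_ploh(prof, build, SMALL_PARAMS)
            pcna, _ = compute_pcna(prof, build, SMALL_PARAMS)
            ptcna, _ = compute_ptcna(prof, build, SMALL_PARAMS)
            assert prof.observed_genome_bp(build) == o.observed_bp
            assert ploh == pytest.approx(o.ploh, rel=1e-9, abs=1e-12)
            assert pcna == pytest.approx(o.pcna, rel=1e-9, abs=1e-12)
            if o.ptcna is None:
                assert ptcna is None
            else:
                assert ptcna == pytest.approx(o.ptcna, rel=1e-9, abs=1e-12)
            checked += 1
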