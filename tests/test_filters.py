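"""Technical-filter battery and clonal/subclonal classification rules."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from crcland.filters import (ClonalityThresholds, FilterError, FilterThresholds,
                             apply_technical_filters, classify_clonality)
from tests.test_records_io import make_variant


def passing_variant(**kw):
    """At-threshold values that must pass under >= semantics."""
    base = dict(variant_depth=7, base_quality=30.0, tumor_vaf=0.003,
                tumor_depth=10, normal_depth=None, population_af=0.0,
                strand_bias_fail=False, damage_artifact=False)
    base.update(kw)
    return make_variant(**base)


class TestTechnicalFilters:
    def test_boundary_values_pass(self):
        kept, removed = apply_technical_filters([passing_variant()])
        assert len(kept) == 1 and not removed

    @pytest.mark.parametrize(
        "kw, reason",
        [
            ({"variant_depth": 6}, "min_variant_depth"),
            ({"base_quality": 29.9}, "min_base_quality"),
            ({"tumor_vaf": 0.0029}, "min_vaf"),
            ({"tumor_depth": 9}, "min_either_depth"),
            ({"population_af": 0.005}, "max_population_af"),
            ({"strand_bias_fail": True}, "strand_bias"),
            ({"damage_artifact": True}, "damage_artifact"),
        ],
    )
    def test_each_rule_fires_with_its_reason_code(self, kw, reason):
        kept, removed = apply_technical_filters([passing_variant(**kw)])
        assert not kept
        (rec, reasons), = removed
        assert reason in reasons

    def test_either_depth_satisfied_by_normal(self):
        v = passing_variant(variant_depth=7, tumor_depth=8, normal_depth=200)
        kept, _ = apply_technical_filters([v])
        assert len(kept) == 1

    def test_kept_and_removed_partition_input(self):
        variants = [passing_variant(), passing_variant(variant_depth=1),
                    passing_variant(population_af=0.5)]
        kept, removed = apply_technical_filters(variants)
        assert len(kept) + len(removed) == len(variants)
        assert all(reasons for _, reasons in removed)

    def test_joint_low_freq_low_depth_rule(self):
        thr = FilterThresholds(low_freq_low_depth_rule=(0.05, 30))
        bad = passing_variant(tumor_vaf=0.04, tumor_depth=20, variant_depth=7)
        ok_depth = passing_variant(tumor_vaf=0.04, tumor_depth=200, variant_depth=8)
        kept, removed = apply_technical_filters([bad, ok_depth], thr)
        assert kept == [ok_depth]
        assert removed[0][1] == ["low_freq_low_depth"]

    def test_missing_field_with_enabled_rule_errors(self):
        with pytest.raises(FilterError):
            apply_technical_filters([passing_variant(variant_depth=None)])

    def test_negative_threshold_rejected(self):
        with pytest.raises(FilterError):
            FilterThresholds(min_variant_depth=-1)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 20),            # variant depth
                st.floats(0, 45),              # base quality
                st.floats(0, 0.9),             # vaf
                st.integers(0, 40),            # tumor depth
                st.floats(0, 0.01),            # population af
            ),
            min_size=1, max_size=20,
        ),
        loosened=st.sampled_from(
            ["min_variant_depth", "min_base_quality", "min_vaf",
             "min_either_depth", "max_population_af"]
        ),
    )
    def test_loosening_one_threshold_never_shrinks_kept_set(self, data, loosened):
        variants = [
            make_variant(variant_depth=min(vd, td), base_quality=bq,
                         tumor_vaf=vaf, tumor_depth=td, population_af=paf)
            for vd, bq, vaf, td, paf in data
        ]
        tight = FilterThresholds()
        looser_value = {
            "min_variant_depth": 2, "min_base_quality": 10.0, "min_vaf": 0.0005,
            "min_either_depth": 3, "max_population_af": 0.001,
        }[loosened]
        loose = dataclasses.replace(tight, **{loosened: looser_value})
        kept_tight, _ = apply_technical_filters(variants, tight)
        kept_loose, _ = apply_technical_filters(variants, loose)
        ids_tight = {id(v) for v in kept_tight}
        ids_loose = {id(v) for v in kept_loose}
        assert ids_tight <= ids_loose


class TestClonality:
    def sample(self, vafs):
        return [make_variant(tumor_vaf=v, variant_depth=None, tumor_depth=None)
                for v in vafs]

    @pytest.mark.parametrize(
        "vaf, expected",
        [
            (0.10, "clonal"),      # exactly 25% of max passes (>= semantics)
            (0.035, "excluded"),   # below max/10 = 0.04
            (0.05, "subclonal"),   # above both exclusions, below 25% of max
        ],
    )
    def test_rule_table_with_max_040(self, vaf, expected):
        calls = classify_clonality(self.sample([0.40, vaf]))
        assert calls[0].label == "clonal"
        assert calls[1].label == expected
        assert calls[1].max_vaf_used == 0.40

    def test_absolute_three_percent_exclusion(self):
        # 0.045 >= 0.40/10 but < 0.03? No: 0.045 > 0.03 -> subclonal;
        # 0.025 < 0.03 absolute -> excluded even though >= max/10 of 0.20
        calls = classify_clonality(self.sample([0.20, 0.025]))
        assert calls[1].label == "excluded"

    def test_max_vaf_variant_is_always_clonal_even_at_tiny_vaf(self):
        calls = classify_clonality(self.sample([0.02, 0.0021]))
        assert calls[0].label == "clonal"

    def test_empty_sample_errors(self):
        with pytest.raises(FilterError):
            classify_clonality([])

    @given(
        vafs=st.lists(st.floats(0.05, 1.0), min_size=1, max_size=15),
        scale=st.floats(0.3, 1.0),
    )
    def test_fraction_rules_scale_invariant_above_absolute_floor(self, vafs, scale):
        """Rescaling all VAFs preserves labels as long as nothing crosses
        the 3% absolute exclusion floor."""
        thr = ClonalityThresholds(exclusion_absolute_vaf=0.0)
        before = [c.label for c in classify_clonality(self.sample(vafs), thr)]
        after = [c.label for c in classify_clonality(
            self.sample([v * scale for v in vafs]), thr)]
        assert before == after

    def test_absolute_rule_breaks_scale_invariance(self):
        vafs = [0.40, 0.05]  # subclonal at full scale
        before = [c.label for c in classify_clonality(self.sample(vafs))]
        shrunk = [c.label for c in classify_clonality(
            self.sample([v / 2 for v in vafs]))]
        assert before[1] == "subclonal"
        assert shrunk[1] == "excluded"  # 0.025 < 3% absolute

    @given(vafs=st.lists(st.floats(0.001, 1.0), min_size=1, max_size=20))
    def test_max_variant_never_subclonal_or_excluded(self, vafs):
        calls = classify_clonality(self.sample(vafs))
        vmax = max(vafs)
        for v, call in zip(vafs, calls):
            if v == vmax:
                assert call.label == "clonal"
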