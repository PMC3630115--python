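import math

import numpy as np
import pytest

from cleavage_entropy.entropy import SpecificityProfile
from cleavage_entropy.errors import (
    ContractError,
    UndefinedCorrelationError,
    ValidationError,
)
from cleavage_entropy.profiling import (
    HIGHLY_SPECIFIC,
    SPECIFIC,
    UNSPECIFIC,
    classify_protease,
    classify_subpocket,
    count_correlation,
    group_summary,
    rank_proteases,
)


def make_profile(pid, s_values, available=None):
    s = np.array(s_values, dtype=float)
    avail = (
        np.ones(8, dtype=bool) if available is None else np.array(available, dtype=bool)
    )
    return SpecificityProfile(
        protease_id=pid,
        s=s,
        available=avail,
        effective_counts=np.full(8, 500),
        n_records=500,
    )


def flat_profile(pid, total):
    return make_profile(pid, [total / 8.0] * 8)


class TestClassifySubpocket:
    @pytest.mark.parametrize(
        "s_i,label",
        [
            (0.455, HIGHLY_SPECIFIC),
            (0.85, SPECIFIC),  # yellow boundary inclusive
            (0.95, UNSPECIFIC),
            (0.5, SPECIFIC),  # red boundary: strict <
            (0.0, HIGHLY_SPECIFIC),
            (1.0, UNSPECIFIC),
        ],
    )
    def test_labels(self, s_i, label):
        assert classify_subpocket(s_i) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            classify_subpocket(1.2)

    def test_custom_cutoffs(self):
        assert classify_subpocket(0.6, yellow_cutoff=0.55) == UNSPECIFIC
        assert classify_subpocket(0.6, red_cutoff=0.7) == HIGHLY_SPECIFIC

    def test_raising_yellow_never_makes_specific_unspecific(self):
        for s in np.linspace(0, 1, 21):
            lo = classify_subpocket(float(s), yellow_cutoff=0.7)
            hi = classify_subpocket(float(s), yellow_cutoff=0.9)
            if lo != UNSPECIFIC:
                assert hi != UNSPECIFIC


class TestClassifyProtease:
    @pytest.mark.parametrize(
        "total,label",
        [
            (7.528, UNSPECIFIC),
            (2.932, HIGHLY_SPECIFIC),
            (6.8, UNSPECIFIC),  # strict inequality at the specific cutoff
            (6.799999, SPECIFIC),
            (4.0, SPECIFIC),  # strict inequality at the highly-specific cutoff
            (3.999999, HIGHLY_SPECIFIC),
        ],
    )
    def test_labels(self, total, label):
        assert classify_protease(total) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            classify_protease(8.5)


class TestRankProteases:
    def test_ascending_order(self):
        ranking = rank_proteases(
            [flat_profile("B", 7.5), flat_profile("A", 4.5), flat_profile("C", 6.0)]
        )
        assert [r.protease_id for r in ranking] == ["A", "C", "B"]
        assert [r.rank for r in ranking] == [1, 2, 3]

    def test_tie_breaks_lexicographic(self):
        ranking = rank_proteases([flat_profile("B", 5.0), flat_profile("A", 5.0)])
        assert [r.protease_id for r in ranking] == ["A", "B"]

    def test_empty_input(self):
        assert rank_proteases([]) == []

    def test_descending(self):
        ranking = rank_proteases(
            [flat_profile("A", 4.5), flat_profile("B", 7.5)], ascending=False
        )
        assert [r.protease_id for r in ranking] == ["B", "A"]

    def test_output_is_permutation_and_idempotent(self):
        profiles = [flat_profile(f"p{i}", t) for i, t in enumerate([3, 7, 5, 1, 6])]
        ranking = rank_proteases(profiles)
        assert sorted(r.protease_id for r in ranking) == sorted(
            p.protease_id for p in profiles
        )
        again = rank_proteases([r.profile for r in ranking])
        assert [r.protease_id for r in again] == [r.protease_id for r in ranking]

    def test_partial_profiles_need_flag(self):
        partial = make_profile("x", [0.5] * 8, available=[True] * 7 + [False])
        with pytest.raises(ValidationError):
            rank_proteases([partial, flat_profile("y", 5.0)])
        ranking = rank_proteases(
            [partial, flat_profile("y", 5.0)], allow_partial=True
        )
        assert len(ranking) == 2


class TestGroupSummary:
    def test_two_member_group(self):
        summaries = group_summary(
            [flat_profile("a", 4.0), flat_profile("b", 6.0)],
            {"a": "g", "b": "g"},
        )
        (g,) = summaries
        assert g.mean_total == pytest.approx(5.0)
        assert g.min_total == pytest.approx(4.0)
        assert g.max_total == pytest.approx(6.0)
        assert g.sd_total == pytest.approx(math.sqrt(2.0), abs=1e-12)  # sample sd

    def test_population_sd_option(self):
        (g,) = group_summary(
            [flat_profile("a", 4.0), flat_profile("b", 6.0)],
            {"a": "g", "b": "g"},
            sample_sd=False,
        )
        assert g.sd_total == pytest.approx(1.0, abs=1e-12)

    def test_single_member_degenerate(self):
        (g,) = group_summary([flat_profile("a", 5.0)], {"a": "solo"})
        assert g.degenerate and g.n == 1
        assert g.mean_total == g.min_total == g.max_total == pytest.approx(5.0)
        assert g.sd_total == 0.0

    def test_unmapped_protease_listed(self):
        with pytest.raises(ValidationError, match="b"):
            group_summary(
                [flat_profile("a", 5.0), flat_profile("b", 6.0)], {"a": "g"}
            )

    def test_regrouping_permutes_summaries(self):
        profiles = [flat_profile(p, t) for p, t in [("a", 4), ("b", 6), ("c", 5)]]
        s1 = group_summary(profiles, {"a": "g1", "b": "g2", "c": "g1"})
        s2 = group_summary(profiles, {"a": "h1", "b": "h2", "c": "h1"})
        assert [g.mean_total for g in s1] == [g.mean_total for g in s2]

    def test_stats_match_direct_recomputation(self):
        rng = np.random.default_rng(61)
        profiles = [
            make_profile(f"p{i}", rng.uniform(0, 1, size=8)) for i in range(9)
        ]
        mapping = {f"p{i}": f"g{i % 3}" for i in range(9)}
        for g in group_summary(profiles, mapping):
            members = [p for p in profiles if mapping[p.protease_id] == g.key]
            totals = np.array([m.s_cleavage for m in members])
            assert g.mean_total == pytest.approx(totals.mean(), abs=1e-12)
            assert g.sd_total == pytest.approx(totals.std(ddof=1), abs=1e-12)
            s_mat = np.vstack([m.s for m in members])
            np.testing.assert_allclose(g.mean_s, s_mat.mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(g.min_s, s_mat.min(axis=0), atol=0)

    def test_callable_grouping(self):
        profiles = [flat_profile("ax", 4.0), flat_profile("bx", 6.0)]
        summaries = group_summary(profiles, lambda pid: pid[0])
        assert {g.key for g in summaries} == {"a", "b"}


class TestCountCorrelation:
    def test_identity_counts(self):
        profiles = [flat_profile(p, t) for p, t in [("a", 4), ("b", 5), ("c", 6)]]
        counts = {p.protease_id: p.s_cleavage for p in profiles}
        result = count_correlation(profiles, counts)
        assert result["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert result["spearman"] == pytest.approx(1.0, abs=1e-12)
        assert result["n"] == 3

    def test_reversed_rank_order(self):
        profiles = [flat_profile(p, t) for p, t in [("a", 4), ("b", 5), ("c", 6)]]
        counts = {"a": 300, "b": 200, "c": 100}
        assert count_correlation(profiles, counts)["spearman"] == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        # frozen from a by-hand rank computation:
        # totals (3.0, 4.0, 5.0, 6.0, 7.0), counts (10, 30, 20, 50, 40)
        # ranks of counts: (1, 3, 2, 5, 4); d = (0, -1, 1, -1, 1); sum d^2 = 4
        # spearman = 1 - 6*4/(5*24) = 0.8
        # pearson: sum xy dev = 80, sum x dev^2 = 10, sum y dev^2 = 1000
        # r = 80/sqrt(10000) = 0.8, r^2 = 0.64
        profiles = [
            flat_profile(p, t)
            for p, t in [("a", 3.0), ("b", 4.0), ("c", 5.0), ("d", 6.0), ("e", 7.0)]
        ]
        counts = {"a": 10, "b": 30, "c": 20, "d": 50, "e": 40}
        result = count_correlation(profiles, counts)
        assert result["spearman"] == pytest.approx(0.8, abs=1e-12)
        assert result["r_squared"] == pytest.approx(0.64, abs=1e-12)

    def test_constant_vector_undefined(self):
        profiles = [flat_profile(p, 5.0) for p in "abc"]
        with pytest.raises(UndefinedCorrelationError):
            count_correlation(profiles, {"a": 1, "b": 2, "c": 3})

    def test_too_few_points(self):
        profiles = [flat_profile("a", 4.0), flat_profile("b", 5.0)]
        with pytest.raises(ValidationError):
            count_correlation(profiles, {"a": 1, "b": 2})
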