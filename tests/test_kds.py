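import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperkds.agreement import AgreementError, KappaMatrix, weighted_kappa
from hyperkds.kds import (
    EnsembleSpec,
    combine_half,
    combine_least,
    combine_mean_round,
    ensemble_responses,
    kds_from_panel,
    kds_single,
    multimodel_kds,
    rank_by_kds,
    screen_models,
)
from hyperkds.panels import GradePanel

grades = st.integers(0, 3)


class TestKdsSingle:
    def test_perfect_responder_and_graders(self):
        assert kds_single(1, 1, 1, 1, 1, 1).kds == pytest.approx(0.0)

    def test_breakdown_identity(self):
        b = kds_single(0.6, 0.7, 0.65, 0.55, 0.5, 0.45)
        expected = (0.6 + 0.7 - 2 * 0.65) + (0.55 + 0.5 - 2 * 0.45)
        assert b.kds == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            kds_single(1.2, 0.7, 0.7, 0.7, 0.7, 0.7)

    @given(st.floats(-0.05, 0.05), *[st.floats(0.4, 0.9)] * 6)
    def test_shifting_grader_kappas_shifts_kds_by_minus_4_delta(
        self, delta, na, nb, ab, nc, nd, cd
    ):
        base = kds_single(na, nb, ab, nc, nd, cd).kds
        shifted = kds_single(na, nb, ab + delta, nc, nd, cd + delta).kds
        assert shifted - base == pytest.approx(-4 * delta, abs=1e-9)


class TestKdsFromPanel:
    def test_perfect_responder_substitution(self):
        # substituting kappa_n* = 1 collapses the score to 2(1-kab)+2(1-kcd)
        for kab, kcd in [(0.748, 0.653), (1.0, 1.0), (0.2, 0.9)]:
            b = kds_single(1, 1, kab, 1, 1, kcd)
            assert b.kds == pytest.approx(2 * (1 - kab) + 2 * (1 - kcd), abs=1e-12)
            assert b.kds >= 0

    def test_responder_identical_to_one_grader_per_pair(self):
        # responder cloning grader A (and C) has kappa_nb = kappa_ab and
        # kappa_nd = kappa_cd, so KDS reduces to (1-kab)+(1-kcd)
        rng = np.random.default_rng(3)
        records = []
        for i in range(30):
            subset = "AB" if i < 15 else "CD"
            g = int(rng.integers(0, 4))
            for rater in ("A", "C", "N"):
                records.append((f"i{i:02d}", rater, g, subset))
            for rater in ("B", "D"):
                noisy = int(np.clip(g + (1 if rng.random() < 0.3 else 0), 0, 3))
                records.append((f"i{i:02d}", rater, noisy, subset))
        panel = GradePanel.from_records(records)
        b = kds_from_panel(panel, "N", ["A", "B", "C", "D"])
        assert b.kappa_na == pytest.approx(1.0)
        assert b.kappa_nc == pytest.approx(1.0)
        assert b.kappa_nb == pytest.approx(b.kappa_ab, abs=1e-12)
        assert b.kappa_nd == pytest.approx(b.kappa_cd, abs=1e-12)
        assert b.kds == pytest.approx(
            (1 - b.kappa_ab) + (1 - b.kappa_cd), abs=1e-12
        )
        assert b.kds >= 0

    def test_composes_from_subsetwise_kappas(self, tagged_panel):
        b = kds_from_panel(tagged_panel, "N", ["A", "B", "C", "D"])
        ab = tagged_panel.images(subset="AB")
        cd = tagged_panel.images(subset="CD")
        expected = kds_single(
            weighted_kappa(tagged_panel, "N", "A", ab).kappa,
            weighted_kappa(tagged_panel, "N", "B", ab).kappa,
            weighted_kappa(tagged_panel, "A", "B", ab).kappa,
            weighted_kappa(tagged_panel, "N", "C", cd).kappa,
            weighted_kappa(tagged_panel, "N", "D", cd).kappa,
            weighted_kappa(tagged_panel, "C", "D", cd).kappa,
        )
        assert b.kds == pytest.approx(expected.kds, abs=1e-12)

    def test_untagged_panel_rejected(self, two_rater_panel):
        with pytest.raises(AgreementError, match="subset"):
            kds_from_panel(two_rater_panel, "X", ["X", "Y", "X", "Y"])

    def test_responder_missing_on_cd_subset_errors(self, tagged_panel):
        frame = tagged_panel.frame.copy()
        sel = (frame["rater_id"] == "N") & (frame["subset"] == "CD")
        frame = frame[~sel]  # responder silent on the whole CD subset
        with pytest.raises(AgreementError):
            kds_from_panel(GradePanel(frame), "N", ["A", "B", "C", "D"])


class TestScreening:
    def _matrix(self, values, raters=None):
        values = np.asarray(values, dtype=float)
        raters = raters or [f"M{i}" for i in range(len(values))]
        return KappaMatrix(raters, values)

    def test_all_high_agreement_is_identity(self):
        v = np.full((4, 4), 0.9)
        np.fill_diagonal(v, 1.0)
        report = screen_models(self._matrix(v))
        assert report.excluded == []
        assert report.survivors == ["M0", "M1", "M2", "M3"]

    def test_single_dissenter_excluded(self):
        # M3 anti-correlated with the rest
        v = np.array(
            [
                [1.0, 0.9, 0.9, -0.5],
                [0.9, 1.0, 0.9, -0.5],
                [0.9, 0.9, 1.0, -0.5],
                [-0.5, -0.5, -0.5, 1.0],
            ]
        )
        report = screen_models(self._matrix(v))
        assert [r for r, _ in report.excluded] == ["M3"]
        assert report.survivors == ["M0", "M1", "M2"]

    def test_two_step_cascade_recomputes_means(self):
        # hand-built: with M3 present both M2 and M3 fall at/below 0.7
        # (M2 mean = (0.75+0.75+0.30)/3 = 0.60); removing M3 (mean 0.37,
        # the lowest) lifts M2 to 0.75 -> exactly one exclusion.
        v = np.array(
            [
                [1.0, 0.9, 0.75, 0.4],
                [0.9, 1.0, 0.75, 0.4],
                [0.75, 0.75, 1.0, 0.3],
                [0.4, 0.4, 0.3, 1.0],
            ]
        )
        report = screen_models(self._matrix(v))
        assert [r for r, _ in report.excluded] == ["M3"]
        assert "M2" in report.survivors

    def test_threshold_is_inclusive_for_exclusion(self):
        # mean exactly 0.7 ("0.7 or less") must be excluded
        v = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.9], [0.9, 0.9, 1.0]])
        v[2, 1] = v[1, 2] = 0.9
        v[0, 2] = v[2, 0] = 0.7
        report = screen_models(self._matrix(v))
        assert report.excluded == [("M0", pytest.approx(0.7))]
        assert report.survivors == ["M1", "M2"]

    def test_exhausting_panel_raises(self):
        v = np.array([[1.0, 0.1], [0.1, 1.0]])
        with pytest.raises(AgreementError, match="exhausted"):
            screen_models(self._matrix(v))


class TestCombiners:
    def test_half_rule_majority_match(self):
        # four of six members answer 2, matching the expert
        assert combine_half([2, 2, 2, 2, 1, 1], 2) == 2

    def test_half_rule_no_match_unanimous_plurality(self):
        assert combine_half([1, 1, 1], 3) == 1

    def test_half_rule_exact_half_is_not_enough(self):
        # 3 of 6 matches is not "more than half": falls to plurality
        assert combine_half([2, 2, 2, 1, 1, 1], 2) == 1

    @pytest.mark.parametrize(
        "policy,expected", [("lowest", 1), ("highest", 2), ("nearest_mean", 1)]
    )
    def test_tie_policies_enumerated(self, policy, expected):
        # members (1,1,2,2), expert 3: no match, tied plurality {1, 2};
        # mean 1.5 -> nearest_mean prefers the lower of the equidistant pair
        assert combine_half([1, 1, 2, 2], 3, tie_policy=policy) == expected

    def test_least_rule_single_match_suffices(self):
        assert combine_least([0, 3, 1], 3) == 3

    def test_least_rule_no_match_plurality(self):
        assert combine_least([1, 1, 2], 3) == 1

    @given(st.lists(grades, min_size=1, max_size=4), grades, grades)
    def test_output_is_member_or_expert_grade(self, members, expert, _):
        allowed = set(members) | {expert}
        assert combine_half(members, expert) in allowed
        assert combine_least(members, expert) in allowed

    def test_mean_round_examples(self):
        assert combine_mean_round([2, 2, 2, 2, 2, 2]) == 2
        assert combine_mean_round([1, 2, 2, 2, 1, 2]) == 2  # mean 1.667
        assert combine_mean_round([1, 1, 2, 2]) == 2  # half rounds up

    def test_empty_members_rejected(self):
        for fn in (lambda: combine_half([], 2), lambda: combine_least([], 2),
                   lambda: combine_mean_round([])):
            with pytest.raises(ValueError):
                fn()


class TestEnsembleSpec:
    def test_reference_required_for_expert_rules(self):
        with pytest.raises(ValueError, match="reference"):
            EnsembleSpec(members=("a", "b"), rule="half")

    def test_mean_round_refuses_reference(self):
        with pytest.raises(ValueError):
            EnsembleSpec(members=("a", "b"), rule="mean_round", reference="S")

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSpec(members=("a", "a"), rule="mean_round")


# frozen closed-form z-scores of the series (1..6) under population SD
Z_SERIES_1_TO_6 = (-1.4639, -0.8783, -0.2928, 0.2928, 0.8783, 1.4639)


class TestMultimodel:
    def _responder_panel(self, n_members=7, n_images=60, seed=5):
        rng = np.random.default_rng(seed)
        records = []
        truth = {}
        for i in range(n_images):
            img = f"i{i:02d}"
            subset = "AB" if i < n_images // 2 else "CD"
            g = int(rng.integers(0, 4))
            truth[img] = g
            for rater in ("A", "B", "C", "D"):
                noisy = int(np.clip(g + rng.choice([-1, 0, 0, 0, 1]), 0, 3))
                records.append((img, rater, noisy, subset))
            for m in range(n_members):
                noisy = int(np.clip(g + rng.choice([-1, 0, 0, 1]), 0, 3))
                records.append((img, f"M{m}", noisy, subset))
        return GradePanel.from_records(records), truth

    def test_z_scores_of_linear_series(self):
        # inject hand-built kds series by standardising directly
        from hyperkds.kds import _z_standardise

        z, mean, se = _z_standardise(np.arange(1.0, 7.0))
        assert mean == pytest.approx(3.5)
        assert np.allclose(z, Z_SERIES_1_TO_6, atol=1e-3)

    def test_table_structure_and_zero_sums(self):
        panel, truth = self._responder_panel()
        ranked = [r for r, _ in rank_by_kds(panel, [f"M{m}" for m in range(7)],
                                            ["A", "B", "C", "D"])]
        table = multimodel_kds(panel, ranked, ["A", "B", "C", "D"], truth)
        assert table.ns == [2, 3, 4, 5, 6, 7]
        assert abs(table.z_half.sum()) < 1e-9
        assert abs(table.z_least.sum()) < 1e-9
        assert abs(table.kds_multi.sum()) < 1e-9
        assert table.members_per_n[3] == ranked[:3]

    def test_identical_members_degenerate(self):
        panel, truth = self._responder_panel(n_members=1)
        # clone M0 six times: every ensemble responds identically
        frame = panel.frame
        clones = []
        base = frame[frame["rater_id"] == "M0"]
        for m in range(1, 7):
            clones.append(base.assign(rater_id=f"M{m}"))
        import pandas as pd

        panel = GradePanel(pd.concat([frame, *clones], ignore_index=True))
        with pytest.raises(AgreementError, match="degenerate normalisation"):
            multimodel_kds(
                panel, [f"M{m}" for m in range(7)], ["A", "B", "C", "D"], truth
            )

    def test_least_rule_kds_never_below_half_rule(self):
        # a least-rule ensemble matches the expert at least as often
        panel, truth = self._responder_panel(seed=9)
        members = [f"M{m}" for m in range(4)]
        half = ensemble_responses(panel, members, "half", truth)
        least = ensemble_responses(panel, members, "least", truth)
        n_half = sum(1 for i, g in half.items() if g == truth[i])
        n_least = sum(1 for i, g in least.items() if g == truth[i])
        assert n_least >= n_half
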