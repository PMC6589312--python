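import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperkds.agreement import (
    AgreementError,
    pairwise_kappa_matrix,
    qualify_graders,
    quadratic_weighted_kappa,
    weighted_kappa,
)
from hyperkds.panels import UNGRADABLE, GradePanel

from oracles import contingency_kappa

# frozen from the brute-force contingency oracle on the fixture ratings
KAPPA_ONE_STEP_FIXTURE = 0.85
THREE_RATER_KAPPAS = {
    ("R1", "R2"): 0.8333333333333334,
    ("R1", "R3"): 0.8333333333333334,
    ("R2", "R3"): 0.6190476190476191,
}


def panel_from_vectors(a, b):
    records = []
    for i, (ga, gb) in enumerate(zip(a, b)):
        records.append((f"img{i}", "X", ga))
        records.append((f"img{i}", "Y", gb))
    return GradePanel.from_records(records)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        panel = panel_from_vectors([0, 1, 2, 3, 1, 2, 0, 3], [0, 1, 2, 3, 1, 2, 0, 3])
        assert weighted_kappa(panel, "X", "Y").kappa == pytest.approx(1.0)

    def test_one_step_fixture_matches_oracle(self, two_rater_panel):
        res = weighted_kappa(two_rater_panel, "X", "Y")
        assert res.kappa == pytest.approx(KAPPA_ONE_STEP_FIXTURE, abs=1e-12)

    def test_ungradable_images_excluded_and_counted(self):
        a = [0, 1, 2, 3, 1, 2, 0, 3, 2, 1]
        b = [0, 1, 2, 3, 1, 2, 0, 3, 2, UNGRADABLE]
        panel = panel_from_vectors(a, b)
        res = weighted_kappa(panel, "X", "Y")
        assert res.n_used == 9
        assert res.n_excluded == 1

    def test_too_few_images_raises(self):
        panel = panel_from_vectors([2], [2])
        with pytest.raises(AgreementError, match="at least 2"):
            weighted_kappa(panel, "X", "Y")

    def test_degenerate_marginals_raises(self):
        panel = panel_from_vectors([2, 2, 2], [2, 2, 2])
        with pytest.raises(AgreementError, match="degenerate"):
            weighted_kappa(panel, "X", "Y")

    def test_symmetry(self, two_rater_panel):
        xy = weighted_kappa(two_rater_panel, "X", "Y").kappa
        yx = weighted_kappa(two_rater_panel, "Y", "X").kappa
        assert xy == pytest.approx(yx, abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=12
        ).filter(lambda ps: len({p[0] for p in ps} | {p[1] for p in ps}) > 1)
    )
    def test_matches_contingency_oracle(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        assert quadratic_weighted_kappa(a, b) == pytest.approx(
            contingency_kappa(a, b), abs=1e-12
        )

    @given(st.permutations(list(range(8))))
    def test_image_order_irrelevant(self, order):
        a = [0, 0, 1, 1, 2, 2, 3, 3]
        b = [0, 1, 1, 2, 2, 3, 3, 3]
        shuffled = quadratic_weighted_kappa(
            [a[i] for i in order], [b[i] for i in order]
        )
        assert shuffled == pytest.approx(KAPPA_ONE_STEP_FIXTURE, abs=1e-12)

    def test_duplicating_pairs_equals_cell_weighting(self):
        # merging identical rating pairs twice == doubling that cell
        a = [0, 1, 2, 3, 1]
        b = [0, 2, 2, 3, 1]
        doubled = quadratic_weighted_kappa(a + a, b + b)
        assert doubled == pytest.approx(quadratic_weighted_kappa(a, b), abs=1e-12)


class TestKappaMatrix:
    def test_identical_raters_all_ones(self):
        g = [0, 1, 2, 3, 1, 2]
        records = []
        for rater in ("P", "Q", "R"):
            records += [(f"img{i}", rater, v) for i, v in enumerate(g)]
        matrix = pairwise_kappa_matrix(GradePanel.from_records(records), ["P", "Q", "R"])
        off = matrix.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(matrix.row_means, 1.0)

    def test_symmetric(self, three_rater_panel):
        matrix = pairwise_kappa_matrix(three_rater_panel, ["R1", "R2", "R3"])
        assert np.allclose(matrix.values, matrix.values.T, atol=1e-12)

    def test_matches_oracle_entries(self, three_rater_panel):
        matrix = pairwise_kappa_matrix(three_rater_panel, ["R1", "R2", "R3"])
        for (rx, ry), expected in THREE_RATER_KAPPAS.items():
            i, j = matrix.raters.index(rx), matrix.raters.index(ry)
            assert matrix.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_errors_name_the_pair(self):
        records = [("i0", "P", 2), ("i1", "P", 1), ("i0", "Q", 2), ("i1", "Q", 1),
                   ("i0", "R", UNGRADABLE), ("i1", "R", 1)]
        with pytest.raises(AgreementError, match=r"\(P, R\)|\(R, P\)"):
            pairwise_kappa_matrix(GradePanel.from_records(records), ["P", "Q", "R"])

    def test_csv_and_json_serialisation(self, three_rater_panel, tmp_path):
        matrix = pairwise_kappa_matrix(three_rater_panel, ["R1", "R2", "R3"])
        out = tmp_path / "m.csv"
        matrix.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "rater,R1,R2,R3"
        assert "row_means" in matrix.to_json()


class TestQualifyGraders:
    def test_identical_candidate_qualifies(self):
        g = [0, 1, 2, 3, 0, 2]
        records = [(f"i{n}", r, v) for r in ("REF", "C") for n, v in enumerate(g)]
        rows = qualify_graders(GradePanel.from_records(records), "REF", ["C"])
        assert rows == [("C", pytest.approx(1.0), True)]

    def test_random_rater_near_zero_kappa(self):
        rng = np.random.default_rng(11)
        n = 2000
        truth = rng.integers(0, 4, size=n)
        noise = rng.integers(0, 4, size=n)
        records = [(f"i{k}", "REF", int(truth[k])) for k in range(n)]
        records += [(f"i{k}", "C", int(noise[k])) for k in range(n)]
        rows = qualify_graders(GradePanel.from_records(records), "REF", ["C"])
        (_, kappa, qualified) = rows[0]
        assert abs(kappa) < 0.1
        assert not qualified

    def test_boundary_is_strict(self):
        # a candidate with kappa exactly at the threshold is not qualified
        g = [0, 1, 2, 3, 0, 2]
        records = [(f"i{n}", r, v) for r in ("REF", "C") for n, v in enumerate(g)]
        rows = qualify_graders(
            GradePanel.from_records(records), "REF", ["C"], threshold=1.0
        )
        assert rows[0][2] is False

    def test_listwise_exclusion_shares_image_set(self):
        records = [
            ("i0", "REF", 0), ("i1", "REF", 1), ("i2", "REF", 2), ("i3", "REF", 3),
            ("i0", "C1", 0), ("i1", "C1", 1), ("i2", "C1", 2), ("i3", "C1", 1),
            ("i0", "C2", 0), ("i1", "C2", 1), ("i2", "C2", 2), ("i3", "C2", UNGRADABLE),
        ]
        panel = GradePanel.from_records(records)
        listwise = qualify_graders(panel, "REF", ["C1", "C2"], listwise=True)
        pairwise = qualify_graders(panel, "REF", ["C1", "C2"], listwise=False)
        # i3 (ungradable for C2) is dropped for everyone under listwise,
        # so C1's disagreement there disappears; pairwise keeps it
        k_c1_listwise = [k for r, k, _ in listwise if r == "C1"][0]
        k_c1_pairwise = [k for r, k, _ in pairwise if r == "C1"][0]
        assert k_c1_listwise == pytest.approx(1.0)
        assert k_c1_pairwise < 1.0
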