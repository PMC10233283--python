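"""Cell-assembly extraction, linking criterion and curve summaries."""

import numpy as np
import pandas as pd
import pytest

from fastmapnet import (
    CAExtractionParams,
    CellAssembly,
    category_specificity,
    export_tidy_results,
    extract_ca,
    is_linked,
    linking_rate,
    reactivated_fraction,
)
from fastmapnet.analysis import OBJECT_AREAS, curve_row, threshold_rates
from oracles import ca_threshold_oracle, linking_fraction_oracle


class TestGammaThreshold:
    def test_matches_brute_force_on_random_rate_fields(self, rng):
        """gamma-relative thresholding equals an exhaustive per-cell scan,
        including areas with zero maximum."""
        for _ in range(20):
            rates = rng.uniform(0, 1, (5, 40))
            rates[rng.integers(0, 5)] = 0.0  # one silent area
            # exact ties at the threshold occur with duplicated values
            rates[0, :10] = rates[0, 20]
            got = threshold_rates(rates, gamma=0.5)
            want = ca_threshold_oracle(rates, 0.5)
            for g, w in zip(got, want):
                assert list(g) == w

    def test_silent_network_yields_empty_ca(self, micro_net):
        ca = extract_ca(micro_net, {}, CAExtractionParams())
        assert all(len(c) == 0 for c in ca.cells.values())

    def test_tie_at_threshold_is_included(self):
        rates = np.array([[1.0, 0.5, 0.49, 0.0]])
        assert list(threshold_rates(rates, 0.5)[0]) == [0, 1]


class TestLinkingCriterion:
    def _ca(self, **areas):
        return CellAssembly(cells={a: frozenset(c) for a, c in areas.items()})

    def test_zero_overlap_not_linked(self):
        word = self._ca(V1=[600, 601], TO=[3], AT=[])
        ref = self._ca(V1=range(22), TO=range(100, 110), AT=range(200, 208))
        res = is_linked(word, ref, "object")
        assert not res.linked and res.fraction == 0.0

    def test_exact_ten_percent_boundary_is_linked(self):
        # referent: 40 cells pooled over V1/TO/AT; word reactivates exactly 4
        ref = self._ca(V1=range(22), TO=range(10), AT=range(50, 58))
        word = self._ca(V1=[0, 1, 2], TO=[5], AT=[])
        res = is_linked(word, ref, "object")
        assert res.fraction == pytest.approx(0.10)
        assert res.linked

    def test_fractions_match_brute_force_on_random_toy_cas(self, rng):
        for _ in range(50):
            ref = self._ca(
                V1=rng.choice(625, 22, replace=False),
                TO=rng.choice(625, rng.integers(1, 30), replace=False),
                AT=rng.choice(625, rng.integers(1, 30), replace=False),
            )
            word = self._ca(
                V1=rng.choice(625, rng.integers(0, 60), replace=False),
                TO=rng.choice(625, rng.integers(0, 60), replace=False),
                AT=rng.choice(625, rng.integers(0, 60), replace=False),
            )
            frac = reactivated_fraction(word, ref, OBJECT_AREAS)
            hit, tot = linking_fraction_oracle(
                {a: word.cells[a] for a in OBJECT_AREAS},
                {a: ref.cells[a] for a in OBJECT_AREAS},
                OBJECT_AREAS,
            )
            assert frac == pytest.approx(hit / tot)
            res = is_linked(word, ref, "object")
            assert res.linked == (frac >= 0.10)

    def test_empty_referent_representation_raises(self):
        word = self._ca(V1=[1])
        ref = self._ca(V1=[], TO=[], AT=[])
        with pytest.raises(ValueError):
            is_linked(word, ref, "object")

    def test_action_words_use_motor_areas(self):
        ref = self._ca(M1_L=range(20), PM_L=range(10), PF_L=range(10))
        word = self._ca(M1_L=[0, 1, 2, 3], V1=range(50))  # V1 hits are irrelevant
        res = is_linked(word, ref, "action")
        assert res.fraction == pytest.approx(4 / 40)
        assert res.fraction_by_rank["primary"] == pytest.approx(4 / 20)
        assert res.fraction_by_rank["secondary"] == 0.0


def _toy_curves():
    rows = []
    area_names = ("A1", "V1", "TO", "AT", "M1_L", "PM_L", "PF_L")
    counts = {
        ("object", "V1"): 20, ("object", "TO"): 10, ("object", "AT"): 8,
        ("object", "M1_L"): 2, ("object", "PM_L"): 1, ("object", "PF_L"): 1,
        ("action", "V1"): 4, ("action", "TO"): 2, ("action", "AT"): 3,
        ("action", "M1_L"): 18, ("action", "PM_L"): 9, ("action", "PF_L"): 7,
    }
    for net in (0, 1):
        for w, wt, linked in (("w0", "object", True), ("w1", "object", net == 0),
                              ("w3", "action", False), ("w4", "action", True)):
            row = {"network": net, "word": w, "word_type": wt, "step": 5,
                   "linked": linked, "frac_incorrect_max": 0.0}
            for a in area_names:
                row[f"cells_{a}"] = counts.get((wt, a), 0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestCurveSummaries:
    def test_linking_rate_all_linked_is_100(self):
        df = _toy_curves()
        df["linked"] = True
        mean, se = linking_rate(df, 5)
        assert mean == 100.0 and se == 0.0

    def test_linking_rate_hand_computed_mean_and_se(self):
        df = _toy_curves()
        # net0: 3/4 linked, net1: 2/4 linked -> mean 62.5%, SE of (75, 50)
        mean, se = linking_rate(df, 5)
        assert mean == pytest.approx(62.5)
        assert se == pytest.approx(np.std([75.0, 50.0], ddof=1) / np.sqrt(2))

    def test_linking_rate_missing_step_raises(self):
        with pytest.raises(ValueError):
            linking_rate(_toy_curves(), 99)

    def test_category_specificity_zero_for_identical_counts(self):
        df = _toy_curves()
        for a in ("V1", "TO", "AT"):
            df[f"cells_{a}"] = 7
        assert category_specificity(df, "V1") == 0.0

    def test_category_specificity_hand_computed_and_sign_convention(self):
        df = _toy_curves()
        # visual area: object mean - action mean (positive = object-preferring)
        assert category_specificity(df, "V1") == pytest.approx(20 - 4)
        assert category_specificity(df, "TO") == pytest.approx(10 - 2)
        # motor area: action mean - object mean (positive = action-preferring)
        assert category_specificity(df, "M1_L") == pytest.approx(18 - 2)
        assert category_specificity(df, "PF_L") == pytest.approx(7 - 1)

    def test_category_specificity_rejects_perisylvian_area(self):
        with pytest.raises(ValueError):
            category_specificity(_toy_curves(), "A1")

    def test_export_roundtrip_schema_and_row_count(self, tmp_path):
        df = _toy_curves()
        out = export_tidy_results(df, tmp_path / "curves.csv", {"seed": 1})
        back = pd.read_csv(out)
        assert list(back.columns) == list(df.columns)
        assert len(back) == len(df)
        pd.testing.assert_frame_equal(
            back, df, check_dtype=False, check_exact=False, atol=1e-12
        )
        assert (tmp_path / "curves.meta.json").exists()


def test_curve_row_contains_all_area_counts():
    from fastmapnet.analysis import LinkResult

    link = LinkResult(True, 0.2, {"primary": 0.3, "secondary": 0.1, "hub": 0.0})
    ca = CellAssembly(cells={"A1": frozenset([1, 2]), "V1": frozenset()})
    row = curve_row(3, "w0", "object", 7, link, 0.0, ca, ("A1", "V1"))
    assert row["cells_A1"] == 2 and row["cells_V1"] == 0
    assert row["linked"] and row["step"] == 7 and row["network"] == 3
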