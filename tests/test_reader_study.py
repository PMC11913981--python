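"""Turing-test statistics: misclassification rates, Fleiss kappa, presentation images."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

from spinesynth.reader_study import (
    RatingTable,
    fleiss_kappa,
    interpret_kappa,
    load_example_rates,
    misclassification_rate,
    prepare_turing_image,
    rate_summary,
    round_half_up,
    summarize_rates,
)
from spinesynth.volume import ImageVolume


def make_table(truths, ratings_by_rater, modality="t1w"):
    items = pd.DataFrame({
        "item_id": [f"i{i}" for i in range(len(truths))],
        "modality": modality,
        "truth": truths,
    })
    ratings = pd.DataFrame(ratings_by_rater)
    return RatingTable(items, ratings)


class TestMisclassificationRate:
    def test_all_correct_is_zero(self):
        truths = ["real", "generated"] * 5
        table = make_table(truths, {"r1": truths, "r2": truths})
        assert misclassification_rate(table, "r1", "t1w") == 0.0

    def test_direct_count(self):
        truths = ["real"] * 10
        judged = ["generated"] * 4 + ["real"] * 6
        table = make_table(truths, {"r1": judged})
        assert misclassification_rate(table, "r1", "t1w") == pytest.approx(0.4)

    def test_flipped_column_gives_complement(self):
        rng = np.random.default_rng(0)
        truths = list(rng.choice(["real", "generated"], size=20))
        judged = list(rng.choice(["real", "generated"], size=20))
        flipped = ["real" if j == "generated" else "generated" for j in judged]
        table = make_table(truths, {"a": judged, "b": flipped})
        r_a = misclassification_rate(table, "a", "t1w")
        r_b = misclassification_rate(table, "b", "t1w")
        assert r_a + r_b == pytest.approx(1.0)

    def test_unknown_rater_or_empty_modality_rejected(self):
        table = make_table(["real"] * 4, {"r1": ["real"] * 4})
        with pytest.raises(ValueError, match="rater"):
            misclassification_rate(table, "nobody", "t1w")
        with pytest.raises(ValueError, match="modality"):
            misclassification_rate(table, "r1", "stir")


class TestRateSummary:
    def test_seven_reader_t1w_column_means_point_39(self):
        rates = load_example_rates()
        mean, sd = rate_summary(rates["t1w"])
        assert mean == 0.39

    def test_seven_reader_stir_column_means_point_42(self):
        rates = load_example_rates()
        mean, sd = rate_summary(rates["stir"])
        assert mean == 0.42

    def test_identical_rates_have_zero_sd(self):
        mean, sd = rate_summary([0.3, 0.3, 0.3])
        assert (mean, sd) == (0.3, 0.0)

    def test_half_up_rounding(self):
        assert round_half_up(0.425) == 0.43
        assert round_half_up(0.424999) == 0.42

    def test_summarize_from_table_matches_direct_rates(self):
        truths = ["real", "generated"] * 3
        judged1 = ["real"] * 6
        judged2 = ["generated"] * 6
        table = make_table(truths, {"a": judged1, "b": judged2})
        mean, sd = summarize_rates(table, "t1w")
        assert mean == 0.5


class TestFleissKappa:
    def test_perfect_agreement_on_mixed_table_is_one(self):
        labels = ["real", "generated", "real", "generated", "real"]
        table = make_table(["real"] * 5, {"a": labels, "b": labels, "c": labels})
        res = fleiss_kappa(table, "t1w")
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "Very good"

    def test_independent_coin_flips_give_near_zero(self):
        rng = np.random.default_rng(42)
        n = 500
        ratings = {f"r{j}": list(rng.choice(["real", "generated"], size=n)) for j in range(5)}
        table = make_table(["real"] * n, ratings)
        res = fleiss_kappa(table, "t1w")
        assert abs(res.kappa) < 0.05

    def test_hand_table_matches_formula_from_scratch(self):
        """4 items x 3 raters, evaluated against a by-hand spreadsheet calculation."""
        table = make_table(
            ["real"] * 4,
            {
                "a": ["real", "real", "generated", "real"],
                "b": ["real", "generated", "generated", "real"],
                "c": ["real", "real", "generated", "generated"],
            },
        )
        # counts per item (real, generated): (3,0), (2,1), (0,3), (2,1)
        # P_i = (sum n_ij^2 - n) / (n (n-1)) -> 1, 1/3, 1, 1/3 ; P_bar = 2/3
        # p_real = 7/12, p_gen = 5/12 ; P_e = (7/12)^2 + (5/12)^2 = 74/144
        p_bar = 2.0 / 3.0
        p_e = 74.0 / 144.0
        expected = (p_bar - p_e) / (1 - p_e)
        res = fleiss_kappa(table, "t1w")
        assert res.kappa == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            n = 60
            ratings = {
                f"r{j}": list(rng.choice(["real", "generated"], size=n, p=[0.6, 0.4]))
                for j in range(4)
            }
            table = make_table(["real"] * n, ratings)
            res = fleiss_kappa(table, "t1w")
            counts = np.stack(
                [
                    (table.ratings.values == "real").sum(axis=1),
                    (table.ratings.values == "generated").sum(axis=1),
                ],
                axis=1,
            )
            assert res.kappa == pytest.approx(sm_fleiss(counts), abs=1e-9)

    def test_two_raters_equals_classical_two_rater_formula(self):
        rng = np.random.default_rng(11)
        n = 200
        a = rng.choice(["real", "generated"], size=n)
        b = np.where(rng.random(n) < 0.7, a, rng.choice(["real", "generated"], size=n))
        table = make_table(["real"] * n, {"a": list(a), "b": list(b)})
        res = fleiss_kappa(table, "t1w")
        p_o = float(np.mean(a == b))
        p_real = ((a == "real").sum() + (b == "real").sum()) / (2 * n)
        p_e = p_real**2 + (1 - p_real) ** 2
        classical = (p_o - p_e) / (1 - p_e)
        assert res.kappa == pytest.approx(classical, abs=1e-9)

    def test_item_and_rater_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 40
        ratings = {f"r{j}": list(rng.choice(["real", "generated"], size=n)) for j in range(4)}
        table = make_table(["real"] * n, ratings)
        base = fleiss_kappa(table, "t1w").kappa
        perm = rng.permutation(n)
        table2 = RatingTable(
            table.items.iloc[perm].reset_index(drop=True),
            table.ratings.iloc[perm][["r2", "r0", "r3", "r1"]].reset_index(drop=True),
        )
        assert fleiss_kappa(table2, "t1w").kappa == pytest.approx(base, abs=1e-12)

    def test_degenerate_single_category_reported(self):
        table = make_table(["real"] * 5, {"a": ["real"] * 5, "b": ["real"] * 5})
        res = fleiss_kappa(table, "t1w")
        assert res.degenerate
        assert "one category" in res.message

    def test_ci99_uses_z_2576(self):
        rng = np.random.default_rng(5)
        n = 100
        ratings = {f"r{j}": list(rng.choice(["real", "generated"], size=n)) for j in range(3)}
        table = make_table(["real"] * n, ratings)
        res = fleiss_kappa(table, "t1w")
        assert res.ci99[0] == pytest.approx(res.kappa - 2.576 * res.se)
        assert res.ci99[1] == pytest.approx(res.kappa + 2.576 * res.se)


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "k,band",
        [(0.09, "Poor"), (0.2, "Poor"), (0.21, "Fair"), (0.4, "Fair"),
         (0.41, "Moderate"), (0.6, "Moderate"), (0.61, "Good"), (0.8, "Good"),
         (0.81, "Very good"), (1.0, "Very good"), (-0.3, "Poor")],
    )
    def test_printed_scale_with_lower_boundary_ownership(self, k, band):
        assert interpret_kappa(k) == band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestPrepareTuringImage:
    def test_output_is_150_square_and_deterministic(self, t2w_volume):
        center = t2w_volume.voxel_to_world(np.asarray(t2w_volume.shape) // 2)
        img = prepare_turing_image(t2w_volume, center)
        assert img.shape == (150, 150)
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert np.array_equal(img, prepare_turing_image(t2w_volume, center))

    def test_landmark_lands_at_image_center(self):
        vol = ImageVolume(np.zeros((9, 80, 80)), np.diag([3.0, 1.1, 1.1, 1.0]))
        vol.data[4, 30, 50] = 1.0
        center = vol.voxel_to_world([4, 30, 50])
        img = prepare_turing_image(vol, center)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert abs(peak[0] - 75) <= 1 and abs(peak[1] - 75) <= 1

    def test_center_outside_volume_rejected(self, t2w_volume):
        with pytest.raises(ValueError, match="outside"):
            prepare_turing_image(t2w_volume, (1000.0, 0.0, 0.0))


def test_rating_table_validation():
    items = pd.DataFrame({"item_id": ["a"], "modality": ["t1w"], "truth": ["real"]})
    with pytest.raises(ValueError, match="missing"):
        RatingTable(items, pd.DataFrame({"r1": [np.nan]}))
    with pytest.raises(ValueError, match="labels"):
        RatingTable(items, pd.DataFrame({"r1": ["maybe"]}))
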