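import numpy as np
import pandas as pd
import pytest

from pollinet.repro_stats import (
    empty_fruit_fraction,
    fit_gradient_glm,
    paired_t,
)
from pollinet.synthetic import (
    DistanceParams,
    ReproductionParams,
    generate_distance_gradient,
    generate_reproduction,
)


def repro_frame(values_by_plant, period, species="S"):
    """Build a per-fruit frame where each plant's seeds list defines its
    fruits; flowers = 2 * fruits so fruit_set = 0.5 everywhere unless
    overridden with (flowers, seeds_list) tuples."""
    rows = []
    for plant, entry in values_by_plant.items():
        if isinstance(entry, tuple):
            flowers, seeds = entry
        else:
            flowers, seeds = 2 * len(entry), entry
        for k, s in enumerate(seeds):
            rows.append((species, plant, period, flowers, len(seeds),
                         f"F{k}", s, s + 2, 1.0))
        if not seeds:
            rows.append((species, plant, period, flowers, 0, None,
                         np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=[
        "plant_species", "plant_individual", "period", "flowers", "fruits",
        "fruit_id", "seeds", "ovules", "seed_mass_mg"])


class TestPairedT:
    def test_alternating_differences_give_zero_t(self):
        pre = repro_frame({f"p{i}": [2] for i in range(4)}, "pre")
        post = repro_frame({f"p{i}": [2 + d] for i, d in enumerate([1, -1, 1, -1])},
                           "apis")
        res = paired_t(pre, post, "seeds_per_fruit", transform="none")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_textbook_differences(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        pre = repro_frame({"p1": [5], "p2": [5], "p3": [5]}, "pre")
        post = repro_frame({"p1": [6], "p2": [7], "p3": [8]}, "apis")
        res = paired_t(pre, post, "seeds_per_fruit", transform="none")
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=2e-3)

    def test_unmatched_plants_dropped_and_counted(self):
        pre = repro_frame({"p1": [2], "p2": [3], "orphan": [9]}, "pre")
        post = repro_frame({"p1": [4], "p2": [5], "other": [9]}, "apis")
        res = paired_t(pre, post, "seeds_per_fruit", transform="none")
        assert res.n_pairs == 2
        assert res.n_dropped == 2

    def test_swapping_periods_negates_t(self):
        pre = repro_frame({"p1": [2], "p2": [5], "p3": [4]}, "pre")
        post = repro_frame({"p1": [3], "p2": [9], "p3": [5]}, "apis")
        a = paired_t(pre, post, "seeds_per_fruit", transform="none")
        b = paired_t(post, pre, "seeds_per_fruit", transform="none")
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_log_transform_flags_zero_adjustment(self):
        pre = repro_frame({"p1": [0], "p2": [2], "p3": [1]}, "pre")
        post = repro_frame({"p1": [1], "p2": [3], "p3": [2]}, "apis")
        res = paired_t(pre, post, "seeds_per_fruit", transform="log")
        assert res.zero_adjusted

    def test_too_few_pairs_errors(self):
        pre = repro_frame({"p1": [2]}, "pre")
        post = repro_frame({"p1": [3]}, "apis")
        with pytest.raises(ValueError, match="at least 2"):
            paired_t(pre, post, "seeds_per_fruit")

    def test_fruit_set_uses_flower_totals(self):
        pre = repro_frame({"p1": (10, [1] * 4), "p2": (10, [1] * 2)}, "pre")
        post = repro_frame({"p1": (10, [1] * 6), "p2": (10, [1] * 8)}, "apis")
        res = paired_t(pre, post, "fruit_set")
        assert res.mean_pre == pytest.approx((0.4 + 0.2) / 2)
        assert res.mean_apis == pytest.approx((0.6 + 0.8) / 2)


class TestGradientGLM:
    def test_poisson_reproduces_class_means_exactly(self):
        """Saturated categorical Poisson MLE equals per-class sample means."""
        df = generate_distance_gradient(
            DistanceParams(n_plants_per_class=(8, 8, 8, 8, 8, 8),
                           fruits_per_plant=10, seed=1)
        )
        res = fit_gradient_glm(df, "seeds_per_fruit")
        per_plant = (
            df.groupby(["plant_individual", "distance_class_m"])["seeds"]
            .mean()
            .reset_index()
        )
        sample = per_plant.groupby("distance_class_m")["seeds"].mean()
        for c in sample.index:
            assert res.class_means[c] == pytest.approx(sample[c], abs=1e-8)

    def test_two_class_closed_form(self):
        # class means 2 and 4 -> intercept ln 2, contrast ln 2
        rows = []
        for k in range(6):
            rows.append(("S", f"a{k}", 0, "F1", 2, 4, 1.0))
            rows.append(("S", f"b{k}", 100, "F1", 4, 6, 1.0))
        df = pd.DataFrame(rows, columns=[
            "plant_species", "plant_individual", "distance_class_m", "fruit_id",
            "seeds", "ovules", "seed_mass_mg"])
        res = fit_gradient_glm(df, "seeds_per_fruit")
        assert res.coefficients["Intercept"] == pytest.approx(np.log(2), abs=1e-6)
        assert res.coefficients["C(dist)[T.100]"] == pytest.approx(np.log(2), abs=1e-6)

    def test_identical_classes_are_nonsignificant(self):
        rows = []
        for d in (0, 100, 500):
            for k in range(5):
                rows.append(("S", f"p{d}-{k}", d, "F1", 3, 5, 2.0))
        df = pd.DataFrame(rows, columns=[
            "plant_species", "plant_individual", "distance_class_m", "fruit_id",
            "seeds", "ovules", "seed_mass_mg"])
        res = fit_gradient_glm(df, "seeds_per_fruit")
        assert (res.tukey["p_adj"] >= 0.99).all()

    def test_near_hive_seed_deficit_detected(self):
        """With the default monotone gradient the near-hive contrasts are
        significantly negative in nearly all seeded simulations."""
        hits = 0
        n = 30
        for s in range(n):
            df = generate_distance_gradient(
                DistanceParams(n_plants_per_class=(15,) * 6, fruits_per_plant=20,
                               seed=s)
            )
            res = fit_gradient_glm(df, "seeds_per_fruit")
            row = res.tukey[(res.tukey.class_a == 0) & (res.tukey.class_b == 4000)]
            hits += (row["estimate"].iloc[0] > 0) and (row["p_adj"].iloc[0] < 0.05)
        assert hits >= int(0.9 * n)

    def test_seed_mass_model_uses_lognormal_family(self):
        df = generate_distance_gradient(
            DistanceParams(n_plants_per_class=(10,) * 6, fruits_per_plant=10, seed=3)
        )
        res = fit_gradient_glm(df, "seed_mass")
        assert res.family == "lognormal"
        assert res.covariate == "seeds"
        assert len(res.tukey) == 15  # k(k-1)/2 for 6 classes

    def test_robust_option_emits_second_table(self):
        df = generate_distance_gradient(
            DistanceParams(n_plants_per_class=(6,) * 6, fruits_per_plant=8, seed=4)
        )
        res = fit_gradient_glm(df, "seeds_per_fruit", robust=True)
        assert res.robust_tukey is not None
        assert len(res.robust_tukey) == len(res.tukey)


class TestEmptyFruitFraction:
    def test_hand_fractions(self):
        df = pd.DataFrame({
            "distance_class_m": [0, 0, 0, 100, 100],
            "seeds": [0, 0, 3, 2, 1],
        })
        frac = empty_fruit_fraction(df)
        assert frac[0] == pytest.approx(2 / 3)
        assert frac[100] == 0.0

    def test_matches_generator_rate_within_3se(self):
        p = DistanceParams(n_plants_per_class=(40, 0, 0, 0, 0, 0),
                           fruits_per_plant=25, plant_sd=0.0, seed=5)
        df = generate_distance_gradient(p)
        observed = empty_fruit_fraction(df)[0]
        # class 0: explicit empty prob + Poisson zeros among non-empty
        p_empty = p.empty_p[0] + (1 - p.empty_p[0]) * np.exp(-p.seeds_mean[0])
        n = 40 * 25
        se = np.sqrt(p_empty * (1 - p_empty) / n)
        assert abs(observed - p_empty) <= 3 * se


class TestPairedPowerAndTypeI:
    def test_type_one_error_near_alpha(self):
        rej = 0
        n = 150
        for s in range(n):
            rp = ReproductionParams(n_plants=25, seeds_mean=(2.0, 2.0),
                                    fruit_set=(0.5, 0.5), seed=3000 + s)
            df = generate_reproduction(rp)
            res = paired_t(df[df.period == "pre"], df[df.period == "apis"],
                           "seeds_per_fruit")
            rej += res.p < 0.05
        assert 0.01 <= rej / n <= 0.11

    def test_thirty_percent_seed_decline_is_detected(self):
        hits = 0
        n = 100
        for s in range(n):
            rp = ReproductionParams(n_plants=25, seeds_mean=(2.0, 1.4),
                                    seed=4000 + s)
            df = generate_reproduction(rp)
            res = paired_t(df[df.period == "pre"], df[df.period == "apis"],
                           "seeds_per_fruit")
            hits += (res.p < 0.05) and (res.t < 0)
        assert hits >= 0.8 * n
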