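"""Mismatch statistics: t-tests, three-way ANOVA, contrasts, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from loudmatch import analysis
from loudmatch.analysis import (
    bonferroni,
    compute_mismatch,
    condition_tests,
    diotic_vs_matched_correlation,
    mode_pairwise_tests,
    room_marginal_contrasts,
    three_way_anova,
)

from conftest import make_mismatch_frame


def brute_force_anova(df: pd.DataFrame) -> dict[str, float]:
    """Textbook balanced three-way ANOVA sums of squares, computed directly.

    Independent of statsmodels: cell/marginal means and explicit SS
    formulas for a balanced design with replicates.
    """
    factors = ["room", "stimulus", "mode"]
    y = df["mismatch"].to_numpy()
    grand = y.mean()
    n_total = y.size
    levels = {f: sorted(df[f].unique()) for f in factors}
    n_rep = n_total // np.prod([len(levels[f]) for f in factors])

    def group_ss(by):
        means = df.groupby(by)["mismatch"].mean()
        counts = df.groupby(by)["mismatch"].count()
        return float((counts * (means - grand) ** 2).sum())

    ss = {f: group_ss([f]) for f in factors}
    for a, b in itertools.combinations(factors, 2):
        ss[f"{a} x {b}"] = group_ss([a, b]) - ss[a] - ss[b]
    ss_cells = group_ss(factors)
    ss["room x stimulus x mode"] = (
        ss_cells
        - sum(ss[f] for f in factors)
        - sum(ss[f"{a} x {b}"] for a, b in itertools.combinations(factors, 2))
    )
    ss_resid = float(((y - df.groupby(factors)["mismatch"].transform("mean")) ** 2).sum())
    df_resid = n_total - np.prod([len(levels[f]) for f in factors])

    out = {}
    terms = {
        **{f: len(levels[f]) - 1 for f in factors},
        **{
            f"{a} x {b}": (len(levels[a]) - 1) * (len(levels[b]) - 1)
            for a, b in itertools.combinations(factors, 2)
        },
        "room x stimulus x mode": int(np.prod([len(levels[f]) - 1 for f in factors])),
    }
    for term, df_num in terms.items():
        out[term] = (ss[term] / df_num) / (ss_resid / df_resid)
    return out


class TestComputeMismatch:
    def _results(self, hp_l, ls_l, hp_r=np.nan, ls_r=np.nan, mode="diotic"):
        return pd.DataFrame(
            {
                "subject": ["S1"], "site": ["OL"], "room": ["OL_anechoic"],
                "stimulus": ["tbn250"], "mode": [mode],
                "hp_level_eardrum_left": [hp_l], "hp_level_eardrum_right": [hp_r],
                "ls_level_eardrum_left": [ls_l], "ls_level_eardrum_right": [ls_r],
            }
        )

    def test_headphone_minus_loudspeaker(self):
        mm = compute_mismatch(self._results(71.0, 65.0))
        assert mm["mismatch"].iloc[0] == pytest.approx(6.0)
        assert compute_mismatch(self._results(65.0, 65.0))["mismatch"].iloc[0] == 0.0

    def test_antisymmetric_under_source_swap(self):
        res = self._results(71.0, 65.0, 70.0, 66.0)
        swapped = res.rename(
            columns={
                "hp_level_eardrum_left": "ls_level_eardrum_left",
                "ls_level_eardrum_left": "hp_level_eardrum_left",
                "hp_level_eardrum_right": "ls_level_eardrum_right",
                "ls_level_eardrum_right": "hp_level_eardrum_right",
            }
        )
        a = compute_mismatch(res)["mismatch"].iloc[0]
        b = compute_mismatch(swapped)["mismatch"].iloc[0]
        assert a == pytest.approx(-b)

    def test_ear_conventions_differ_only_for_asymmetric_ears(self):
        sym = self._results(71.0, 65.0, 71.0, 65.0)
        asym = self._results(71.0, 65.0, 73.0, 65.0)
        for res, differ in ((sym, False), (asym, True)):
            left = compute_mismatch(res, "left")["mismatch"].iloc[0]
            mean = compute_mismatch(res, "per_ear_mean")["mismatch"].iloc[0]
            assert (left != mean) == differ

    def test_missing_counterpart_rows_excluded(self, caplog):
        res = self._results(71.0, np.nan)
        with caplog.at_level("WARNING"):
            mm = compute_mismatch(res)
        assert len(mm) == 0
        assert "excluding" in caplog.text


class TestConditionTests:
    def test_full_factorial_yields_64_tests(self):
        mm = make_mismatch_frame(n_subjects=3)
        out = condition_tests(mm)
        assert len(out) == 64

    def test_null_data_nothing_significant(self):
        mm = make_mismatch_frame(n_subjects=8, noise_sd=1.0, seed=1)
        out = condition_tests(mm)
        assert out["significant"].sum() == 0

    def test_large_shift_detected_after_correction(self):
        key = ("OL_anechoic", "tbn250", "diotic")
        mm = make_mismatch_frame(n_subjects=27, effects={key: 6.0}, seed=2)
        out = condition_tests(mm)
        hit = out.set_index(["room", "stimulus", "mode"]).loc[key]
        assert hit["significant"]
        # t = 6 / (sd/sqrt(27)) is enormous; all other conditions stay null
        assert out["significant"].sum() == 1

    def test_bonferroni_monotone_and_capped(self):
        p = np.array([0.001, 0.02, 0.5])
        adj = bonferroni(p, 64)
        assert np.all(adj >= p)
        assert adj.max() <= 1.0

    def test_singleton_condition_flagged_untested(self, caplog):
        mm = make_mismatch_frame(n_subjects=1)
        with caplog.at_level("WARNING"):
            out = condition_tests(mm)
        assert out["t"].isna().all()
        assert not out["significant"].any()


class TestThreeWayAnova:
    def test_matches_brute_force_on_balanced_toy(self):
        """2 x 2 x 2 design with 4 replicates: F values agree with the
        direct sums-of-squares computation to 1e-10 relative error."""
        mm = make_mismatch_frame(
            n_subjects=4,
            rooms=("r1", "r2"), stimuli=("s1", "s2"), modes=("m1", "m2"),
            effects={("r1", "s1", "m1"): 3.0, ("r2", "s2", "m2"): -1.5},
            seed=3,
        )
        got = three_way_anova(mm).set_index("term")
        expected = brute_force_anova(mm)
        for term, f_exp in expected.items():
            assert got.loc[term, "F"] == pytest.approx(f_exp, rel=1e-10)
        assert (got["df_den"] == len(mm) - 8).all()

    def test_implanted_room_effect_dominates(self):
        effects = {
            (room, s, m): {"OL_anechoic": 0.0, "AC_anechoic": 4.0,
                           "OL_earpiecelab": 0.0, "AC_teakitchen": 4.0}[room]
            for room in ("OL_anechoic", "AC_anechoic", "OL_earpiecelab", "AC_teakitchen")
            for s in ("tbn250", "tbn1000", "tbn4000", "uen17")
            for m in ("monaural", "diotic", "ic_matched", "uncorrelated")
        }
        mm = make_mismatch_frame(n_subjects=10, effects=effects, seed=4)
        table = three_way_anova(mm).set_index("term")
        assert table.loc["room", "p"] < 1e-6
        assert table.loc["room", "F"] > 10 * table.loc["stimulus", "F"]
        assert table.loc["room x stimulus x mode", "p"] > 0.01

    def test_empty_cells_rejected(self):
        mm = make_mismatch_frame(n_subjects=3)
        mm = mm[~((mm.room == "OL_anechoic") & (mm.stimulus == "tbn250") & (mm["mode"] == "diotic"))]
        with pytest.raises(ValueError, match="empty design cells"):
            three_way_anova(mm)


class TestRoomContrasts:
    def test_four_rooms_give_six_pairs(self):
        out = room_marginal_contrasts(make_mismatch_frame(n_subjects=5))
        assert len(out) == 6

    def test_identical_rooms_not_significant(self):
        out = room_marginal_contrasts(make_mismatch_frame(n_subjects=10, seed=5))
        assert np.allclose(out["delta"], 0.0, atol=1.0)
        assert not out["significant"].any()

    def test_implanted_offset_recovered(self):
        effects = {
            ("AC_anechoic", s, m): 2.6
            for s in ("tbn250", "tbn1000", "tbn4000", "uen17")
            for m in ("monaural", "diotic", "ic_matched", "uncorrelated")
        }
        mm = make_mismatch_frame(n_subjects=27, effects=effects, noise_sd=2.0, seed=6)
        out = room_marginal_contrasts(mm).set_index("pair")
        row = out.loc["AC_anechoic - OL_anechoic"]
        assert row["delta"] == pytest.approx(2.6, abs=2 * row["se"])
        assert row["significant"]


class TestModePairwise:
    def test_monaural_contrasts_significant(self):
        effects = {
            (r, s, "monaural"): 7.0
            for r in ("OL_anechoic", "AC_anechoic", "OL_earpiecelab", "AC_teakitchen")
            for s in ("tbn250", "tbn1000", "tbn4000", "uen17")
        }
        mm = make_mismatch_frame(n_subjects=15, effects=effects, seed=7)
        out = mode_pairwise_tests(mm)
        mono = out[(out["mode_a"] == "diotic") & (out["mode_b"] == "monaural")]
        assert mono["significant"].all()
        assert np.allclose(mono["delta"], -7.0, atol=1.5)

    def test_identical_modes_not_significant_and_family_reported(self):
        mm = make_mismatch_frame(n_subjects=10, seed=8)
        out = mode_pairwise_tests(mm)
        assert not out["significant"].any()
        assert (out["family_size"] == 6).all()
        assert (out["n_comparisons_total"] == 16 * 6).all()


class TestCorrelations:
    def test_identical_modes_give_unit_correlation(self):
        mm = make_mismatch_frame(n_subjects=10, noise_sd=0.0, seed=9)
        rng = np.random.default_rng(0)
        subject_effect = {f"S{s:02d}": rng.normal(0, 2) for s in range(10)}
        mm["mismatch"] = mm["subject"].map(subject_effect)
        out = diotic_vs_matched_correlation(mm)
        assert np.allclose(out["r"], 1.0)

    def test_independent_data_rarely_significant(self):
        mm = make_mismatch_frame(n_subjects=12, seed=10)
        out = diotic_vs_matched_correlation(mm)
        assert out["significant"].mean() < 0.3
        assert np.all(np.abs(out["r"]) <= 1.0)

    def test_offset_structure_keeps_high_correlation(self):
        """Room-matched = diotic - 2 dB + small noise: r near 1 with the
        diotic values sitting above the diagonal."""
        mm = make_mismatch_frame(n_subjects=15, noise_sd=0.0)
        rng = np.random.default_rng(11)
        subject_effect = {f"S{s:02d}": rng.normal(4, 2) for s in range(15)}
        base = mm["subject"].map(subject_effect)
        mm["mismatch"] = np.where(
            mm["mode"] == "ic_matched", base - 2 + rng.normal(0, 0.3, len(mm)), base
        )
        out = diotic_vs_matched_correlation(mm)
        assert (out["r"] > 0.9).all()


class TestAswSummary:
    def _asw(self, ratings, mm=None):
        frame = make_mismatch_frame(n_subjects=len(ratings) // 64 or 1, noise_sd=0.0)
        frame = frame.rename(columns={"mismatch": "rating"})
        frame["rating"] = ratings[: len(frame)]
        return frame

    def test_zero_ratings_zero_means(self):
        asw = self._asw(np.zeros(64))
        summary, _ = analysis.asw_summary(asw)
        assert (summary["mean"] == 0).all()

    def test_out_of_scale_ratings_rejected(self, caplog):
        ratings = np.zeros(64)
        ratings[0] = 75.0
        with caplog.at_level("WARNING"):
            summary, _ = analysis.asw_summary(self._asw(ratings))
        assert "out-of-scale" in caplog.text
        assert summary["n"].sum() == 63

    def test_negative_link_to_mismatch_recovered(self):
        mm = make_mismatch_frame(n_subjects=20, noise_sd=3.0, seed=12)
        rng = np.random.default_rng(13)
        asw = mm.rename(columns={"mismatch": "rating"}).copy()
        asw["rating"] = np.clip(-4 * mm["mismatch"] + rng.normal(0, 2, len(mm)), -50, 50)
        _, corr = analysis.asw_summary(asw, mm)
        assert (corr["r"] < -0.5).all()
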