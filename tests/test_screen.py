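"""Combinatorial screen: enumeration, FDR, tallies and shift predictions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nutriage.models import build_model_spec, fit_gam
from nutriage.screen import (
    bh_fdr,
    enumerate_triples,
    flag_screen,
    predict_sd_shift,
    run_screen,
    tally_screen,
)


def _bh_bruteforce(p, q):
    """Literal step-up definition, independent of the implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    flags = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            kmax = rank
    flags[order[:kmax]] = True
    return flags


class TestEnumerateTriples:
    @pytest.mark.parametrize("n,expected", [(19, 969), (3, 1), (8, 56)])
    def test_counts(self, n, expected):
        triples = enumerate_triples([f"v{i:02d}" for i in range(n)])
        assert len(triples) == expected
        assert len(set(triples)) == expected

    def test_lexicographic_and_deterministic(self):
        triples = enumerate_triples(["c", "a", "b", "d"])
        assert triples[0] == ("a", "b", "c")
        assert triples == enumerate_triples(["d", "c", "b", "a"])

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_triples(["a", "b", "b", "c"])


class TestBhFdr:
    def test_all_ones_nothing_significant(self):
        q_adj, flags = bh_fdr(np.ones(10))
        assert not flags.any()
        np.testing.assert_allclose(q_adj, 1.0)

    def test_single_small_p_significant(self):
        _, flags = bh_fdr([0.01], q=0.05)
        assert flags.all()

    def test_matches_bruteforce_on_worked_example(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.27, 0.60]
        q_adj, flags = bh_fdr(p, q=0.05)
        np.testing.assert_array_equal(flags, _bh_bruteforce(p, 0.05))
        assert (q_adj >= np.asarray(p)).all()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_bruteforce_and_never_exceeds_uncorrected(self, p):
        q_adj, flags = bh_fdr(p, q=0.05)
        np.testing.assert_array_equal(flags, _bh_bruteforce(p, 0.05))
        assert flags.sum() <= (np.asarray(p) <= 0.05).sum()

    def test_empty_input(self):
        q_adj, flags = bh_fdr([])
        assert q_adj.size == 0 and flags.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            bh_fdr([0.5, 1.2])


def _screen_data(rng, ns=60, nv=2, effect=0.0, effect_var="v1"):
    n = ns * nv
    df = pd.DataFrame({f"v{j}": rng.normal(0, 1, n) for j in range(4)})
    df["subject_id"] = np.repeat(np.arange(ns), nv)
    u = np.repeat(rng.normal(0, 0.3, ns), nv)
    df["s1"] = u + rng.normal(0, 1, n) + effect * df[effect_var] ** 2
    df["s2"] = u + rng.normal(0, 1, n)
    return df


class TestRunScreen:
    def test_bookkeeping_four_vars_two_outcomes(self, rng):
        df = _screen_data(rng)
        triples = enumerate_triples(["v0", "v1", "v2", "v3"])
        table = run_screen(triples, ["s1", "s2"], df, k=15)
        assert len(table) == len(triples) * 2 == 8
        assert table["p"].between(0, 1).all()
        assert (table["n"] == len(df)).all()

    def test_checkpoint_resume_skips_done_fits(self, rng, tmp_path):
        df = _screen_data(rng)
        triples = enumerate_triples(["v0", "v1", "v2", "v3"])
        ckpt = tmp_path / "ckpt.csv"
        first = run_screen(triples[:2], ["s1"], df, k=15, checkpoint=ckpt)
        full = run_screen(triples, ["s1"], df, k=15, checkpoint=ckpt)
        merged = full.set_index("triple")
        for t in first["triple"]:
            assert merged.loc[t, "p"] == pytest.approx(
                first.set_index("triple").loc[t, "p"]
            )

    def test_planted_triple_attains_minimum_p(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            df = _screen_data(rng, ns=120, effect=0.5, effect_var="v1")
            triples = enumerate_triples(["v0", "v1", "v2", "v3"])
            table = run_screen(triples, ["s1"], df, k=15)
            best = table.loc[table["p"].idxmin(), "triple"]
            if "v1" in best.split("+"):
                hits += 1
        assert hits >= 4


class TestFlagAndTally:
    def _toy_table(self):
        rows = []
        sig = {
            ("t1", "o1"): True, ("t1", "o2"): True, ("t1", "o3"): True,
            ("t2", "o3"): True,
            ("t3", "o1"): True,
        }
        members = {"t1": ("a", "b", "c"), "t2": ("a", "d", "e"),
                   "t3": ("f", "g", "h"), "t4": ("b", "d", "f"),
                   "t5": ("c", "e", "g")}
        for t, (v1, v2, v3) in members.items():
            for o in ("o1", "o2", "o3"):
                rows.append(
                    {"triple": t, "var1": v1, "var2": v2, "var3": v3,
                     "outcome": o, "p": 0.01 if sig.get((t, o)) else 0.8,
                     "significant": bool(sig.get((t, o), False))}
                )
        return pd.DataFrame(rows)

    def test_hand_tallied_counts(self):
        table = self._toy_table()
        counts = tally_screen(table, ageing_outcomes=("o3",), containing="a")
        assert counts["n_triples_significant_any"] == 3  # t1, t2, t3
        assert counts["n_triples_ageing_only"] == 1  # t2 (o3 only)
        assert counts["n_triples_significant_all"] == 1  # t1 covers o1-o3
        assert counts["n_containing_a"] == 2  # t1 and t2

    def test_exclusion_list_relaxes_all_outcome_criterion(self):
        table = self._toy_table()
        counts = tally_screen(table, exclude_outcomes=("o2", "o3"))
        # with only o1 required: t1 and t3 qualify
        assert counts["n_triples_significant_all"] == 2

    def test_all_flags_false_gives_zero_counts(self):
        table = self._toy_table()
        table["significant"] = False
        counts = tally_screen(table, ageing_outcomes=("o3",), containing="a")
        assert all(v == 0 for v in counts.values())

    def test_unknown_containing_variable_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            tally_screen(self._toy_table(), containing="zzz")

    def test_flags_consistent_with_q_threshold(self, rng):
        df = _screen_data(rng, ns=80, effect=0.6)
        triples = enumerate_triples(["v0", "v1", "v2", "v3"])
        table = flag_screen(run_screen(triples, ["s1", "s2"], df, k=15), q=0.05)
        assert (table["q"] >= table["p"] - 1e-12).all()
        np.testing.assert_array_equal(
            table["significant"].to_numpy(), (table["q"] <= 0.05).to_numpy()
        )


class TestRefitWithConfounders:
    def test_top_hit_refit_under_adjusted_model(self):
        rng = np.random.default_rng(17)
        ns, nv = 100, 3
        n = ns * nv
        df = pd.DataFrame({f"v{j}": rng.normal(0, 1, n) for j in range(4)})
        df["subject_id"] = np.repeat(np.arange(ns), nv)
        for col, gen in (
            ("income", lambda: rng.normal(30000, 8000, n)),
            ("education_years", lambda: rng.integers(6, 20, n).astype(float)),
            ("alcohol_g_day", lambda: rng.gamma(1.2, 7, n)),
            ("pase", lambda: rng.normal(90, 30, n)),
            ("age", lambda: rng.uniform(67, 84, n)),
            ("comorbidity_count", lambda: rng.poisson(3, n).astype(float)),
        ):
            df[col] = gen()
        df["sex"] = np.where(rng.random(n) < 0.5, "men", "women")
        df["smoking"] = np.where(rng.random(n) < 0.1, "current", "not_current")
        df["s1"] = 0.8 * df["v0"] ** 2 + rng.normal(0, 0.5, n)
        triples = enumerate_triples(["v0", "v1", "v2", "v3"])
        from nutriage.screen import refit_with_confounders

        flagged = flag_screen(run_screen(triples, ["s1"], df, k=15), q=0.05)
        assert flagged["significant"].any()
        refits = refit_with_confounders(flagged, df, top_n=1)
        assert len(refits) == 1
        assert refits["adjusted_p"].iloc[0] < 0.05
        assert "v0" in refits["triple"].iloc[0]


@pytest.fixture(scope="module")
def linear_fit():
    rng = np.random.default_rng(9)
    n = 1200
    df = pd.DataFrame({f"v{j}": rng.normal(0, 1, n) for j in range(3)})
    df["subject_id"] = np.arange(n) // 3
    beta = 0.4
    df["s1"] = beta * df["v0"] + rng.normal(0, 0.4, n)
    spec = build_model_spec("screen", "s1", micro_triple=("v0", "v1", "v2"), k=15)
    return fit_gam(spec, df), beta


class TestPredictSdShift:

    def test_zero_shift_is_zero_change(self, linear_fit):
        fit, _ = linear_fit
        assert predict_sd_shift(fit, "v0", 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_planted_linear_effect_scales_with_shift(self, linear_fit):
        fit, beta = linear_fit
        x = fit.results.model.data["v0"]
        expected = 2.0 * x.std(ddof=0) * beta
        assert predict_sd_shift(fit, "v0", 2.0) == pytest.approx(expected, abs=0.1)

    def test_variable_not_in_fit_rejected(self, linear_fit):
        fit, _ = linear_fit
        with pytest.raises(ValueError, match="not in the fitted model"):
            predict_sd_shift(fit, "nope", 2.0)

    def test_raw_unit_evaluation_point(self):
        """A variable with mean 4.75 and SD 2.73 shifted by +2 SD is
        evaluated at 10.21 in raw units."""
        rng = np.random.default_rng(4)
        n = 400
        v0 = 4.75 + 2.73 * np.append(np.ones(n // 2), -np.ones(n // 2))
        df = pd.DataFrame(
            {"v0": v0, "v1": rng.normal(0, 1, n), "v2": rng.normal(0, 1, n)}
        )
        df["subject_id"] = np.arange(n)
        df["s1"] = 0.1 * df["v0"] + rng.normal(0, 0.3, n)
        mu, sd = df["v0"].mean(), df["v0"].std(ddof=0)
        assert mu + 2 * sd == pytest.approx(10.21, abs=1e-9)
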