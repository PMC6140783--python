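"""qPCR 2^-dCt reductions, two-way ANOVA and luciferase normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from dmrqtl import assays
from dmrqtl.tables_io import CtTable, LuminescenceTable, ValidationError

HK = ("18S", "GAPDH", "HPRT1")


def ct_table(rows):
    data = pd.DataFrame(rows, columns=["sample", "gene", "condition", "replicate", "ct"])
    return CtTable(data=data, housekeepers=HK)


def simple_ct(target_ct_by_sample, hk_ct=20.0, gene="RUNX2_P1", condition="+DMR"):
    rows = []
    for sample, ct in target_ct_by_sample.items():
        rows.append((sample, gene, condition, 1, ct))
        for hk in HK:
            rows.append((sample, hk, condition, 1, hk_ct))
    return ct_table(rows)


class TestDdct:
    def test_target_equal_to_housekeepers_gives_unit_expression(self):
        res = assays.ddct_expression(simple_ct({"S1": 20.0}))
        row = res.per_sample.iloc[0]
        assert row["delta_ct"] == pytest.approx(0.0)
        assert row["rel_expr"] == pytest.approx(1.0)

    @pytest.mark.parametrize("dct,expected", [(2.0, 0.25), (-2.0, 4.0)])
    def test_powers_of_two(self, dct, expected):
        res = assays.ddct_expression(simple_ct({"S1": 20.0 + dct}))
        assert res.per_sample.iloc[0]["rel_expr"] == pytest.approx(expected)

    def test_housekeeper_aggregate_is_ct_mean(self):
        rows = [("S1", "RUNX2_P1", "+DMR", 1, 24.0)]
        for hk, ct in zip(HK, (10.0, 18.0, 26.0)):  # mean 18
            rows.append(("S1", hk, "+DMR", 1, ct))
        res = assays.ddct_expression(ct_table(rows))
        assert res.per_sample.iloc[0]["delta_ct"] == pytest.approx(24.0 - 18.0)

    def test_fold_change_between_conditions(self):
        rows = []
        for cond, ct in (("+DMR", 24.0), ("-DMR", 22.0)):  # dCt drop of 2 -> x4
            for i in range(3):
                rows.append((f"{cond}{i}", "RUNX2_P1", cond, 1, ct))
                for hk in HK:
                    rows.append((f"{cond}{i}", hk, cond, 1, 20.0))
        res = assays.ddct_expression(ct_table(rows), condition_pair=("+DMR", "-DMR"))
        assert res.fold_change["RUNX2_P1"] == pytest.approx(4.0)

    def test_fold_change_invariant_to_global_ct_shift(self):
        rng = np.random.default_rng(0)
        rows = []
        for cond in ("+DMR", "-DMR"):
            for i in range(4):
                s = f"{cond}{i}"
                rows.append((s, "RUNX2_P1", cond, 1, 24 + rng.normal(0, 0.3)))
                for hk in HK:
                    rows.append((s, hk, cond, 1, 20 + rng.normal(0, 0.3)))
        base = ct_table(rows)
        shifted = ct_table([(s, g, c, r, ct + 3.5) for s, g, c, r, ct in rows])
        f0 = assays.ddct_expression(base).fold_change["RUNX2_P1"]
        f1 = assays.ddct_expression(shifted).fold_change["RUNX2_P1"]
        assert f0 == pytest.approx(f1, rel=1e-12)

    def test_missing_target_ct_drops_sample_with_warning(self):
        rows = [("S1", "RUNX2_P1", "+DMR", 1, 24.0)]
        for s in ("S1", "S2"):
            for hk in HK:
                rows.append((s, hk, "+DMR", 1, 20.0))
        with pytest.warns(UserWarning, match="S2"):
            res = assays.ddct_expression(ct_table(rows), targets=["RUNX2_P1"])
        assert list(res.per_sample["sample"]) == ["S1"]

    def test_simulated_deletion_shift_recovered(self):
        """A true -log2(3.9)-cycle shift on one target is recovered as a
        ~3.9-fold expression increase (mean over 100 simulated experiments)."""
        from dmrqtl.simulate import default_config, simulate_ct

        folds = []
        cfg = default_config(n_samples=4, seed=0)
        for i in range(100):
            ct = simulate_ct(cfg, rng=np.random.default_rng(70_000 + i))
            res = assays.ddct_expression(ct, condition_pair=("+DMR", "-DMR"))
            folds.append(res.fold_change["RUNX2_P1"])
        assert np.mean(folds) == pytest.approx(3.9, rel=0.06)


class TestTwowayAnova:
    def grid(self, values):
        rows = []
        for (g, c), cell in values.items():
            for v in cell:
                rows.append({"gene": g, "condition": c, "rel_expr": v})
        return pd.DataFrame(rows)

    def test_constant_response_gives_f_zero_p_one(self):
        df = self.grid({(g, c): [2.0, 2.0] for g in "AB" for c in "XY"})
        table = assays.twoway_anova(df)
        assert (table.loc[["C(g)", "C(c)", "C(g):C(c)"], "F"] == 0).all()
        assert (table.loc[["C(g)", "C(c)", "C(g):C(c)"], "PR(>F)"] == 1).all()

    def test_additive_effects_have_zero_interaction(self):
        # response = gene effect + condition effect exactly
        df = self.grid({("A", "X"): [1.0, 1.0], ("A", "Y"): [3.0, 3.0],
                        ("B", "X"): [2.0, 2.0], ("B", "Y"): [4.0, 4.0]})
        table = assays.twoway_anova(df)
        assert table.loc["C(g):C(c)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_type2_equals_type1_when_balanced(self, seed):
        rng = np.random.default_rng(seed)
        df = self.grid({(g, c): list(rng.normal(5, 1, 4)) for g in "AB" for c in "XY"})
        t2 = assays.twoway_anova(df)
        model = smf.ols("rel_expr ~ C(gene) * C(condition)",
                        data=df.rename(columns={})).fit()
        t1 = sm.stats.anova_lm(model, typ=1)
        np.testing.assert_allclose(
            t2["sum_sq"].to_numpy()[:3],
            t1["sum_sq"].to_numpy()[:3],
            rtol=1e-9,
        )

    def test_empty_cell_error_names_cell(self):
        df = self.grid({("A", "X"): [1.0, 2.0], ("A", "Y"): [3.0, 4.0],
                        ("B", "X"): [2.0, 3.0]})
        with pytest.raises(ValidationError, match="B.*Y"):
            assays.twoway_anova(df)


def exact_mw_oracle(x, y):
    """Brute force: enumerate every assignment of the pooled values to the
    two groups; two-sided p is the probability of a U at least as extreme
    (distance from nm/2) as observed."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    u_obs = u_stat(x, y)
    center = n * m / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        total += 1
        if abs(u_stat(xs, ys) - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_triplets_give_p_point_one(self):
        """{1,2,3} vs {4,5,6}: U=0, the most extreme of C(6,3)=20 splits in
        either direction, so exact two-sided p = 2/20 = 0.1."""
        u, p = assays.mann_whitney_exact(np.array([1, 2, 3.0]), np.array([4, 5, 6.0]))
        assert p == pytest.approx(0.1, abs=1e-12)
        assert exact_mw_oracle(np.array([1, 2, 3.0]), np.array([4, 5, 6.0])) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 5))
        y = rng.normal(0.5, 1, rng.integers(3, 5))
        _, p = assays.mann_whitney_exact(x, y)
        assert p == pytest.approx(exact_mw_oracle(x, y), abs=1e-10)

    def test_tied_data_handled_exactly_for_small_n(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 5.0, 6.0])
        _, p = assays.mann_whitney_exact(x, y)
        assert p == pytest.approx(exact_mw_oracle(x, y), abs=1e-10)


class TestLuciferase:
    def lum_table(self, cells):
        rows = []
        w = 0
        for (construct, state), wells in cells.items():
            for firefly, renilla in wells:
                w += 1
                rows.append((f"W{w}", construct, state, firefly, renilla))
        return LuminescenceTable(data=pd.DataFrame(
            rows, columns=["well", "construct", "methylation_state", "firefly", "renilla"]
        ))

    def test_control_mean_activity_is_exactly_one(self):
        lum = self.lum_table({
            ("empty", "non-methylated"): [(100, 200), (120, 200), (140, 200)],
            ("TG", "non-methylated"): [(300, 200), (320, 200), (340, 200)],
        })
        res = assays.luciferase_normalize(lum)
        s = res.summary.set_index("construct")
        assert s.loc["empty", "mean_activity"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_construct_and_control_gives_p_one(self):
        wells = [(100, 200), (120, 210), (140, 190)]
        lum = self.lum_table({
            ("empty", "methylated"): wells,
            ("CT", "methylated"): wells,
        })
        res = assays.luciferase_normalize(lum)
        p = res.summary.set_index("construct").loc["CT", "p_vs_control"]
        assert p == pytest.approx(1.0)

    def test_multiplicative_shift_recovered_as_mean_activity(self):
        k = 3.2
        ctrl = [(100.0, 200), (120.0, 210), (140.0, 190), (110.0, 205)]
        lum = self.lum_table({
            ("empty", "non-methylated"): ctrl,
            ("TG", "non-methylated"): [(f * k, r) for f, r in ctrl],
        })
        res = assays.luciferase_normalize(lum)
        s = res.summary.set_index("construct")
        assert s.loc["TG", "mean_activity"] == pytest.approx(k, rel=1e-12)
        assert s.loc["TG", "p_vs_control"] < 0.05

    def test_matched_state_control_required(self):
        lum = self.lum_table({
            ("empty", "non-methylated"): [(100, 200)] * 3,
            ("TG", "methylated"): [(300, 200)] * 3,
        })
        with pytest.raises(ValidationError, match="methylated"):
            assays.luciferase_normalize(lum)

    def test_nonpositive_renilla_excluded_with_warning(self):
        rows = [("W1", "empty", "methylated", 100.0, 200.0),
                ("W2", "empty", "methylated", 100.0, 0.0),
                ("W3", "empty", "methylated", 110.0, 190.0),
                ("W4", "empty", "methylated", 90.0, 210.0)]
        # bypass table validation of renilla via construction then normalize
        lum = LuminescenceTable(data=pd.DataFrame(
            rows, columns=["well", "construct", "methylation_state", "firefly", "renilla"]
        ))
        with pytest.warns(UserWarning, match="renilla"):
            res = assays.luciferase_normalize(lum)
        assert len(res.per_well) == 3

    def test_simulated_plate_recovers_activity_multipliers(self, cohort):
        res = assays.luciferase_normalize(cohort.luminescence)
        s = res.summary.set_index(["construct", "methylation_state"])
        truth = cohort.truth["luminescence_activity"]
        for key, expected in truth.items():
            construct, state = key.split("|")
            if construct == "empty":
                continue
            got = s.loc[(construct, state), "mean_activity"]
            assert got == pytest.approx(expected, rel=0.25)
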