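"""The donor-consistency DE criterion, its union over time, and the empirical null."""

import numpy as np
import pandas as pd
import pytest

from rpewound import (SimulationConfig, call_genes, de_call_table,
                      donor_fold_call, empirical_null_counts,
                      passage_dependent_genes, simulate_gene_level)
from rpewound.diffexpr import DiffExprError

from conftest import ZERO_EFFECT, donor_matrix


class TestDonorFoldCall:
    @pytest.mark.parametrize("folds,expected_call", [
        ((2.0, 2.0, 2.0), "up"),       # mean exactly at 2.0: boundary passes
        ((1.6, 1.6, 1.6), "none"),     # each passes 1.5 but mean 1.6 < 2.0
        ((4.0, 1.5, 1.5), "up"),       # all >= 1.5, mean 2.33 >= 2.0
        ((1.4, 4.0, 4.0), "none"),     # one donor below 1.5
        ((2.0, 2.0, 0.4), "none"),     # direction inconsistent
    ])
    def test_up_direction_cases(self, folds, expected_call):
        a = np.ones(3)
        call, ratios, mean_fold = donor_fold_call(a, np.array(folds))
        assert call == expected_call

    def test_down_direction_symmetric(self):
        a = np.ones(3)
        call, _, mean_fold = donor_fold_call(a, np.array([0.5, 0.5, 0.5]))
        assert call == "down" and mean_fold == pytest.approx(2.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DiffExprError):
            donor_fold_call(np.array([1.0, 0.0, 1.0]), np.ones(3))

    def test_geometric_mean_option(self):
        # arithmetic mean of (4, 1.5, 1.5) is 2.33 -> up; geometric is 2.08 -> up;
        # (3.0, 1.5, 1.5) arithmetic 2.0 -> up, geometric 1.89 -> none
        call_a, _, _ = donor_fold_call(np.ones(3), np.array([3.0, 1.5, 1.5]))
        call_g, _, _ = donor_fold_call(np.ones(3), np.array([3.0, 1.5, 1.5]),
                                       mean_kind="geometric")
        assert call_a == "up" and call_g == "none"


class TestCallGenesProperties:
    @pytest.fixture
    def random_pair(self, rng):
        a = donor_matrix(rng.lognormal(5, 1, (500, 3)))
        b = donor_matrix(a.to_numpy() * rng.lognormal(0, 0.8, (500, 3)))
        return a, b

    def test_swapping_conditions_flips_directions(self, random_pair):
        a, b = random_pair
        fwd = call_genes(a, b)
        rev = call_genes(b, a)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert (fwd["call"].map(flip) == rev["call"]).all()
        consistent = fwd["mean_fold"].notna()
        np.testing.assert_allclose(fwd.loc[consistent, "mean_fold"],
                                   rev.loc[consistent, "mean_fold"])

    def test_raising_thresholds_never_adds_calls(self, random_pair):
        a, b = random_pair
        base = call_genes(a, b)["call"] != "none"
        stricter_each = call_genes(a, b, min_each=2.0)["call"] != "none"
        stricter_mean = call_genes(a, b, min_mean=3.0)["call"] != "none"
        assert (stricter_each <= base).all()
        assert (stricter_mean <= base).all()

    def test_scale_invariance(self, random_pair):
        a, b = random_pair
        c1 = call_genes(a, b)["call"]
        c2 = call_genes(a * 37.5, b * 37.5)["call"]
        assert (c1 == c2).all()


class TestUnionOverTime:
    def _sheet_and_expr(self, day_effects):
        """Two passages x len(day_effects) days x 3 donors; one gene whose
        P5/P0 ratio at each day is given."""
        rows, cols, vals = [], [], []
        for day, ratio in day_effects.items():
            for d in ("D1", "D2", "D3"):
                rows.append({"sample_id": f"{d}_P0_{day}", "donor": d,
                             "passage": "P0", "day": day, "density": "x",
                             "treatment": "none"})
                rows.append({"sample_id": f"{d}_P5_{day}", "donor": d,
                             "passage": "P5", "day": day, "density": "x",
                             "treatment": "none"})
                cols += [f"{d}_P0_{day}", f"{d}_P5_{day}"]
                vals += [100.0, 100.0 * ratio]
        sheet = pd.DataFrame(rows)
        expr = pd.DataFrame([vals], index=["g"], columns=cols)
        return expr, sheet

    def test_single_day_call_puts_gene_in_up_set(self):
        expr, sheet = self._sheet_and_expr({3: 1.0, 16: 3.0, 32: 1.0, 64: 1.0})
        table = de_call_table(expr, sheet)
        up, down = passage_dependent_genes(table)
        assert list(up) == ["g"] and len(down) == 0

    def test_no_call_anywhere_leaves_gene_out(self):
        expr, sheet = self._sheet_and_expr({3: 1.2, 16: 1.2, 32: 1.2, 64: 1.2})
        table = de_call_table(expr, sheet)
        up, down = passage_dependent_genes(table)
        assert len(up) == 0 and len(down) == 0

    def test_bidirectional_gene_is_ambiguous_and_excluded(self):
        expr, sheet = self._sheet_and_expr({3: 3.0, 16: 1.0, 32: 1.0, 64: 0.3})
        table = de_call_table(expr, sheet)
        up, down = passage_dependent_genes(table)
        assert len(up) == 0 and len(down) == 0
        assert list(table.ambiguous_genes) == ["g"]


class TestEmpiricalNull:
    def _condition(self, values, donors=("D1", "D2", "D3")):
        sheet = pd.DataFrame([
            {"sample_id": f"{d}", "donor": d, "passage": "P0", "day": 3,
             "density": "x", "treatment": "none"} for d in donors])
        expr = donor_matrix(values, donors=donors)
        expr.columns = list(donors)
        return expr, sheet

    def test_identical_donor_columns_give_zero(self):
        expr, sheet = self._condition(np.tile([[10.0], [20.0]], (1, 3)))
        est = empirical_null_counts(expr, sheet, {"passage": "P0", "day": 3})
        assert est.count == 0

    def test_outlier_donor_produces_a_chance_call(self):
        # D1 low, D2 mid, D3 high: pairwise folds 2, 2, 4 all >= 1.5, mean >= 2
        expr, sheet = self._condition([[10.0, 20.0, 40.0]])
        est = empirical_null_counts(expr, sheet, {"passage": "P0", "day": 3})
        assert est.count == 1
        assert est.comparisons == [("D1", "D2"), ("D1", "D3"), ("D2", "D3")]

    def test_cyclic_pairing_is_structurally_silent(self):
        expr, sheet = self._condition([[10.0, 20.0, 40.0]])
        est = empirical_null_counts(expr, sheet, {"passage": "P0", "day": 3},
                                    pairing="cyclic")
        assert est.count == 0

    def test_single_donor_rejected(self):
        expr, sheet = self._condition([[10.0]], donors=("D1",))
        with pytest.raises(DiffExprError):
            empirical_null_counts(expr, sheet, {"passage": "P0", "day": 3})

    def test_null_count_monotone_in_residual_noise(self):
        # Monte-Carlo oracle: chance calls grow with within-condition noise
        totals = {}
        for rsd in (0.15, 0.35, 0.60):
            total = 0
            for seed in range(1, 6):
                cfg = SimulationConfig(seed=seed, n_genes=4000, donor_sd=0.0,
                                       residual_sd=rsd,
                                       effect_log2fc=ZERO_EFFECT)
                expr, sheet, _ = simulate_gene_level(cfg)
                total += empirical_null_counts(
                    expr, sheet, {"passage": "P0", "day": 3}).count
            totals[rsd] = total
        assert totals[0.15] <= totals[0.35] <= totals[0.60]
        assert totals[0.60] > totals[0.15]

    def test_donor_effects_inflate_null(self):
        def null_at(donor_sd):
            cfg = SimulationConfig(seed=2, n_genes=4000, donor_sd=donor_sd,
                                   residual_sd=0.3,
                                   effect_log2fc=ZERO_EFFECT)
            expr, sheet, _ = simulate_gene_level(cfg)
            return empirical_null_counts(expr, sheet,
                                         {"passage": "P0", "day": 3}).count
        assert null_at(0.5) > null_at(0.0)
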