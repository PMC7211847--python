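"""Pair enumeration, the H² slope estimator, and the auxiliary tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from clonalherit.errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from clonalherit.heritability import (
    H2Estimate,
    PairSet,
    enumerate_pairs,
    estimate_h2,
    family_size_speed_test,
    offscreen_speed_test,
    report_frame,
    speed_generation_correlation,
    well_effect_test,
)
from clonalherit.io import LineageForest, LineageNode, TrackSet, build_forest
from clonalherit.traits import CellTraits, TraitTable, compute_traits

from conftest import make_cell


def pair_set(pairs, mode="first", relationship="sister_sister", trait="speed"):
    return PairSet(relationship=relationship, trait=trait, mode=mode,
                   pairs=[(float(x), float(y), "f") for x, y in pairs])


def trait_table(values, **common):
    """Quick TraitTable of complete cells: values maps cell_id -> (speed, gt)."""
    rows = []
    for cid, (speed, gt) in values.items():
        rows.append(CellTraits(
            cell_id=cid, family_id=common.get("family_id", "f"),
            well_id=common.get("well", "W1"), field_id="P1",
            generation=common.get("generation", 1),
            generation_time=gt, speed=speed, path_length=speed * gt,
            net_displacement=0.0, complete=True, exclusion_reason="none",
        ))
    return TraitTable(rows=rows, frame_interval=20.0, scale=1.0)


def small_family_forest():
    """founder f -> daughters m (with d1, d2) and aunt (with c1)."""
    d1 = LineageNode("d1", 2)
    d2 = LineageNode("d2", 2)
    c1 = LineageNode("c1", 2)
    m = LineageNode("m", 1, [d1, d2])
    aunt = LineageNode("aunt", 1, [c1])
    return LineageForest(families=[LineageNode("f", 0, [m, aunt])])


class TestEnumeratePairs:
    def make_table(self, vals):
        return trait_table({cid: (v, v) for cid, v in vals.items()})

    def test_mother_daughter_uses_daughter_mean(self):
        forest = small_family_forest()
        tt = self.make_table({"m": 10.0, "d1": 8.0, "d2": 12.0, "aunt": 5.0, "c1": 7.0})
        ps = enumerate_pairs(forest, tt, "mother_daughter", "speed")
        # m vs mean(8, 12); aunt vs her single daughter; founder absent from table
        assert sorted((x, y) for x, y, _ in ps.pairs) == [(5.0, 7.0), (10.0, 10.0)]

    def test_sister_first_mode_orders_by_cell_id(self):
        forest = small_family_forest()
        tt = self.make_table({"m": 10.0, "d1": 8.0, "d2": 12.0, "aunt": 5.0, "c1": 7.0})
        ps = enumerate_pairs(forest, tt, "sister_sister", "speed", "first")
        # aunt/m are themselves a dyad (daughters of the founder)
        assert sorted((x, y) for x, y, _ in ps.pairs) == [(5.0, 10.0), (8.0, 12.0)]

    def test_sister_double_entry_both_orientations(self):
        forest = small_family_forest()
        tt = self.make_table({"d1": 8.0, "d2": 12.0})
        ps = enumerate_pairs(forest, tt, "sister_sister", "speed", "double_entry")
        assert sorted((x, y) for x, y, _ in ps.pairs) == [(8.0, 12.0), (12.0, 8.0)]

    def test_cousin_branch_and_focal_modes(self):
        # branch A granddaughters {6, 10}, branch B {9}
        ga1, ga2, gb1 = LineageNode("ga1", 2), LineageNode("ga2", 2), LineageNode("gb1", 2)
        root = LineageNode("f", 0, [LineageNode("a", 1, [ga1, ga2]),
                                    LineageNode("b", 1, [gb1])])
        forest = LineageForest([root])
        tt = self.make_table({"ga1": 6.0, "ga2": 10.0, "gb1": 9.0})
        branch = enumerate_pairs(forest, tt, "cousin_cousin", "speed", "branch")
        assert [(x, y) for x, y, _ in branch.pairs] == [(8.0, 9.0)]
        focal = enumerate_pairs(forest, tt, "cousin_cousin", "speed", "focal")
        assert sorted((x, y) for x, y, _ in focal.pairs) == [(6.0, 9.0), (9.0, 8.0), (10.0, 9.0)]

    def test_incomplete_cells_never_contribute(self, three_family_ts):
        ts, expected = three_family_ts
        forest = build_forest(ts)
        tt = compute_traits(forest, ts)
        for rel in ("sister_sister", "mother_daughter", "cousin_cousin"):
            ps = enumerate_pairs(forest, tt, rel, "speed")
            assert all(fam == "a0" or fam == "b0" for _, _, fam in ps.pairs)
        # family A is the only one with a complete sister dyad (a11 excluded b/c a12 off-screen)
        sis = enumerate_pairs(forest, tt, "sister_sister", "speed")
        assert len(sis.pairs) == 1  # (a1, a2)

    def test_unknown_tokens_rejected(self):
        forest = small_family_forest()
        tt = self.make_table({"d1": 1.0})
        with pytest.raises(ConfigurationError):
            enumerate_pairs(forest, tt, "uncle_niece", "speed")
        with pytest.raises(ConfigurationError):
            enumerate_pairs(forest, tt, "sister_sister", "speed", "random_mode")
        with pytest.raises(ConfigurationError):
            enumerate_pairs(forest, tt, "sister_sister", "weight")


class TestEstimateH2:
    def test_identity_pairs(self):
        est = estimate_h2(pair_set([(1, 1), (2, 2), (3, 3)]))
        assert est.slope == pytest.approx(1.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        est = estimate_h2(pair_set([(1, 5), (2, 5), (3, 5)]))
        assert est.slope == pytest.approx(0.0)

    def test_matches_cov_var_oracle(self):
        rng = np.random.default_rng(123)
        x = rng.normal(10, 3, size=50)
        y = 0.4 * x + rng.normal(0, 2, size=50)
        est = estimate_h2(pair_set(zip(x, y)))
        # independent oracle: sums-of-products formulas
        n = len(x)
        cov = (np.sum(x * y) - np.sum(x) * np.sum(y) / n) / (n - 1)
        var = (np.sum(x * x) - np.sum(x) ** 2 / n) / (n - 1)
        assert est.slope == pytest.approx(cov / var, abs=1e-12)
        r = cov / math.sqrt(var * ((np.sum(y * y) - np.sum(y) ** 2 / n) / (n - 1)))
        assert est.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_affine_invariance_and_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = estimate_h2(pair_set(zip(x, y)))
        shifted = estimate_h2(pair_set(zip(x + 7.5, y - 3.25)))
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        scaled = estimate_h2(pair_set(zip(2.0 * x, 3.0 * y)))
        assert scaled.slope == pytest.approx(base.slope * 3.0 / 2.0, rel=1e-9)

    def test_double_entry_swap_invariant_and_dyad_df(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=20)
        b = a * 0.5 + rng.normal(size=20)
        doubled = list(zip(a, b)) + list(zip(b, a))
        est = estimate_h2(pair_set(doubled, mode="double_entry"))
        swapped = estimate_h2(pair_set([(y, x) for x, y in doubled], mode="double_entry"))
        assert est.slope == pytest.approx(swapped.slope, rel=1e-12)
        assert est.df == 18  # dyads - 2, not rows - 2
        assert est.n_pairs == 40

    def test_insufficient_and_degenerate(self):
        with pytest.raises(InsufficientDataError):
            estimate_h2(pair_set([(1, 2), (2, 3)]))
        with pytest.raises(DegenerateDataError):
            estimate_h2(pair_set([(1, 2), (1, 3), (1, 4)]))


class TestAuxiliaryStatistics:
    def test_spearman_monotone_limits(self):
        tt = trait_table({f"c{i}": (float(i), float(i)) for i in range(10)})
        rho, _ = speed_generation_correlation(tt)
        assert rho == pytest.approx(1.0)
        tt2 = trait_table({f"c{i}": (float(i), 100.0 - i) for i in range(10)})
        rho2, _ = speed_generation_correlation(tt2)
        assert rho2 == pytest.approx(-1.0)

    def test_spearman_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(31)
        sp = rng.normal(20, 5, 30)
        gt = rng.normal(14, 4, 30)
        tt = trait_table({f"c{i}": (sp[i], gt[i]) for i in range(30)})
        rho, _ = speed_generation_correlation(tt)
        # oracle: rank then Pearson product-moment
        rk_s = stats.rankdata(sp)
        rk_g = stats.rankdata(gt)
        r = np.corrcoef(rk_s, rk_g)[0, 1]
        assert rho == pytest.approx(r, abs=1e-12)

    def test_well_effect_identical_vs_shifted(self):
        vals = list(np.linspace(5, 15, 20))
        rows = {}
        for i, v in enumerate(vals):
            rows[f"a{i}"] = (v, 10.0)
        t1 = trait_table(rows, well="W1")
        t2 = trait_table({f"b{i}": (v, 10.0) for i, v in enumerate(vals)}, well="W2")
        tt = TraitTable(rows=t1.rows + t2.rows, frame_interval=20.0, scale=1.0)
        h, p = well_effect_test(tt)
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99
        t3 = trait_table({f"c{i}": (v + 100.0, 10.0) for i, v in enumerate(vals)},
                         well="W3")
        tt2 = TraitTable(rows=t1.rows + t3.rows, frame_interval=20.0, scale=1.0)
        _, p2 = well_effect_test(tt2)
        assert p2 < 0.001

    def test_kruskal_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(77)
        wells = {}
        rows = []
        for w in range(3):
            vals = rng.normal(10 + w, 2, 20)
            wells[f"W{w}"] = vals
            rows += trait_table(
                {f"w{w}c{i}": (v, 10.0) for i, v in enumerate(vals)}, well=f"W{w}"
            ).rows
        tt = TraitTable(rows=rows, frame_interval=20.0, scale=1.0)
        h, _ = well_effect_test(tt)
        # oracle: H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1), no ties among floats
        pooled = np.concatenate(list(wells.values()))
        ranks = stats.rankdata(pooled)
        n_tot = len(pooled)
        h_oracle = -3.0 * (n_tot + 1)
        start = 0
        for vals in wells.values():
            rj = ranks[start:start + len(vals)].sum()
            h_oracle += 12.0 / (n_tot * (n_tot + 1)) * rj**2 / len(vals)
            start += len(vals)
        assert h == pytest.approx(h_oracle, abs=1e-10)

    def _welch_oracle(self, a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        return t, df, p

    def test_family_size_classes_welch(self):
        rng = np.random.default_rng(11)
        cells = []
        # two families of 2 complete cells, one family of 6 complete cells
        for fam in ("fA", "fB"):
            cells.append(make_cell(fam, 0, 10, fate="divided"))
            cells += [make_cell(f"{fam}.{i}", 10, 40, mother=fam, fate="divided")
                      for i in (0, 1)]
        cells.append(make_cell("fC", 0, 10, fate="divided"))
        for d in ("0", "1"):
            cells.append(make_cell(f"fC.{d}", 10, 40, mother="fC", fate="divided"))
            cells += [make_cell(f"fC.{d}.{g}", 40, 80, mother=f"fC.{d}",
                                fate="divided") for g in ("0", "1")]
        ts = TrackSet(cells={c.cell_id: c for c in cells})
        forest = build_forest(ts)
        tt = compute_traits(forest, ts)
        speeds = {r.cell_id: rng.normal(10, 2) for r in tt.rows}
        for r in tt.rows:
            r.speed = speeds[r.cell_id]
        recs = family_size_speed_test(tt, forest)
        assert len(recs) == 1  # one comparison: size 2 vs size 6
        small = [speeds[c] for c in ("fA.0", "fA.1", "fB.0", "fB.1")]
        big = [speeds[c] for c in ("fC.0", "fC.1", "fC.0.0", "fC.0.1",
                                   "fC.1.0", "fC.1.1")]
        t, df, _ = self._welch_oracle(small, big)
        assert recs[0]["t"] == pytest.approx(t, abs=1e-10)
        assert recs[0]["df"] == pytest.approx(df, abs=1e-10)

    def test_welch_oracle_on_random_groups(self):
        rng = np.random.default_rng(55)
        a = rng.normal(10, 1, 50)
        b = rng.normal(30, 1, 50)
        res = stats.ttest_ind(a, b, equal_var=False)
        t, df, p = self._welch_oracle(a, b)
        assert float(res.statistic) == pytest.approx(t, abs=1e-10)
        assert float(res.df) == pytest.approx(df, abs=1e-10)
        assert p < 1e-6

    def test_offscreen_test_identical_gives_t_zero(self):
        rows = trait_table({f"c{i}": (float(v), 10.0) for i, v in enumerate(range(10))}).rows
        partial = []
        for i, v in enumerate(range(10)):
            partial.append(CellTraits(
                cell_id=f"o{i}", family_id="f", well_id="W1", field_id="P1",
                generation=1, generation_time=float("nan"), speed=float(v),
                path_length=0.0, net_displacement=0.0, complete=False,
                exclusion_reason="off_screen",
            ))
        tt = TraitTable(rows=rows + partial, frame_interval=20.0, scale=1.0)
        rec = offscreen_speed_test(tt)
        assert rec["t"] == pytest.approx(0.0, abs=1e-12)
        assert rec["n_offscreen"] == 10 and rec["n_complete"] == 10

    def test_offscreen_requires_both_groups(self):
        tt = trait_table({"c": (1.0, 1.0), "d": (2.0, 2.0), "e": (3.0, 3.0)})
        with pytest.raises(InsufficientDataError):
            offscreen_speed_test(tt)


class TestReport:
    def _est(self, p):
        return H2Estimate(relationship="sister_sister", trait="speed",
                          slope=0.5, intercept=0.0, slope_se=0.1, t_statistic=5.0,
                          p_value=p, r_squared=0.28, n_pairs=52, df=50)

    @pytest.mark.parametrize("p,stars", [(0.0005, "***"), (0.009, "**"),
                                         (0.04, "*"), (0.2, "")])
    def test_star_thresholds(self, p, stars):
        assert self._est(p).stars() == stars

    def test_report_cell_rendering(self):
        frame = report_frame([self._est(0.0005)])
        cell = frame.loc[0, "speed:sister_sister"]
        assert cell == "0.50*** (0.28)"
        assert frame.loc[0, "speed:mother_daughter"] == "—"
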