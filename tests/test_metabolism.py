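"""Paired Wilcoxon, differential metabolites, DA scores, flux aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon

from aegmap.metabolism import (
    FluxMatrices,
    PairedMetaboliteTable,
    da_score,
    da_table,
    differential_metabolites,
    metabolite_flux,
    paired_wilcoxon,
    zscore_flux,
)
from aegmap.synthetic import generate_metabolome

from conftest import small_config


def wilcoxon_enumeration_p(d: np.ndarray) -> float:
    """Two-sided exact p by brute force over all 2^n sign patterns."""
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    total = ws.size
    sf = (ws >= w_obs - 1e-9).sum() / total
    cdf = (ws <= w_obs + 1e-9).sum() / total
    return min(1.0, 2.0 * min(sf, cdf))


class TestPairedWilcoxon:
    def test_five_positive_differences(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        w, p = paired_wilcoxon(x, y)
        assert w == 15.0
        assert p == pytest.approx(2 / 32)

    def test_identical_vectors_p_one(self):
        x = np.ones(6)
        with pytest.warns(UserWarning, match="zero"):
            _, p = paired_wilcoxon(x, x)
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_enumeration_n12(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0.3, 1.0, 12)
        y = r.normal(0.0, 1.0, 12)
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(wilcoxon_enumeration_p(x - y), abs=1e-12)

    def test_matches_enumeration_with_tied_ranks(self):
        # integer differences force ties in |d|; the DP must stay exact
        x = np.array([3.0, 4.0, 5.0, 2.0, 8.0, 1.0, 9.0, 7.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 4.0, 9.0])
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(wilcoxon_enumeration_p(x - y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact(self, seed):
        r = np.random.default_rng(100 + seed)
        x = r.normal(0.5, 1.0, 15)
        y = r.normal(0.0, 1.0, 15)
        _, p = paired_wilcoxon(x, y)
        ref = wilcoxon(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_normal_approximation_close_to_scipy(self):
        r = np.random.default_rng(3)
        x = r.normal(0.2, 1.0, 40)
        y = r.normal(0.0, 1.0, 40)
        _, p = paired_wilcoxon(x, y)
        ref = wilcoxon(x, y, alternative="two-sided", method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_calibrated(self):
        # exact test at alpha=0.05, n=13: rejection rate within [0.03, 0.07]
        r = np.random.default_rng(0)
        rejections = 0
        n_sim = 1500
        for _ in range(n_sim):
            d = r.normal(size=13)
            _, p = paired_wilcoxon(d, np.zeros(13))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestDifferentialMetabolites:
    def test_planted_directions_recovered(self, small_cfg):
        tumor, normal, _, direction = generate_metabolome(small_cfg)
        table = PairedMetaboliteTable(tumor=tumor, normal=normal)
        up, down, res = differential_metabolites(table)
        planted_up = set(direction.index[direction == 1])
        planted_dn = set(direction.index[direction == -1])
        assert len(up & planted_up) / len(planted_up) >= 0.9
        assert len(down & planted_dn) / len(planted_dn) >= 0.9
        # q-values reported alongside raw p
        assert {"p_value", "q_value", "log2fc"} <= set(res.columns)

    def test_identical_tables_give_empty_sets(self, rng):
        vals = pd.DataFrame(
            rng.lognormal(2, 0.5, (10, 6)),
            index=[f"m{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning):
            up, down, _ = differential_metabolites(
                PairedMetaboliteTable(tumor=vals, normal=vals.copy())
            )
        assert not up and not down

    def test_nonpositive_intensity_rejected(self):
        t = pd.DataFrame([[1.0, 2.0]], index=["m"])
        n = pd.DataFrame([[0.0, 2.0]], index=["m"])
        with pytest.raises(ValueError, match="positive"):
            PairedMetaboliteTable(tumor=t, normal=n)


class TestDaScore:
    def test_formula(self):
        res = da_score(
            up={f"u{i}" for i in range(3)},
            down={"d0"},
            pathways={"pw": [f"u{i}" for i in range(3)] + ["d0"] + [f"x{i}" for i in range(6)]},
            measured={f"u{i}" for i in range(3)} | {"d0"} | {f"x{i}" for i in range(6)},
        )
        assert res[0].da_score == pytest.approx(0.2)

    def test_all_up_members_give_one(self):
        res = da_score(
            up={"a", "b", "c"},
            down=set(),
            pathways={"pw": ["a", "b", "c"]},
            measured={"a", "b", "c"},
        )
        assert res[0].da_score == 1.0

    def test_matches_set_intersection_oracle(self, rng):
        metabs = [f"m{i}" for i in range(60)]
        for _ in range(100):
            measured = set(rng.choice(metabs, size=40, replace=False))
            up = set(rng.choice(sorted(measured), size=8, replace=False))
            down = set(rng.choice(sorted(measured - up), size=8, replace=False))
            pathways = {
                f"pw{j}": list(rng.choice(metabs, size=rng.integers(3, 15), replace=False))
                for j in range(5)
            }
            results = da_score(up, down, pathways, measured)
            for r in results:
                members = set(pathways[r.pathway]) & measured
                n_up = sum(1 for m in members if m in up)
                n_dn = sum(1 for m in members if m in down)
                assert r.n_up == n_up and r.n_down == n_dn
                assert r.da_score == pytest.approx((n_up - n_dn) / len(members))
                assert -1.0 <= r.da_score <= 1.0

    def test_antisymmetric_under_up_down_swap(self, rng):
        metabs = {f"m{i}" for i in range(30)}
        up = {f"m{i}" for i in range(8)}
        down = {f"m{i}" for i in range(8, 14)}
        pathways = {"a": [f"m{i}" for i in range(12)], "b": [f"m{i}" for i in range(5, 25)]}
        fwd = da_score(up, down, pathways, metabs)
        rev = da_score(down, up, pathways, metabs)
        for f, r in zip(fwd, rev):
            assert f.da_score == pytest.approx(-r.da_score)

    def test_small_pathways_skipped_and_empty_map_rejected(self):
        res = da_score({"a"}, set(), {"tiny": ["a", "b"]}, {"a", "b"})
        assert res == []
        with pytest.raises(ValueError, match="empty"):
            da_score({"a"}, set(), {}, {"a"})

    def test_unmeasured_up_rejected(self):
        with pytest.raises(ValueError, match="unmeasured"):
            da_score({"ghost"}, set(), {"pw": ["a", "b", "c"]}, {"a", "b", "c"})


class TestFlux:
    def test_identity_stoichiometry_returns_fluxes(self, rng):
        r = pd.DataFrame(rng.random((3, 4)), columns=[f"r{i}" for i in range(4)])
        s = pd.DataFrame(np.eye(4), index=r.columns, columns=[f"m{i}" for i in range(4)])
        m = metabolite_flux(FluxMatrices(reaction_flux=r, stoichiometry=s))
        np.testing.assert_allclose(m.to_numpy(), r.to_numpy(), atol=1e-15)

    def test_hand_multiplied_two_by_two(self):
        r = pd.DataFrame([[1.0, 2.0]], columns=["r1", "r2"], index=["ct"])
        s = pd.DataFrame(
            [[1.0, 0.0], [-1.0, 1.0]], index=["r1", "r2"], columns=["m1", "m2"]
        )
        m = metabolite_flux(FluxMatrices(reaction_flux=r, stoichiometry=s))
        np.testing.assert_allclose(m.to_numpy(), [[-1.0, 2.0]])

    def test_random_shapes_match_triple_loop(self, rng):
        r = pd.DataFrame(rng.normal(size=(6, 9)), columns=[f"r{i}" for i in range(9)])
        s = pd.DataFrame(
            rng.integers(-2, 3, (9, 5)).astype(float),
            index=r.columns, columns=[f"m{i}" for i in range(5)],
        )
        m = metabolite_flux(FluxMatrices(reaction_flux=r, stoichiometry=s)).to_numpy()
        want = np.zeros((6, 5))
        for i in range(6):
            for j in range(5):
                for k in range(9):
                    want[i, j] += r.iloc[i, k] * s.iloc[k, j]
        np.testing.assert_allclose(m, want, atol=1e-12)

    def test_linearity_in_fluxes(self, rng):
        cols = [f"r{i}" for i in range(5)]
        r1 = pd.DataFrame(rng.normal(size=(3, 5)), columns=cols)
        r2 = pd.DataFrame(rng.normal(size=(3, 5)), columns=cols)
        s = pd.DataFrame(rng.normal(size=(5, 4)), index=cols)
        f = lambda r: metabolite_flux(FluxMatrices(reaction_flux=r, stoichiometry=s))
        np.testing.assert_allclose(
            f(r1 + r2).to_numpy(), (f(r1) + f(r2)).to_numpy(), atol=1e-12
        )

    def test_axis_mismatch_names_shapes(self, rng):
        r = pd.DataFrame(rng.random((2, 3)), columns=["a", "b", "c"])
        s = pd.DataFrame(rng.random((4, 2)), index=["w", "x", "y", "z"])
        with pytest.raises(ValueError, match="axes differ"):
            metabolite_flux(FluxMatrices(reaction_flux=r, stoichiometry=s))

    def test_bad_compartment_tag_rejected(self, rng):
        r = pd.DataFrame(rng.random((2, 2)), columns=["a", "b"])
        s = pd.DataFrame(rng.random((2, 1)), index=["a", "b"], columns=["glucose[x]"])
        with pytest.raises(ValueError, match="compartment"):
            FluxMatrices(reaction_flux=r, stoichiometry=s)


class TestZscore:
    def test_two_values_give_plus_minus_707(self):
        m = pd.DataFrame({"met": [1.0, 3.0]}, index=["ct1", "ct2"])
        z = zscore_flux(m)  # sample SD (n-1)
        np.testing.assert_allclose(
            z["met"].to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )

    def test_constant_column_zero_with_warning(self):
        m = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_flux(m)
        np.testing.assert_allclose(z["a"].to_numpy(), 0.0)

    def test_columns_mean_zero(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 8)))
        z = zscore_flux(m)
        np.testing.assert_allclose(z.mean().to_numpy(), 0.0, atol=1e-12)

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError, match="2 cell types"):
            zscore_flux(pd.DataFrame({"a": [1.0]}))


def test_da_table_roundtrip(small_cfg):
    tumor, normal, pathways, _ = generate_metabolome(small_cfg)
    up, down, res = differential_metabolites(
        PairedMetaboliteTable(tumor=tumor, normal=normal)
    )
    tab = da_table(da_score(up, down, pathways, set(res.index)))
    assert tab["da_score"].between(-1, 1).all()
    # the pathway seeded with planted-up members scores positive
    assert tab.loc["arginine_proline_metabolism", "da_score"] > 0
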