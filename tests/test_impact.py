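"""Differential hubbing, PIF and RIF regulator scores."""

import numpy as np
import pandas as pd
import pytest

from imfnet import impact, pcit


def _net(edges, universe, group=""):
    df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "r"]) if edges else \
        pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    deg = pd.Series(0, index=pd.Index(universe, name="gene"), dtype=int)
    if len(df):
        vc = pd.concat([df["gene_a"], df["gene_b"]]).value_counts()
        deg.loc[vc.index] = vc.astype(int)
    return pcit.CorrelationNetwork(group=group, edges=df, degrees=deg, gene_universe=list(universe))


class TestDifferentialHubbing:
    def test_identical_networks_zero(self):
        net = _net([("a", "b", 0.95), ("a", "c", 0.92)], list("abc"))
        dh = impact.differential_hubbing(net, net)
        assert (dh["dh"] == 0).all()

    def test_degree_difference(self):
        high = _net([("a", x, 0.95) for x in "bcdef"] + [("b", "c", 0.91)], list("abcdef"))
        low = _net([("a", "b", 0.95), ("a", "c", 0.93)], list("abcdef"))
        dh = impact.differential_hubbing(high, low)
        assert dh.loc["a", "dh"] == 3
        assert dh.loc["a", "k_high"] == 5 and dh.loc["a", "k_low"] == 2

    def test_sign_convention_flips(self):
        high = _net([("a", "b", 0.95)], list("ab"))
        low = _net([], list("ab"))
        default = impact.differential_hubbing(high, low)
        flipped = impact.differential_hubbing(high, low, sign="low_minus_high")
        assert (default["dh"] == -flipped["dh"]).all()

    def test_universe_mismatch_needs_union_flag(self):
        high = _net([], list("abc"))
        low = _net([], list("abd"))
        with pytest.raises(ValueError, match="union"):
            impact.differential_hubbing(high, low)
        dh = impact.differential_hubbing(high, low, union=True)
        assert set(dh.index) == set("abcd")


class TestTopDh:
    def test_single_extremes(self):
        dh = pd.DataFrame({"k_high": [3, 0, 1], "k_low": [0, 1, 1], "dh": [3, -1, 0]},
                          index=pd.Index(list("abc"), name="gene"))
        pos, neg = impact.top_dh(dh, k=1)
        assert list(pos.index) == ["a"] and list(neg.index) == ["b"]

    def test_k_larger_than_table(self):
        dh = pd.DataFrame({"dh": [2, -2]}, index=pd.Index(["a", "b"], name="gene"))
        pos, neg = impact.top_dh(dh, k=10)
        assert list(pos.index) == ["a", "b"]
        assert list(neg.index) == ["b", "a"]

    def test_ties_resolved_by_gene_id(self):
        dh = pd.DataFrame({"dh": [0, 0, 0]}, index=pd.Index(["z", "a", "m"], name="gene"))
        pos, neg = impact.top_dh(dh, k=2)
        assert list(pos.index) == ["a", "m"]
        assert list(neg.index) == ["a", "m"]


class TestPifScores:
    def test_arithmetic(self):
        eh = pd.DataFrame([[4.0, 4.0]], index=["g"], columns=["h1", "h2"])
        el = pd.DataFrame([[2.0, 2.0]], index=["g"], columns=["l1", "l2"])
        out = impact.pif_scores(eh, el)
        assert out.loc["g"].to_numpy() == pytest.approx([3.0, 2.0, 6.0])

    def test_equal_means_zero(self, rng):
        eh = pd.DataFrame(rng.normal(size=(5, 4)))
        out = impact.pif_scores(eh, eh.copy())
        assert np.allclose(out["pif"], 0.0)

    def test_group_swap_antisymmetry(self, rng):
        eh = pd.DataFrame(rng.normal(5, 1, size=(8, 4)))
        el = pd.DataFrame(rng.normal(5, 1, size=(8, 4)))
        assert np.allclose(impact.pif_scores(eh, el)["pif"],
                           -impact.pif_scores(el, eh)["pif"])

    def test_gene_mismatch_rejected(self, rng):
        eh = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"))
        el = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abd"))
        with pytest.raises(ValueError, match="absent"):
            impact.pif_scores(eh, el)


class TestCandidateRegulators:
    def test_empty_networks(self):
        net = _net([], list("abc"))
        assert impact.candidate_regulators(net, net) == []

    def test_single_low_group_edge_qualifies(self):
        high = _net([], list("abc"))
        low = _net([("b", "c", 0.91)], list("abc"))
        assert impact.candidate_regulators(high, low) == ["b", "c"]


def _exact_correlation_vector(rng, anchor, r):
    """A vector with exact sample correlation r against ``anchor``."""
    x = (anchor - anchor.mean()) / anchor.std()
    raw = rng.normal(size=len(anchor))
    raw = raw - raw.mean()
    raw = raw - x * np.dot(raw, x) / np.dot(x, x)
    y = r * x + np.sqrt(1 - r**2) * raw / raw.std()
    return y


class TestRifScores:
    def test_identical_groups_zero_rif1(self, rng):
        expr = pd.DataFrame(rng.normal(5, 1, size=(6, 5)),
                            index=[f"g{i}" for i in range(6)])
        rif = impact.rif_scores(expr, expr.copy(), ["g1", "g2"], ["g0", "g3"])
        assert np.allclose(rif["rif1_raw"], 0.0)

    def test_hand_computed_rif1(self, rng):
        """One regulator, two DE genes with PIF (6, 2) and wiring change (1, -0.5)."""
        n = 6
        anchor = rng.normal(size=n)
        x = (anchor - anchor.mean()) / anchor.std()
        # high group: r(reg, de1) = 1, r(reg, de2) = 0
        reg_h = 2.0 * x + 1.0
        de1_h = x + 4.0                      # r = 1, mean 4
        de2_h = _exact_correlation_vector(rng, anchor, 0.0) + 2.5
        # low group: r(reg, de1) = 0, r(reg, de2) = 0.5
        anchor_l = rng.normal(size=n)
        xl = (anchor_l - anchor_l.mean()) / anchor_l.std()
        reg_l = 2.0 * xl + 1.0
        de1_l = _exact_correlation_vector(rng, anchor_l, 0.0) + 2.0   # mean 2
        de2_l = _exact_correlation_vector(rng, anchor_l, 0.5) + 1.5   # mean 1.5
        eh = pd.DataFrame([reg_h, de1_h, de2_h], index=["reg", "de1", "de2"])
        el = pd.DataFrame([reg_l, de1_l, de2_l], index=["reg", "de1", "de2"])
        # PIF: de1 = 3 * 2 = 6, de2 = 2 * 1 = 2; RIF1 = (6*1 + 2*0.25)/2
        rif = impact.rif_scores(eh, el, ["de1", "de2"], ["reg"])
        assert rif.loc["reg", "rif1_raw"] == pytest.approx(3.25, abs=1e-10)

    def test_location_scale_invariance_of_rif1(self, rng):
        eh = pd.DataFrame(rng.normal(5, 1, size=(8, 6)), index=[f"g{i}" for i in range(8)])
        el = pd.DataFrame(rng.normal(5, 1, size=(8, 6)), index=eh.index)
        base = impact.rif_scores(eh, el, ["g1", "g2", "g3"], ["g0", "g4"])
        eh2, el2 = eh.copy(), el.copy()
        eh2.loc["g0"] = eh2.loc["g0"] * 3.0 + 7.0
        el2.loc["g0"] = el2.loc["g0"] * 3.0 + 7.0
        shifted = impact.rif_scores(eh2, el2, ["g1", "g2", "g3"], ["g0", "g4"])
        assert shifted.loc["g0", "rif1_raw"] == pytest.approx(base.loc["g0", "rif1_raw"])

    def test_group_swap_negates_rif_scores(self, rng):
        eh = pd.DataFrame(rng.normal(5, 1, size=(8, 6)), index=[f"g{i}" for i in range(8)])
        el = pd.DataFrame(rng.normal(5, 1, size=(8, 6)), index=eh.index)
        de, cand = ["g1", "g2", "g3"], ["g0", "g4", "g5"]
        fwd = impact.rif_scores(eh, el, de, cand)
        rev = impact.rif_scores(el, eh, de, cand)
        assert np.allclose(fwd["rif1_raw"], -rev["rif1_raw"])
        assert np.allclose(fwd["rif2_raw"], -rev["rif2_raw"])

    def test_self_pair_excluded_for_de_candidates(self, rng):
        expr_h = pd.DataFrame(rng.normal(5, 1, size=(4, 5)), index=list("abcd"))
        expr_l = pd.DataFrame(rng.normal(5, 1, size=(4, 5)), index=list("abcd"))
        rif = impact.rif_scores(expr_h, expr_l, ["a", "b"], ["a", "c"])
        # candidate 'a' is scored only against 'b'; finite, not dominated by r=1 self-term
        assert np.isfinite(rif.loc["a", "rif1_raw"])

    def test_planted_regulator_recovered_among_nulls(self):
        """Differentially wired regulator vs 50 null candidates, 20 seeds."""
        wins = 0
        n = 14
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)

            def draw(coupled):
                a = rng.normal(size=n)
                a = (a - a.mean()) / a.std()
                rows = {"reg": 4.0 + 2 * a + 0.1 * rng.normal(size=n)}
                for j in range(10):
                    c = 0.9 if coupled else 0.0
                    rows[f"de{j}"] = (5.0 + 2 * (c * a + np.sqrt(1 - c**2) * rng.normal(size=n))
                                      + (1.0 if coupled else -1.0))
                for j in range(50):
                    rows[f"null{j}"] = 5.0 + rng.normal(size=n)
                return pd.DataFrame(rows).T

            eh, el = draw(True), draw(False)
            rif = impact.rif_scores(eh, el, [f"de{j}" for j in range(10)],
                                    ["reg"] + [f"null{j}" for j in range(50)])
            wins += int(rif["rif1_z"].abs().idxmax() == "reg")
        assert wins >= 18


class TestZscore:
    def test_arithmetic(self):
        assert impact.zscore([1, 2, 3]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_fixed_point(self, rng):
        v = impact.zscore(rng.normal(size=50))
        assert impact.zscore(v) == pytest.approx(v)
        assert abs(v.mean()) < 1e-10 and abs(v.std(ddof=1) - 1) < 1e-10

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            impact.zscore([2.0, 2.0, 2.0])


class TestTopPif:
    def test_ordering_and_limits(self):
        pif = pd.Series({"a": 1.0, "b": 5.0, "c": -2.0, "d": 5.0})
        assert impact.top_pif(pif, k=1) == ["b"]
        assert impact.top_pif(pif, k=10) == ["b", "d", "a", "c"]
        assert impact.top_pif(pif, k=2, use_abs=True) == ["b", "d"]
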