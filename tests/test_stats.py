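"""ANOVA, Duncan's multiple range test and the per-variable pipeline."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from flavorgrade import (
    GroupDesign, GroupSummary, anova_oneway, duncan_mrt, per_variable_tests,
    summaries_from_replicates,
)
from flavorgrade.tables import ReplicateMatrix
import pandas as pd


def brute_force_anova(groups):
    """Independent textbook oracle from raw sums of squares."""
    allx = np.concatenate(groups)
    grand = allx.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(allx) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return f, sps.f.sf(f, df_b, df_w)


class TestAnova:
    def test_nerol_p_value_reproduced(self):
        """Summary-statistics ANOVA reproduces the published p to 3 d.p."""
        res = anova_oneway([GroupSummary("SG", 207.45, 6.97, 3),
                            GroupSummary("1G", 193.13, 25.46, 3),
                            GroupSummary("2G", 197.60, 10.69, 3)])
        assert round(res.p_value, 3) == 0.581

    def test_equal_means_give_f_zero(self):
        res = anova_oneway([GroupSummary("a", 5.0, 1.0, 3),
                            GroupSummary("b", 5.0, 1.0, 3)])
        assert res.f_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_on_toy_replicates(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        f_oracle, p_oracle = brute_force_anova(groups)
        summaries = [GroupSummary(str(i), float(np.mean(g)),
                                  float(np.std(g, ddof=1)), len(g))
                     for i, g in enumerate(groups)]
        res = anova_oneway(summaries)
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_summary_route_identical_to_replicate_route(self):
        rng = np.random.default_rng(42)
        x = rng.normal(10, 2, 30)
        labels = np.repeat(["a", "b", "c"], 10)
        res_sum = anova_oneway(summaries_from_replicates(x, labels))
        f_sp, p_sp = sps.f_oneway(*(x[labels == g] for g in "abc"))
        assert res_sum.f_stat == pytest.approx(f_sp, rel=1e-10)
        assert res_sum.p_value == pytest.approx(p_sp, rel=1e-10)

    def test_degenerate_zero_variance(self):
        res = anova_oneway([GroupSummary("a", 1.0, 0.0, 3),
                            GroupSummary("b", 2.0, 0.0, 3)])
        assert res.degenerate and res.p_value == 0.0
        res2 = anova_oneway([GroupSummary("a", 1.0, 0.0, 3),
                             GroupSummary("b", 1.0, 0.0, 3)])
        assert res2.degenerate and math.isnan(res2.p_value)


class TestDuncan:
    HEXANAL = [GroupSummary("SG", 21.18, 0.92, 3),
               GroupSummary("1G", 23.01, 0.12, 3),
               GroupSummary("2G", 33.18, 2.95, 3)]

    def test_hexanal_partition(self):
        """The two lower grades are indistinguishable; the lowest grade's
        higher hexanal level separates (published letters a/a/b)."""
        d = duncan_mrt(self.HEXANAL)
        assert d.letters["SG"] == d.letters["1G"]
        assert d.letters["2G"] != d.letters["SG"]
        assert d.different[frozenset({"SG", "2G"})]
        assert d.different[frozenset({"1G", "2G"})]
        assert not d.different[frozenset({"SG", "1G"})]

    def test_letter_order_conventions(self):
        asc = duncan_mrt(self.HEXANAL, letter_order="ascending")
        assert (asc.letters["SG"], asc.letters["1G"], asc.letters["2G"]) \
            == ("a", "a", "b")
        desc = duncan_mrt(self.HEXANAL, letter_order="descending")
        assert (desc.letters["2G"], desc.letters["SG"]) == ("a", "b")

    def test_identical_groups_share_one_letter(self):
        gs = [GroupSummary(g, 5.0, 1.0, 3) for g in "abc"]
        d = duncan_mrt(gs)
        assert set(d.letters.values()) == {"a"}

    def test_extreme_separation_matches_welch_oracle(self):
        gs = [GroupSummary("lo", 0.0, 1.0, 3),
              GroupSummary("hi", 100.0, 1.0, 3)]
        d = duncan_mrt(gs)
        t = (100.0 - 0.0) / math.sqrt(1.0 / 3 + 1.0 / 3)
        p_welch = 2 * sps.t.sf(t, 4)
        assert p_welch < 0.05
        assert d.different[frozenset({"lo", "hi"})]
        assert d.letters["lo"] != d.letters["hi"]

    def test_two_groups_coincides_with_pooled_t(self):
        """For k=2 the Duncan decision equals the pooled two-sample t-test."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            m2 = rng.uniform(0, 3)
            gs = [GroupSummary("a", 0.0, 1.0, 4),
                  GroupSummary("b", float(m2), 1.0, 4)]
            d = duncan_mrt(gs, alpha=0.05)
            se = math.sqrt(1.0 * (1 / 4 + 1 / 4))
            t = abs(m2) / se
            t_reject = 2 * sps.t.sf(t, 6) < 0.05
            assert d.different[frozenset({"a", "b"})] == t_reject

    def test_decision_monotone_in_gap(self):
        """Widening the gap between two means never flips a 'different'
        decision back to 'same'."""
        prev = False
        for gap in np.linspace(0, 10, 30):
            gs = [GroupSummary("a", 0.0, 1.0, 3),
                  GroupSummary("b", float(gap), 1.0, 3)]
            diff = duncan_mrt(gs).different[frozenset({"a", "b"})]
            assert diff or not prev
            prev = prev or diff


class TestPerVariable:
    def test_fixture_common_compounds_significance(self, volatiles):
        """Among the 60 compounds detected in every grade, the recomputed
        significance calls coincide exactly with the published per-compound
        p column: the same five compounds (nonanal, (E)-2-nonenal, nerol,
        the diisobutyrate and isopropyl myristate) are non-significant."""
        res = per_variable_tests(volatiles)
        det = volatiles.detected_frame()
        common = det.index[det.all(axis=1)]
        assert len(common) == 60
        nonsig = {c for c in common if res.loc[c, "p_value"] >= 0.05}
        assert nonsig == {"37", "47", "61", "101", "107"}
        assert (res.loc[common, "p_value"] < 0.05).sum() == 55

    def test_computed_p_matches_published_column(self, volatiles):
        """Summary-derived p-values agree with the published 3-d.p.
        significance column for compounds detected everywhere."""
        res = per_variable_tests(volatiles)
        det = volatiles.detected_frame()
        for r in volatiles.records:
            if not det.loc[r.compound_id].all() or r.p_value is None:
                continue
            assert res.loc[r.compound_id, "p_value"] == pytest.approx(
                r.p_value, abs=0.02)

    def test_partial_and_untestable_flags(self, volatiles):
        res = per_variable_tests(volatiles)
        assert bool(res.loc["2", "partial"])       # absent in one grade
        assert bool(res.loc["3", "untestable"])    # present in one grade only

    def test_constant_variable_flagged_degenerate(self):
        vals = pd.DataFrame({"const": [1.0] * 6, "var": [1, 2, 3, 4, 5, 6.0]})
        mat = ReplicateMatrix(vals, pd.Series(["a"] * 3 + ["b"] * 3))
        res = per_variable_tests(mat, GroupDesign(("a", "b")))
        assert bool(res.loc["const", "degenerate"])
        assert res.loc["const", "letter_a"] == "a"

    def test_type_one_error_calibrated(self):
        """Under null data (all groups drawn from one distribution) the
        p<0.05 fraction over 5 x 1000 variables sits within two binomial
        standard errors of the nominal 0.05."""
        n_var, n = 1000, 3
        labels = np.repeat(["g1", "g2", "g3"], n)
        hits = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (3 * n, n_var))
            mat = ReplicateMatrix(
                pd.DataFrame(X, columns=[f"v{i}" for i in range(n_var)]),
                pd.Series(labels))
            res = per_variable_tests(mat, GroupDesign(("g1", "g2", "g3")))
            hits += int((res["p_value"] < 0.05).sum())
            total += n_var
        frac = hits / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert abs(frac - 0.05) <= 2 * se
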