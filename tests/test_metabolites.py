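"""Metabolite screen: ANOVA oracle, post hoc, normalization, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import anova_f_oracle
from resistomics.metabolites import (
    MetaboliteMatrix,
    anova_per_metabolite,
    posthoc_pairwise,
    reference_normalize,
    top_k_cluster_order,
)
from resistomics.simulate import SimulationSpec, gen_metabolite_table


def matrix_from_groups(groups: dict[str, np.ndarray],
                       metabolite: str = "met") -> MetaboliteMatrix:
    rows, labels, idx = [], [], []
    for g, vals in groups.items():
        for i, v in enumerate(np.atleast_2d(vals).T if np.ndim(vals) == 1
                              else vals):
            rows.append(np.atleast_1d(v))
            labels.append(g)
            idx.append(f"{g}_{i}")
    values = pd.DataFrame(np.vstack(rows), index=idx,
                          columns=[metabolite] if np.ndim(
                              next(iter(groups.values()))) == 1 else None)
    return MetaboliteMatrix(values, pd.Series(labels, index=idx))


class TestMatrixInvariants:
    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            matrix_from_groups({"a": np.array([1.0, 2.0])})

    def test_group_with_one_sample_rejected(self):
        with pytest.raises(ValueError, match="within-group"):
            matrix_from_groups({"a": np.array([1.0, 2.0]),
                                "b": np.array([3.0])})

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            matrix_from_groups({"a": np.array([1.0, 0.0]),
                                "b": np.array([2.0, 3.0])})

    def test_missing_metabolites_dropped_with_warning(self, caplog):
        values = pd.DataFrame(
            {"m1": [1.0, 2, 3, 4], "m2": [1.0, np.nan, 3, 4]},
            index=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        with caplog.at_level("WARNING"):
            m = MetaboliteMatrix(values, groups)
        assert list(m.values.columns) == ["m1"]


class TestAnova:
    def test_worked_three_group_example(self):
        """Groups (1,2,3), (2,3,4), (3,4,5) on the raw scale: SSB = 6 on
        2 df, SSW = 6 on 6 df, hence F = 3."""
        m = matrix_from_groups({
            "a": np.array([1.0, 2, 3]),
            "b": np.array([2.0, 3, 4]),
            "c": np.array([3.0, 4, 5]),
        })
        res = anova_per_metabolite(m, log_transform=False)
        assert res.iloc[0]["F"] == pytest.approx(3.0, abs=1e-12)
        assert res.iloc[0]["p"] == pytest.approx(
            stats.f.sf(3.0, 2, 6), abs=1e-12)

    def test_zero_within_group_variance_flagged_degenerate(self):
        m = matrix_from_groups({
            "a": np.array([1.0, 1, 1]), "b": np.array([2.0, 2, 2])})
        res = anova_per_metabolite(m)
        assert bool(res.iloc[0]["degenerate"])
        assert np.isnan(res.iloc[0]["p"]) and np.isnan(res.iloc[0]["padj"])

    def test_invariant_to_within_group_sample_order(self, rng):
        spec = SimulationSpec(seed=5, n_metabolites=15, samples_per_group=4)
        m, _ = gen_metabolite_table(spec)
        res1 = anova_per_metabolite(m)
        perm = rng.permutation(len(m.values))
        shuffled = MetaboliteMatrix(m.values.iloc[perm], m.groups.iloc[perm])
        res2 = anova_per_metabolite(shuffled)
        pd.testing.assert_frame_equal(res1, res2)

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(30):
            groups = {
                g: np.exp(rng.normal(size=int(rng.integers(3, 7))))
                for g in ("a", "b", "c")
            }
            m = matrix_from_groups(groups)
            res = anova_per_metabolite(m, log_transform=False)
            expect = anova_f_oracle([groups[g] for g in ("a", "b", "c")])
            assert res.iloc[0]["F"] == pytest.approx(expect, abs=1e-9)

    def test_bh_null_rate_bounded(self):
        """Under a global null the BH-significant fraction at FDR 0.05
        stays below 0.05 plus 3 binomial standard errors."""
        n_sig = n_tot = 0
        for seed in range(150):
            spec = SimulationSpec(seed=seed, effect_size=0.0, n_metabolites=20)
            m, _ = gen_metabolite_table(spec)
            res = anova_per_metabolite(m)
            n_sig += int((res["padj"] < 0.05).sum())
            n_tot += len(res)
        frac = n_sig / n_tot
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tot)


class TestPosthoc:
    def test_identical_groups_give_p_one(self):
        m = matrix_from_groups({
            "a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])})
        res = posthoc_pairwise(m, "met", log_transform=False)
        assert res.iloc[0]["p_adj"] == pytest.approx(1.0)

    def test_symmetric_in_pair_order(self):
        m = matrix_from_groups({
            "a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 7]),
            "c": np.array([2.0, 2, 4])})
        res = posthoc_pairwise(m, "met", log_transform=False)
        m2 = matrix_from_groups({
            "c": np.array([2.0, 2, 4]), "b": np.array([4.0, 5, 7]),
            "a": np.array([1.0, 2, 3])})
        res2 = posthoc_pairwise(m2, "met", log_transform=False)
        pair = lambda df: {frozenset((r.group1, r.group2)): r.p_adj
                           for r in df.itertuples()}
        for k, v in pair(res).items():
            assert v == pytest.approx(pair(res2)[k])

    def test_tukey_dominates_pooled_t(self, rng):
        """Tukey's family-wise adjusted p never undercuts the t-test on
        the same pair computed with the pooled within-group variance."""
        from scipy.stats import t as tdist
        for _ in range(100):
            groups = {g: rng.normal(size=4) + rng.normal()
                      for g in ("a", "b", "c")}
            groups = {g: np.exp(v) for g, v in groups.items()}
            m = matrix_from_groups(groups)
            res = posthoc_pairwise(m, "met", log_transform=True)
            logs = {g: np.log2(v) for g, v in groups.items()}
            ssw = sum(((v - v.mean()) ** 2).sum() for v in logs.values())
            df_w = sum(len(v) for v in logs.values()) - 3
            msw = ssw / df_w
            for r in res.itertuples():
                x, y = logs[r.group1], logs[r.group2]
                se = np.sqrt(msw * (1 / len(x) + 1 / len(y)))
                t_p = 2 * tdist.sf(abs(x.mean() - y.mean()) / se, df_w)
                assert r.p_adj >= t_p - 1e-12

    def test_unknown_metabolite_rejected(self):
        m = matrix_from_groups({
            "a": np.array([1.0, 2]), "b": np.array([3.0, 4])})
        with pytest.raises(KeyError):
            posthoc_pairwise(m, "nope")


class TestReferenceNormalize:
    def test_reference_rows_average_to_zero(self):
        spec = SimulationSpec(seed=9, n_metabolites=12)
        m, _ = gen_metabolite_table(spec)
        norm = reference_normalize(m, "parental")
        ref = norm[(m.groups == "parental").values]
        assert np.abs(ref.mean(axis=0)).max() < 1e-12

    def test_doubling_shifts_by_one_log2_unit(self):
        m = matrix_from_groups({
            "ref": np.array([1.0, 1, 1]), "x": np.array([2.0, 2, 2])})
        norm = reference_normalize(m, "ref")
        doubled = MetaboliteMatrix(m.values * np.where(
            (m.groups == "x").values[:, None], 2.0, 1.0), m.groups)
        norm2 = reference_normalize(doubled, "ref")
        diff = (norm2 - norm)[(m.groups == "x").values]
        assert np.allclose(diff, 1.0)

    def test_round_trip_recovers_input(self, rng):
        spec = SimulationSpec(seed=13, n_metabolites=8)
        m, _ = gen_metabolite_table(spec)
        norm = reference_normalize(m, "parental")
        log2 = np.log2(m.values)
        ref_mean = log2[(m.groups == "parental").values].mean(axis=0)
        back = 2.0 ** (norm + ref_mean)
        assert np.allclose(back, m.values, rtol=1e-10)

    def test_missing_reference_group_rejected(self):
        m = matrix_from_groups({
            "a": np.array([1.0, 2]), "b": np.array([3.0, 4])})
        with pytest.raises(ValueError, match="reference"):
            reference_normalize(m, "zzz")


class TestTopKClusterOrder:
    def _anova(self, metabolites, ps):
        return pd.DataFrame({
            "metabolite": metabolites, "F": 1.0, "p": ps, "padj": ps,
            "degenerate": False})

    def test_k_one_returns_single_smallest_p(self):
        norm = pd.DataFrame(np.ones((4, 3)), columns=list("abc"))
        anova = self._anova(list("abc"), [0.5, 0.01, 0.2])
        assert top_k_cluster_order(norm, anova, 1) == ["b"]

    def test_identical_rows_adjacent_in_leaf_order(self, rng):
        data = rng.normal(size=(6, 5))
        data[:, 2] = data[:, 0]  # metabolite 'c' duplicates 'a'
        norm = pd.DataFrame(data, columns=list("abcde"))
        anova = self._anova(list("abcde"), [0.01, 0.02, 0.03, 0.04, 0.05])
        order = top_k_cluster_order(norm, anova, 5)
        assert abs(order.index("a") - order.index("c")) == 1

    def test_leaf_order_invariant_to_column_permutation(self, rng):
        data = rng.normal(size=(6, 8))
        cols = [f"m{i}" for i in range(8)]
        norm = pd.DataFrame(data, columns=cols)
        ps = rng.uniform(size=8)
        anova = self._anova(cols, ps)
        order1 = top_k_cluster_order(norm, anova, 5)
        perm = rng.permutation(8)
        order2 = top_k_cluster_order(
            norm.iloc[:, perm], anova.iloc[perm].reset_index(drop=True), 5)
        assert order1 == order2

    def test_k_zero_warns_and_returns_empty(self, caplog):
        norm = pd.DataFrame(np.ones((3, 2)), columns=list("ab"))
        with caplog.at_level("WARNING"):
            assert top_k_cluster_order(
                norm, self._anova(list("ab"), [0.1, 0.2]), 0) == []

    def test_k_exceeding_usable_rejected(self):
        norm = pd.DataFrame(np.ones((3, 2)), columns=list("ab"))
        with pytest.raises(ValueError):
            top_k_cluster_order(norm, self._anova(list("ab"), [0.1, 0.2]), 3)

    def test_planted_perturbation_ranks_above_null(self):
        """Perturbed metabolites (2 SD shift, 3/group) land above the
        unperturbed ones by median ANOVA rank in >= 90% of seeds."""
        good = 0
        for seed in range(60):
            spec = SimulationSpec(seed=seed, n_metabolites=40,
                                  n_perturbed_metabolites=6)
            m, truth = gen_metabolite_table(spec)
            res = anova_per_metabolite(m)
            rank = {r.metabolite: i for i, r in enumerate(res.itertuples())}
            pert = truth["perturbed_metabolites"]
            null = [c for c in m.values.columns if c not in pert]
            good += (np.median([rank[x] for x in pert])
                     < np.median([rank[x] for x in null]))
        assert good >= 0.9 * 60
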