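"""BLUE estimation, one-way ANOVA, Duncan letters, early/late calls."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
import pytest

from soyhap import association as assoc
from soyhap.errors import InsufficientDataError
from soyhap.models import HaplotypeTable, PhenologyRecord


def _rec(cultivar, env, days, year=2020):
    ve = dt.date(year, 5, 17)
    return PhenologyRecord(cultivar_id=cultivar, env_id=env, ve_date=ve,
                           r1_date=ve + dt.timedelta(days=45),
                           r7_date=ve + dt.timedelta(days=int(days)))


class TestBlue:
    def test_balanced_noise_free_identity(self):
        """Balanced complete data: BLUE differences equal true cultivar
        mean differences exactly (both solvers)."""
        true_means = {"A": 100.0, "B": 105.0, "C": 112.0}
        env_effects = {"E1": -2.0, "E2": 0.0, "E3": 3.0}
        records = [_rec(c, e, true_means[c] + env_effects[e])
                   for c in true_means for e in env_effects]
        for method in ("reml", "ols"):
            blues = {b.cultivar_id: b.blue_value
                     for b in assoc.compute_blue(records, method=method)}
            for a, b in itertools.combinations(true_means, 2):
                assert blues[a] - blues[b] == pytest.approx(
                    true_means[a] - true_means[b], abs=1e-9), method
        # and with sum-to-zero environment coding the level matches too
        blues = {b.cultivar_id: b.blue_value
                 for b in assoc.compute_blue(records, method="ols")}
        grand_env = np.mean(list(env_effects.values()))
        for c in true_means:
            assert blues[c] == pytest.approx(true_means[c] + grand_env,
                                             abs=1e-9)

    def test_recovery_correlation_default_bundle(self, default_bundle):
        """Six environments, 3-day noise: BLUEs track the true genetic
        values with correlation above 0.95."""
        panel = [r for r in default_bundle.phenology
                 if r.cultivar_id.startswith("CV")]
        blues = assoc.compute_blue(panel)
        truth = default_bundle.genetic_values
        pairs = [(b.blue_value, truth[b.cultivar_id]) for b in blues]
        corr = np.corrcoef(*zip(*pairs))[0, 1]
        assert corr > 0.95

    def test_reml_matches_statsmodels_oracle(self):
        """Independent mixed-model fit (statsmodels MixedLM, REML) on a
        small unbalanced panel reproduces the same BLUEs."""
        import pandas as pd
        import statsmodels.api as sm

        rng = np.random.default_rng(44)
        records = []
        for i in range(25):
            for env, effect in (("E1", -3.0), ("E2", 0.0), ("E3", 2.0),
                                ("E4", 4.0)):
                if rng.random() < 0.25:  # unbalanced
                    continue
                records.append(_rec(f"c{i:02d}", env,
                                    100 + 0.7 * i + effect
                                    + rng.normal(0, 2)))
        mine = {b.cultivar_id: b.blue_value
                for b in assoc.compute_blue(records, method="reml")}
        df = pd.DataFrame([(r.cultivar_id, r.env_id, r.ve_r7_days)
                           for r in records],
                          columns=["cultivar", "env", "days"])
        exog = pd.get_dummies(pd.Categorical(df["cultivar"]), dtype=float)
        fit = sm.MixedLM(df["days"].to_numpy(float), exog,
                         groups=df["env"].to_numpy()).fit(reml=True)
        re_mean = float(np.mean([float(v.iloc[0])
                                 for v in fit.random_effects.values()]))
        for i, c in enumerate(exog.columns):
            assert mine[c] == pytest.approx(
                float(fit.fe_params.iloc[i]) + re_mean, abs=1e-4)

    def test_irrelevant_singleton_rows_do_not_move_blue(self):
        """A cultivar observed in every environment keeps its BLUE when
        cultivars observed in a single environment are dropped: their
        rows are absorbed entirely by their own fixed effects."""
        rng = np.random.default_rng(9)
        envs = ["E1", "E2", "E3"]
        full = [_rec("full", e, 100 + rng.normal(0, 2)) for e in envs]
        others = [_rec("anchor", e, 95 + rng.normal(0, 2)) for e in envs]
        singletons = [_rec(f"s{i}", envs[i % 3], 90 + 5 * i)
                      for i in range(6)]
        for method in ("reml", "ols"):
            with_all = {b.cultivar_id: b.blue_value for b in
                        assoc.compute_blue(full + others + singletons,
                                           method=method)}
            without = {b.cultivar_id: b.blue_value for b in
                       assoc.compute_blue(full + others, method=method)}
            assert with_all["full"] == pytest.approx(without["full"],
                                                     abs=1e-6), method

    def test_requires_two_environments(self):
        records = [_rec(f"c{i}", "E1", 100 + i) for i in range(5)]
        with pytest.raises(InsufficientDataError):
            assoc.compute_blue(records)


class TestAnova:
    def test_two_group_t_squared_equals_f(self):
        rng = np.random.default_rng(3)
        groups = {"H1": rng.normal(100, 3, 40).tolist(),
                  "H2": rng.normal(104, 3, 25).tolist()}
        f_stat, p, df_b, df_w, t_stat = assoc.anova_haplotypes(groups)
        assert t_stat**2 == pytest.approx(f_stat, abs=1e-10)
        assert (df_b, df_w) == (1, 63)

    def test_all_equal_degenerate(self):
        groups = {"H1": [5.0] * 10, "H2": [5.0] * 12}
        f_stat, p, *_ = assoc.anova_haplotypes(groups)
        assert f_stat == 0.0 and p == 1.0

    def test_small_groups_excluded_with_warning(self, caplog):
        groups = {"H1": [1.0, 2.0, 3.0], "H2": [4.0], "H3": [2.0, 3.0]}
        with caplog.at_level("WARNING"):
            f_stat, *_ = assoc.anova_haplotypes(groups)
        assert "H2" in caplog.text
        with pytest.raises(InsufficientDataError):
            assoc.anova_haplotypes({"H1": [1.0, 2.0], "H2": [3.0]})


def duncan_oracle(groups: dict[str, list[float]], alpha: float = 0.05):
    """Brute-force pair significance from the definition: a pair is
    non-significant iff SOME containing span of the descending-ordered
    means has range <= its critical range (protected step-down)."""
    labels = list(groups)
    means = np.array([np.mean(groups[lab]) for lab in labels])
    order = np.argsort(-means, kind="stable")
    mse, df = assoc.pooled_mse(groups)
    sizes = np.array([len(groups[lab]) for lab in labels], float)
    nh = len(sizes) / np.sum(1.0 / sizes)
    ranges = assoc.duncan_critical_ranges(len(labels), mse, df, nh, alpha)
    k = len(labels)
    nonsig = {}
    for a in range(k):
        for b in range(a + 1, k):
            nonsig[(a, b)] = any(
                means[order[i]] - means[order[j]] <= ranges[j - i + 1]
                for i in range(0, a + 1) for j in range(b, k))
    return labels, order, nonsig


def shares_letter(letters, lab1, lab2):
    return bool(set(letters[lab1]) & set(letters[lab2]))


class TestDuncan:
    def test_all_equal_single_letter(self):
        groups = {"H1": [10.0, 10.1, 9.9], "H2": [10.0, 10.05, 9.95],
                  "H3": [10.02, 9.98, 10.0]}
        letters, _ = assoc.duncan_mrt(groups)
        assert set(letters.values()) == {"a"}

    def test_widely_separated_distinct_letters(self):
        rng = np.random.default_rng(8)
        groups = {lab: (base + rng.normal(0, 1, 12)).tolist()
                  for lab, base in (("lo", 0.0), ("mid", 10.0), ("hi", 20.0))}
        letters, _ = assoc.duncan_mrt(groups)
        assert letters["hi"] == "a"
        assert letters["mid"] == "b"
        assert letters["lo"] == "c"

    def test_matches_span_enumeration_oracle(self):
        """Random 3-6 group data: the letter-sharing pattern equals the
        brute-force span oracle."""
        rng = np.random.default_rng(55)
        for _ in range(60):
            k = int(rng.integers(3, 7))
            groups = {f"G{j}": (rng.normal(rng.uniform(0, 3), 1.0,
                                           int(rng.integers(3, 12)))).tolist()
                      for j in range(k)}
            letters, _ = assoc.duncan_mrt(groups)
            labels, order, nonsig = duncan_oracle(groups)
            for (a, b), expected in nonsig.items():
                got = shares_letter(letters, labels[order[a]],
                                    labels[order[b]])
                assert got == expected, (groups, letters)

    def test_invariant_to_shift_and_relabeling(self):
        rng = np.random.default_rng(10)
        groups = {f"G{j}": rng.normal(j, 1.0, 8).tolist() for j in range(4)}
        letters, _ = assoc.duncan_mrt(groups)
        shifted = {lab: [v + 123.4 for v in vals]
                   for lab, vals in groups.items()}
        letters_shift, _ = assoc.duncan_mrt(shifted)
        assert letters == letters_shift
        renamed = {f"X{lab}": vals for lab, vals in groups.items()}
        letters_renamed, _ = assoc.duncan_mrt(renamed)
        assert {f"X{lab}": v for lab, v in letters.items()} == letters_renamed

    def test_two_groups_agree_with_t_test(self):
        """With 2 equal-size groups, Duncan's decision at alpha equals
        the unadjusted equal-variance t-test decision."""
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        agree = 0
        for _ in range(100):
            shift = rng.uniform(0, 2.0)
            g1 = rng.normal(0, 1, 10)
            g2 = rng.normal(shift, 1, 10)
            letters, _ = assoc.duncan_mrt({"A": g1.tolist(),
                                           "B": g2.tolist()})
            duncan_sig = not shares_letter(letters, "A", "B")
            t_sig = sps.ttest_ind(g1, g2, equal_var=True).pvalue < 0.05
            agree += duncan_sig == t_sig
        assert agree == 100


def test_studentized_range_quantile_matches_scipy():
    """The quadrature-based quantile agrees with scipy's reference
    distribution across span sizes, dfs and protection levels."""
    from scipy import stats as sps

    for prob, k, df in [(0.95, 2, 10), (0.95, 4, 30), (0.99, 6, 5),
                        (0.90, 3, 100), (0.9025, 3, 25), (0.95, 2, 437)]:
        mine = assoc.studentized_range_quantile(prob, k, float(df))
        ref = float(sps.studentized_range.ppf(prob, k, df))
        assert mine == pytest.approx(ref, abs=1e-6)


class TestEarlyLate:
    def test_two_group_split(self):
        early, late = assoc.classify_early_late(
            {"H1": 110.0, "H2": 120.0}, {"H1": "b", "H2": "a"})
        assert early == frozenset({"H1"})
        assert late == frozenset({"H2"})

    def test_all_shared_letter_empty_sets(self):
        early, late = assoc.classify_early_late(
            {"H1": 110.0, "H2": 111.0}, {"H1": "a", "H2": "a"})
        assert early == frozenset() and late == frozenset()

    def test_intermediate_overlapping_unclassified(self):
        means = {"H1": 100.0, "H2": 105.0, "H3": 110.0}
        letters = {"H1": "b", "H2": "ab", "H3": "a"}
        early, late = assoc.classify_early_late(means, letters)
        assert early == frozenset({"H1"})
        assert late == frozenset({"H2", "H3"})
        assert not early & late


def test_associate_gene_end_to_end(default_bundle):
    """Planted -5 d haplotype of the stop-gain gene is recovered as the
    early set with a distinct Duncan letter."""
    from soyhap.haplotypes import build_haplotypes

    bundle = default_bundle
    panel = [r for r in bundle.phenology if r.cultivar_id.startswith("CV")]
    blues = assoc.compute_blue(panel)
    gene = bundle.genes[0]
    table = build_haplotypes(gene, bundle.variants)
    result = assoc.associate_gene(blues, table)
    assert result.anova_p < 1e-6
    # the alt-carrying haplotype is the early one (planted effect -5 d)
    alt_label = next(lab for lab, s in table.haplotypes.items() if "A" in s)
    assert result.early_set == frozenset({alt_label})
    assert result.late_set == frozenset(table.haplotypes) - {alt_label}
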