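"""Gated frequencies, paired Wilcoxon, binomial tests, Bonferroni families."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clsig.cohort import (
    NOT_COMPUTED,
    binomial_vs_reference,
    bonferroni,
    exact_signed_rank_p,
    paired_wilcoxon,
    stars,
    stratify,
    vgene_usage_comparison,
)
from clsig.reference import AnalysisParameters


def toy_clonotypes(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "donor_id", "cd5", "light_chain", "b_subset", "mut_status",
            "is_clsig", "subset_id", "typicality",
        ],
    )
    return df


def test_single_clsig_frequency_is_undefined():
    rows = [["D1", "POS", "KAPPA", "N", "U", True, "T01", "TYPICAL"]]
    rows += [["D1", "POS", "KAPPA", "N", "U", False, None, "NA"]] * 99
    rec = stratify(toy_clonotypes(rows), ["cd5"])
    assert len(rec) == 1
    assert rec["n_clsig"].iloc[0] == 1
    assert np.isnan(rec["freq_pct"].iloc[0])


def test_two_clsig_among_thousand_is_0_2_pct():
    rows = [["D1", "POS", "KAPPA", "N", "U", True, "T01", "TYPICAL"]] * 2
    rows += [["D1", "POS", "KAPPA", "N", "U", False, None, "NA"]] * 998
    rec = stratify(toy_clonotypes(rows), ["cd5"])
    assert rec["freq_pct"].iloc[0] == pytest.approx(0.2)


def test_zero_clsig_is_undefined_not_zero():
    rows = [["D1", "POS", "KAPPA", "N", "U", False, None, "NA"]] * 50
    rec = stratify(toy_clonotypes(rows), ["cd5"])
    assert rec["n_clsig"].iloc[0] == 0
    assert np.isnan(rec["freq_pct"].iloc[0])


def test_unknown_key_is_parameter_error():
    with pytest.raises(ValueError):
        stratify(toy_clonotypes([]), ["flavour"])


def test_stratum_additivity(rng):
    """Numerators and denominators of a partition sum to the parent stratum."""
    rows = []
    for i in range(500):
        rows.append(
            [
                f"D{rng.integers(1, 4)}",
                "POS" if rng.random() < 0.5 else "NEG",
                "KAPPA" if rng.random() < 0.5 else "LAMBDA",
                "N",
                "U" if rng.random() < 0.6 else "M",
                bool(rng.random() < 0.1),
                "T01",
                "NA",
            ]
        )
    df = toy_clonotypes(rows)
    parent = stratify(df, ["cd5"])
    child = stratify(df, ["cd5", "mut_status"])
    for (donor, cd5), grp in child.groupby(["donor_id", "cd5"]):
        prow = parent[(parent["donor_id"] == donor) & (parent["cd5"] == cd5)]
        assert grp["n_total"].sum() == prow["n_total"].iloc[0]
        assert grp["n_clsig"].sum() == prow["n_clsig"].iloc[0]


def test_subset_key_partitions_numerator_only():
    rows = [["D1", "POS", "KAPPA", "N", "U", True, "T01", "TYPICAL"]] * 2
    rows += [["D1", "POS", "KAPPA", "N", "U", True, "T02", "TYPICAL"]] * 3
    rows += [["D1", "POS", "KAPPA", "N", "U", False, None, "NA"]] * 95
    rec = stratify(toy_clonotypes(rows), ["subset_id"])
    assert set(rec["subset_id"]) == {"T01", "T02"}
    assert (rec["n_total"] == 100).all()
    assert sorted(rec["n_clsig"]) == [2, 3]


# -- Wilcoxon ----------------------------------------------------------------

def test_wilcoxon_not_computed_below_three_pairs():
    assert paired_wilcoxon({"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 0.0}) is (
        NOT_COMPUTED
    )


def test_wilcoxon_undefined_pairs_dropped():
    x = {"a": 1.0, "b": 2.0, "c": np.nan, "d": 3.0, "e": 4.0}
    y = {"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0, "e": np.nan}
    res = paired_wilcoxon(x, y)
    assert res.n == 3


def test_wilcoxon_all_zero_differences_not_computed():
    v = {"a": 1.0, "b": 2.0, "c": 3.0}
    assert paired_wilcoxon(v, v) is NOT_COMPUTED


def test_wilcoxon_five_positive_pairs_p_0625():
    res = paired_wilcoxon(
        {k: v for k, v in zip("abcde", [1, 2, 3, 4, 5.0])},
        {k: 0.0 for k in "abcde"},
    )
    assert res.p_raw == pytest.approx(0.0625)


def brute_force_p(d):
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ]
    )
    lo = min(w, total - w)
    hi = total - lo
    p = ((ws <= lo + 1e-9).sum() + (ws >= hi - 1e-9).sum()) / 2.0**n
    return min(1.0, p)


def test_wilcoxon_matches_exhaustive_enumeration(rng):
    """Exact p equals full 2^n sign enumeration for all n <= 10, with ties."""
    for n in range(1, 11):
        for _ in range(20):
            d = rng.integers(-5, 6, size=n).astype(float)
            if np.all(d == 0):
                continue
            p, _, _ = exact_signed_rank_p(d)
            assert p == pytest.approx(brute_force_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact_when_tie_free(rng):
    for _ in range(50):
        d = rng.normal(size=int(rng.integers(6, 20)))
        p, _, _ = exact_signed_rank_p(d)
        assert p == pytest.approx(stats.wilcoxon(d, method="exact").pvalue)


def test_wilcoxon_large_n_uses_normal_approximation(rng):
    d = rng.normal(0.3, 1.0, size=60)
    p, _, n = exact_signed_rank_p(d)
    ref = stats.wilcoxon(d, correction=True, method="approx").pvalue
    assert p == pytest.approx(ref, rel=1e-6)


# -- binomial ----------------------------------------------------------------

def test_binomial_matches_scipy_and_contains_tail():
    res = binomial_vs_reference(0, 10, 0.1)
    assert res.p_raw >= 0.9**10
    assert res.p_raw == pytest.approx(stats.binomtest(0, 10, 0.1).pvalue)


def test_binomial_mode_gives_p_one():
    assert binomial_vs_reference(2, 10, 0.2).p_raw == pytest.approx(1.0)


def test_binomial_degenerate_pref_zero():
    assert binomial_vs_reference(0, 10, 0.0).p_raw == 1.0


def test_binomial_symmetry(rng):
    for _ in range(30):
        n = int(rng.integers(1, 40))
        k = int(rng.integers(0, n + 1))
        p = float(rng.random())
        a = binomial_vs_reference(k, n, p).p_raw
        b = binomial_vs_reference(n - k, n, 1 - p).p_raw
        assert a == pytest.approx(b, rel=1e-9)


def test_binomial_invalid_pref():
    with pytest.raises(ValueError):
        binomial_vs_reference(1, 2, 1.5)


# -- Bonferroni and stars ----------------------------------------------------

def test_bonferroni_family():
    r1 = binomial_vs_reference(0, 10, 0.5)
    fam = bonferroni([r1])
    assert fam[0].p_adjusted == fam[0].p_raw
    many = bonferroni([r1] * 5)
    assert all(t.p_adjusted == min(1.0, t.p_raw * 5) for t in many)


def test_bonferroni_clamps_at_one():
    r = binomial_vs_reference(5, 10, 0.5)  # p = 1 at mode
    assert bonferroni([r] * 5)[0].p_adjusted == 1.0


def test_star_convention():
    assert stars(0.04) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
    assert stars(0.00009) == "****"
    assert stars(0.2) == "ns"
    # 0.03 * 3 = 0.09 -> no star after correction
    from clsig.cohort import TestMethod, TestResult

    r = TestResult("x", TestMethod.BINOMIAL, 3, 1.0, 0.03)
    adj = bonferroni([r, r, r])[0]
    assert adj.p_adjusted == pytest.approx(0.09)
    assert adj.significance == "ns"


# -- V-gene usage ------------------------------------------------------------

def test_vgene_usage_comparison_setup(subset_defs):
    d = subset_defs[0]
    typical = sorted(d.typical_v_genes)
    clsig = pd.DataFrame({"v_gene": [typical[0]] * 8})
    genes = typical + ["IGHV1-2", "IGHV1-69", "IGHV5-51", "IGHV7-4-1"]
    controls = pd.DataFrame({"v_gene": genes[:4] * 5})
    out = vgene_usage_comparison(clsig, controls, d)
    assert out["typical_share_clsig"] == 1.0
    assert 0 < out["typical_share_control"] < 1
    assert out["typical_test"].n == 8
    # empty control set -> NOT_COMPUTED
    assert vgene_usage_comparison(clsig, controls.iloc[:0], d) is NOT_COMPUTED
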