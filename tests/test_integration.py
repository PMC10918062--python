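"""Spearman correlation, one-proportion test, exact intervals, and the full
integration stage."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirmint import (
    ConsistencyError,
    NormalizedMatrix,
    SimConfig,
    UndefinedStatisticError,
    clopper_pearson_ci,
    correlate_targets,
    cpm,
    de_ttest,
    direction_call,
    generate_dataset,
    integrate,
    log2_transform,
    one_proportion_test,
    one_proportion_test_exact,
    spearman_pvalue,
    spearman_rho,
)
from mirmint.selection import SelectionResult


# ---------------------------------------------------------------------------
# Spearman rho
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3], [10, 20, 30], 1.0),
        ([1, 2, 2, 4], [4, 3, 2, 1], -0.9486832980505138),  # average-rank ties
    ],
)
def test_spearman_rho_examples(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)
    assert spearman_rho(y, x) == pytest.approx(expected, abs=1e-12)  # symmetry


def test_spearman_rho_constant_input_undefined():
    with pytest.raises(UndefinedStatisticError):
        spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_rho_matches_scipy(rng):
    for _ in range(20):
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# Spearman p-values
# ---------------------------------------------------------------------------

def exact_spearman_oracle(x, y):
    """Two-sided permutation p by looping scipy.spearmanr over all n! orders."""
    n = len(x)
    obs = abs(stats.spearmanr(x, y).statistic)
    hits = total = 0
    y = np.asarray(y)
    for perm in permutations(range(n)):
        total += 1
        hits += abs(stats.spearmanr(x, y[list(perm)]).statistic) >= obs - 1e-12
    return hits / total


def test_exact_p_perfect_correlation_n3():
    assert spearman_pvalue(1.0, 3, "exact") == pytest.approx(2 / 6)


def test_p_of_zero_rho_is_one():
    assert spearman_pvalue(0.0, 5, "exact") == 1.0
    assert spearman_pvalue(0.0, 50, "t_approx") == 1.0


def test_exact_p_matches_enumeration_oracle(rng):
    for n in (4, 5, 6):
        for _ in range(4):
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho = spearman_rho(x, y)
            assert spearman_pvalue(rho, n, "exact") == pytest.approx(
                exact_spearman_oracle(x, y), abs=1e-12
            )


def test_t_approx_matches_closed_form():
    rho, n = 0.6, 20
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    assert spearman_pvalue(rho, n, "t_approx") == pytest.approx(2 * stats.t.sf(t, n - 2))
    assert spearman_pvalue(0.999999, 30, "t_approx") < 1e-12
    with pytest.raises(ValueError):
        spearman_pvalue(1.5, 10)


# ---------------------------------------------------------------------------
# one-proportion test
# ---------------------------------------------------------------------------

def test_one_proportion_worked_examples():
    z, p = one_proportion_test(2, 2)
    assert z == pytest.approx(0.7071, abs=1e-4)
    assert p == pytest.approx(0.4795, abs=1e-4)
    z, p = one_proportion_test(8, 10)
    assert z == pytest.approx(1.5811, abs=1e-4)
    assert p == pytest.approx(0.1138, abs=1e-4)


def test_one_proportion_null_value_floors_to_zero():
    z, p = one_proportion_test(5, 10, 0.5)
    assert z == 0.0 and p == 1.0


def test_one_proportion_two_sided_symmetry():
    for n in (4, 7, 12):
        for x in range(n + 1):
            _, p1 = one_proportion_test(x, n, 0.5)
            _, p2 = one_proportion_test(n - x, n, 0.5)
            assert p1 == pytest.approx(p2, abs=1e-15)


def test_one_proportion_monotone_in_distance():
    """Beyond the continuity-correction floor, p decreases as |x - n*p0|
    grows for fixed n."""
    n = 20
    ps = [one_proportion_test(x, n, 0.5)[1] for x in range(10, 21)]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_one_proportion_domain_errors():
    with pytest.raises(UndefinedStatisticError):
        one_proportion_test(0, 0)
    with pytest.raises(ValueError):
        one_proportion_test(5, 4)
    with pytest.raises(ValueError):
        one_proportion_test(1, 4, p0=1.0)


def test_exact_binomial_variant():
    p_hat, p = one_proportion_test_exact(8, 10)
    assert p_hat == 0.8
    assert p == pytest.approx(stats.binomtest(8, 10, 0.5).pvalue)


# ---------------------------------------------------------------------------
# Clopper-Pearson intervals
# ---------------------------------------------------------------------------

def test_ci_printed_table_values():
    low, high = clopper_pearson_ci(3, 4)
    assert (round(low, 2), round(high, 2)) == (19.41, 99.37)
    low, high = clopper_pearson_ci(2, 2)
    assert (round(low, 2), round(high, 2)) == (15.81, 100.00)
    assert low == pytest.approx(100 * 0.025 ** (1 / 2))


def test_ci_boundary_closed_forms():
    for n in (1, 4, 9):
        low, high = clopper_pearson_ci(n, n)
        assert low == pytest.approx(100 * 0.025 ** (1 / n))
        assert high == 100.0
        low0, high0 = clopper_pearson_ci(0, n)
        assert low0 == 0.0
        # reflection symmetry: interval for x=0 mirrors x=n
        assert high0 == pytest.approx(100 - low)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 40), st.data())
def test_ci_always_covers_point_estimate(n, data):
    x = data.draw(st.integers(0, n))
    low, high = clopper_pearson_ci(x, n)
    assert low - 1e-9 <= 100 * x / n <= high + 1e-9
    assert 0.0 <= low <= high <= 100.0


def test_ci_rejects_bad_conf():
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 2, conf=1.0)


# ---------------------------------------------------------------------------
# direction calls
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("inv, pos, expected", [(3, 1, "YES"), (1, 3, "NO"), (2, 2, "EQUAL")])
def test_direction_call(inv, pos, expected):
    assert direction_call(inv, pos) == expected


def test_direction_swap_maps_yes_to_no():
    for inv, pos in [(5, 2), (0, 3), (4, 4)]:
        a, b = direction_call(inv, pos), direction_call(pos, inv)
        assert {a, b} in ({"YES", "NO"}, {"EQUAL"})


# ---------------------------------------------------------------------------
# correlate_targets / integrate
# ---------------------------------------------------------------------------

def _expr(df_vals, index, samples):
    return NormalizedMatrix(pd.DataFrame(df_vals, index=index, columns=samples), log2=True)


def test_correlate_filters_to_significant_targets():
    samples = list("abcdef")
    mi = _expr([[1, 2, 3, 4, 5, 6.0]], ["miR-x"], samples)
    mr = _expr(np.arange(18.0).reshape(3, 6), ["G1", "G2", "G3"], samples)
    out = correlate_targets("miR-x", ["G1", "G2", "G3"], mi, mr, de_mrna_sig=set())
    assert len(out) == 0
    out = correlate_targets("miR-x", ["G1", "G4"], mi, mr, de_mrna_sig={"G1", "G4"})
    assert list(out["gene"]) == ["G1"]  # G4 absent from the matrix -> excluded


def test_correlate_rejects_sample_mismatch():
    mi = _expr([[1, 2, 3.0]], ["miR-x"], ["a", "b", "c"])
    mr = _expr([[1, 2, 3.0]], ["G1"], ["a", "c", "b"])
    with pytest.raises(ConsistencyError):
        correlate_targets("miR-x", ["G1"], mi, mr, {"G1"})


def test_correlate_recovers_planted_inverse_pair():
    """A strongly coupled regulator-target pair at 10 samples/group is
    classified inverse at alpha 0.05."""
    ds = generate_dataset(
        SimConfig(n_mirna=40, n_mrna=120, n_per_group=10, targets_per_mirna=8,
                  n_regulators=2, frac_de_mirna=0.2, seed=7)
    )
    mi = log2_transform(cpm(ds.mirna))
    mr = log2_transform(cpm(ds.mrna))
    reg = sorted(ds.truth.regulators)[0]
    inverse_genes = [g for (m, g), s in ds.truth.regulated_pairs.items()
                     if m == reg and s < 0]
    out = correlate_targets(reg, inverse_genes, mi, mr, set(inverse_genes))
    assert (out["class"] == "inverse").mean() >= 0.75


def _mini_world(n_sig_targets=6):
    """Hand-built world with one focus miRNA whose 6 DE targets all move
    opposite to it across 8 samples (plus one uncorrelated non-DE gene)."""
    samples = [f"s{i}" for i in range(8)]
    x = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
    mi = _expr([x], ["miR-x"], samples)
    genes = [f"G{i}" for i in range(1, 8)]
    vals = np.vstack(
        [-x + 0.1 * np.sin(np.arange(8) + i) for i in range(6)]
        + [np.cos(np.arange(8))]
    )
    mr = _expr(vals, genes, samples)
    from mirmint import TargetMap

    tmap = TargetMap(tuple(("miR-x", g) for g in genes))
    de_mirna = pd.DataFrame({"feature": ["miR-x"], "p": [0.001], "log2fc": [1.0]})
    focus = SelectionResult(
        pd.DataFrame({"rank": [1], "mirna": ["miR-x"], "group_mean": [10.0],
                      "in_focus_set": [True]}),
        ("miR-x",),
    )
    return focus, tmap, mi, mr, de_mirna, set(genes[:n_sig_targets])


def test_integrate_all_inverse_candidate():
    focus, tmap, mi, mr, de_mirna, sig = _mini_world()
    res = integrate(focus, tmap, mi, mr, de_mirna, sig)
    row = res.proportion.iloc[0]
    assert row["n_sig"] == 6 and row["n_inverse"] == 6
    assert row["inversely_related"] == "YES"
    assert (row["ci_low"], row["ci_high"]) == pytest.approx(
        (100 * 0.025 ** (1 / 6), 100.0)
    )
    assert res.candidate_regulators == {"miR-x"}
    assert res.candidate_pairs == {("miR-x", f"G{i}") for i in range(1, 7)}


def test_integrate_skips_below_min_targets():
    focus, tmap, mi, mr, de_mirna, _ = _mini_world()
    res = integrate(focus, tmap, mi, mr, de_mirna, de_mrna_sig=set())
    assert len(res.proportion) == 0
    assert len(res.candidates) == 0
    assert res.candidate_regulators == frozenset()


def test_integrate_label_swap_preserves_p():
    """Swapping inverse/positive labels flips the direction call but leaves
    the two-sided proportion p unchanged (checked via the symmetric test)."""
    _, p_yes = one_proportion_test(6, 8, 0.5)
    _, p_no = one_proportion_test(2, 8, 0.5)
    assert p_yes == pytest.approx(p_no)
    assert direction_call(6, 2) == "YES" and direction_call(2, 6) == "NO"


def test_integrate_output_ordering_deterministic():
    focus, tmap, mi, mr, de_mirna, sig = _mini_world()
    r1 = integrate(focus, tmap, mi, mr, de_mirna, sig)
    r2 = integrate(focus, tmap, mi, mr, de_mirna, sig)
    pd.testing.assert_frame_equal(r1.proportion, r2.proportion)
    pd.testing.assert_frame_equal(r1.correlations, r2.correlations)
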