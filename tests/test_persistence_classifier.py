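import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.sandbox.stats.runs import runstest_1samp

from raretrends import persistence_classifier as pc


def run_count_distribution(n0, n1):
    """Exact distribution of the number of runs over all C(n, n1)
    arrangements (standard combinatorial formula; independent oracle)."""
    total = comb(n0 + n1, n1)
    dist = {}
    for k in range(1, min(n0, n1) + 1):
        dist[2 * k] = 2 * comb(n1 - 1, k - 1) * comb(n0 - 1, k - 1) / total
        r = comb(n1 - 1, k) * comb(n0 - 1, k - 1) + comb(n1 - 1, k - 1) * comb(n0 - 1, k)
        if r:
            dist[2 * k + 1] = r / total
    return dist


def exact_two_sided_p(presence):
    n1 = presence.count("1")
    n0 = presence.count("0")
    R = 1 + sum(1 for a, b in zip(presence, presence[1:]) if a != b)
    e = 1 + 2 * n1 * n0 / (n1 + n0)
    dist = run_count_distribution(n0, n1)
    return sum(p for r, p in dist.items() if abs(r - e) >= abs(R - e) - 1e-12)


def pop(years_abund, aid="A", sid="sp"):
    years = list(range(2000, 2000 + len(years_abund)))
    return pc.PopulationSeries(aid, sid, years, list(years_abund))


@pytest.mark.parametrize(
    "s,expected",
    [("00111", (1, 0)), ("11100", (0, 1)), ("0110101", (3, 2)), ("1", (0, 0))],
)
def test_transition_counts(s, expected):
    assert pc.count_transitions(s) == expected


def test_runs_test_plugin_values():
    # n0 = n1 = 5, R = 10: E[R] = 6, Var[R] = 20/9
    assert pc.runs_test("0101010101") == pytest.approx(0.00729036, abs=1e-7)
    # R = 2 is symmetric about E[R], same |z|
    assert pc.runs_test("0000011111") == pytest.approx(0.00729036, abs=1e-7)


def test_runs_test_undefined_for_one_level():
    assert math.isnan(pc.runs_test("11111"))
    assert math.isnan(pc.runs_test("000"))


def test_runs_test_matches_independent_implementation():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(4, 30))
        s = "".join(rng.choice(["0", "1"], n))
        if len(set(s)) < 2:
            continue
        _, p_ref = runstest_1samp(np.array([int(c) for c in s]), cutoff=0.5, correction=False)
        assert pc.runs_test(s) == pytest.approx(p_ref, abs=1e-12)


def test_runs_test_approximation_tightens_with_length():
    """The normal tail approaches the enumeration oracle as strings grow:
    for balanced two-block strings the absolute error shrinks with length."""
    errs = []
    for n in (10, 20, 40):
        s = "0" * (n // 2) + "1" * (n // 2)
        errs.append(abs(pc.runs_test(s) - exact_two_sided_p(s)))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-4


def test_select_rare_populations():
    from raretrends.rarefaction import RarefiedYear

    years = [
        RarefiedYear("A", 2000, -1.0, {"common": 5, "rare1": 1, "never": 9}),
        RarefiedYear("A", 2001, 0.0, {"common": 5, "rare2": 2, "never": 8}),
        RarefiedYear("A", 2002, 1.0, {"common": 5, "rare1": 4, "never": 7}),
    ]
    pops = pc.select_rare_populations(years)
    assert {p.species_id for p in pops} == {"rare1", "rare2"}
    r1 = next(p for p in pops if p.species_id == "rare1")
    assert r1.abundances == [1, 0, 4]   # full trajectory, explicit zeros
    assert r1.presence == "101"


def test_classify_rules():
    always = pop([3, 1, 2, 5, 1, 2, 1, 4, 2, 1])
    assert pc.classify(always).category == "persistent"

    imm = pop([0, 0, 0, 0, 1, 2, 1, 1, 2, 1])  # 0000111111: runs p < 0.05
    res = pc.classify(imm)
    assert res.category == "immigration"
    assert (res.n_immigration_events, res.n_extinction_events) == (1, 0)

    ext = pop([1, 2, 1, 1, 2, 1, 0, 0, 0, 0])
    assert pc.classify(ext).category == "extinction"

    # 0011001100: transitions (2,2) but runs p = 0.206 -> gate fails -> persistent
    ambiguous = pop([0, 0, 1, 1, 0, 0, 1, 1, 0, 0])
    res = pc.classify(ambiguous)
    assert res.category == "persistent"
    assert res.runs_p > 0.05

    # long clean multiple: blocks of 5, runs test significant
    multi = pop([0] * 5 + [1] * 5 + [0] * 5 + [1] * 5)
    res = pc.classify(multi)
    assert res.category == "multiple"
    assert res.n_immigration_events + res.n_extinction_events >= 2


def test_classify_is_invariant_to_abundance_magnitude():
    rng = np.random.default_rng(2)
    for _ in range(30):
        ab = rng.integers(0, 4, size=15)
        if ab.max() == 0:
            continue
        base = pc.classify(pop(ab.tolist()))
        ones = pc.classify(pop([1 if a > 0 else 0 for a in ab]))
        assert base.category == ones.category


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=4, max_size=25).filter(lambda s: any(s)))
def test_reversal_swaps_immigration_and_extinction(bits):
    cat = pc.classify(pop(bits)).category
    rev = pc.classify(pop(bits[::-1])).category
    swap = {"immigration": "extinction", "extinction": "immigration",
            "persistent": "persistent", "multiple": "multiple"}
    assert rev == swap[cat]


def test_tabulate_counts_and_proportions():
    results = [pc.classify(pop([1] * 10, sid=f"s{i}")) for i in range(6)]
    results += [pc.classify(pop([0] * 5 + [1] * 5 + [0] * 5 + [1] * 5, sid=f"m{i}")) for i in range(2)]
    results.append(pc.classify(pop([0] * 5 + [1] * 5, sid="i")))
    results.append(pc.classify(pop([1] * 5 + [0] * 5, sid="e")))
    table = pc.tabulate_categories(results)
    assert table["counts"] == {"persistent": 6, "immigration": 1, "extinction": 1, "multiple": 2}
    assert sum(table["counts"].values()) == table["n_populations"] == 10
    assert table["proportions"]["persistent"] == pytest.approx(0.6)
    assert sum(table["proportions"].values()) == pytest.approx(1.0)


def test_population_series_validation():
    with pytest.raises(ValueError):
        pc.PopulationSeries("A", "s", [2000, 2000], [1, 1])
    with pytest.raises(ValueError):
        pc.PopulationSeries("A", "s", [2000, 2001], [0, 0])
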