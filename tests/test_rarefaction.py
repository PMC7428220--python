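import numpy as np
import pytest

from raretrends import rarefaction


def effort_series(make, spy):
    """Series with given {year: n_samples}; each sample holds 2 species."""
    rows = []
    for y, n in spy.items():
        for j in range(n):
            rows.append((y, f"s{j}", "sp1", 1 + j))
            rows.append((y, f"s{j}", "sp2", 2))
    return make(rows)


@pytest.mark.parametrize(
    "spy,kept",
    [
        ({2000: 4, 2001: 4, 2002: 1}, [2000, 2001]),   # mean 3, threshold 1.5
        ({2000: 2, 2001: 2}, [2000, 2001]),             # threshold 1, ties kept
        ({2000: 10, 2001: 5, 2002: 5, 2003: 4}, [2000, 2001, 2002, 2003]),  # mean 6
    ],
)
def test_filter_years_half_mean_rule(series_factory, spy, kept):
    out = rarefaction.filter_years(effort_series(series_factory, spy))
    assert sorted(out.samples_per_year()) == kept


def test_filter_years_all_removed_is_degenerate(series_factory):
    s = effort_series(series_factory, {2000: 1})
    s.records = s.records.iloc[0:0]
    with pytest.raises(rarefaction.DegenerateSeriesError):
        rarefaction.filter_years(s)


def test_year_at_minimum_keeps_full_sums(series_factory):
    s = effort_series(series_factory, {2000: 3, 2001: 2})
    for seed in (0, 1, 99):
        out = rarefaction.rarefy(s, seed)
        by_year = {r.year: r for r in out}
        # 2001 attains n_min=2: its output is its full within-year sums
        assert by_year[2001].abundances == {"sp1": 1 + 2, "sp2": 4}
        assert len(by_year[2000].sample_ids) == 2  # exactly n_min whole occasions


def test_single_sample_years_are_identity(series_factory):
    s = effort_series(series_factory, {2000: 1, 2001: 1, 2002: 1})
    out = rarefaction.rarefy(s, seed=5)
    assert all(len(r.sample_ids) == 1 for r in out)
    assert all(r.abundances == {"sp1": 1, "sp2": 2} for r in out)


def test_same_seed_reproduces_draw(series_factory):
    s = effort_series(series_factory, {2000: 5, 2001: 2, 2002: 4})
    a = rarefaction.rarefy(s, seed=42)
    b = rarefaction.rarefy(s, seed=42)
    assert [(r.year, r.sample_ids, r.abundances) for r in a] == \
           [(r.year, r.sample_ids, r.abundances) for r in b]


def test_rarefied_never_exceeds_raw_sums(series_factory):
    rng = np.random.default_rng(3)
    rows = []
    for y in range(2000, 2006):
        for j in range(int(rng.integers(2, 6))):
            for sp in ("a", "b", "c"):
                if rng.random() < 0.7:
                    rows.append((y, f"s{j}", sp, int(rng.integers(1, 9))))
    s = rarefaction.filter_years(series_factory(rows))
    raw = s.records.groupby(["year", "species_id"])["abundance"].sum()
    out = rarefaction.rarefy(s, seed=1)
    n_min = min(s.samples_per_year().values())
    for r in out:
        assert len(set(r.sample_ids)) == n_min
        for sp, ab in r.abundances.items():
            assert 1 <= ab <= raw[(r.year, sp)]


def test_centered_years_sum_to_zero(series_factory):
    s = effort_series(series_factory, {2000: 2, 2003: 2, 2010: 2})
    out = rarefaction.rarefy(s, seed=0)
    assert abs(sum(r.centered_year for r in out)) < 1e-9


def test_iterations_identical_when_effort_equal(series_factory):
    s = effort_series(series_factory, {2000: 3, 2001: 3, 2002: 3})
    its = rarefaction.rarefy_iterations(s, n_iterations=20, base_seed=9)
    ref = [(r.year, r.abundances) for r in its[0]]
    assert all([(r.year, r.abundances) for r in it] == ref for it in its)


def test_iterations_vary_but_plan_is_stable(series_factory):
    rng = np.random.default_rng(11)
    rows = []
    for y in range(2000, 2008):
        for j in range(int(rng.integers(2, 7))):
            for k in range(4):
                rows.append((y, f"s{j}", f"sp{k}", int(rng.integers(1, 20))))
    s = rarefaction.filter_years(series_factory(rows))
    n_min = min(s.samples_per_year().values())
    its = rarefaction.rarefy_iterations(s, n_iterations=20, base_seed=2)
    totals = set()
    for it in its:
        assert [r.year for r in it] == sorted(s.samples_per_year())
        assert all(len(r.sample_ids) == n_min for r in it)
        totals.add(sum(sum(r.abundances.values()) for r in it))
    assert len(totals) > 1  # subsampling varies across iterations


def test_single_iteration_matches_direct_call(series_factory):
    s = effort_series(series_factory, {2000: 4, 2001: 2})
    (it1,) = rarefaction.rarefy_iterations(s, n_iterations=1, base_seed=7)
    direct = rarefaction.rarefy(s, 7, iteration=1)
    assert [(r.year, r.abundances) for r in it1] == [(r.year, r.abundances) for r in direct]


def test_non_aggregable_keeps_one_designated_sample(series_factory):
    s = effort_series(series_factory, {2000: 3, 2001: 3})
    s.is_aggregable = False
    out = rarefaction.rarefy(s, seed=0)
    assert all(r.sample_ids == ("s0",) for r in out)
    assert all(r.abundances == {"sp1": 1, "sp2": 2} for r in out)
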