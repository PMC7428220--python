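"""Sample-based rarefaction: equalize sampling effort across the years of an
assemblage time series.

Monitoring effort often varies from year to year. To make yearly summaries
comparable, every retained year is represented by the same number of *whole*
sampling occasions: years with fewer than half the mean number of occasions
are excluded, the minimum occasion count among the remaining years (``n_min``)
is found, and exactly ``n_min`` occasions are drawn uniformly without
replacement from each year. Entire occasions are kept intact (sample
integrity) and species abundances are then summed within each year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AssemblageTimeSeries


class DegenerateSeriesError(ValueError):
    """Effort filtering removed every year of a series."""


@dataclass(frozen=True)
class RarefactionPlan:
    """Record of one rarefaction draw: which years survived effort filtering,
    the common occasion count, and the seed that drove sample selection."""

    retained_years: tuple[int, ...]
    n_min: int
    seed: int
    iteration_index: int = 1


@dataclass
class RarefiedYear:
    """Post-rarefaction species -> abundance map for one assemblage-year.

    ``centered_year`` is the calendar year minus the mean of the retained
    years of its assemblage — the predictor used by all trend models.
    """

    assemblage_id: str
    year: int
    centered_year: float
    abundances: dict[str, int]
    sample_ids: tuple[str, ...] = ()


def filter_years(series: AssemblageTimeSeries) -> AssemblageTimeSeries:
    """Drop years with fewer than half the mean number of sampling occasions.

    The mean is computed once, over all years originally present; a year is
    excluded iff its occasion count is strictly below mean/2 (ties retained).
    """
    spy = series.samples_per_year()
    if not spy:
        raise DegenerateSeriesError(f"{series.assemblage_id}: empty series")
    mean_occ = float(np.mean(list(spy.values())))
    keep = {y for y, n in spy.items() if n >= mean_occ / 2.0}
    if not keep:
        raise DegenerateSeriesError(f"{series.assemblage_id}: all years below effort threshold")
    kept = series.records[series.records["year"].isin(keep)].reset_index(drop=True)
    return AssemblageTimeSeries(series.assemblage_id, kept, series.is_aggregable)


def _rng_for(seed: int, iteration: int = 1) -> np.random.Generator:
    # Splittable counter-based derivation: independent, reproducible streams
    # per (seed, iteration) regardless of call order.
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(iteration))))


def make_plan(series: AssemblageTimeSeries, seed: int, iteration: int = 1) -> RarefactionPlan:
    """The draw-independent part of a rarefaction: retained years and n_min.

    ``series`` must already be effort-filtered; the plan is identical across
    iterations except for the seed pair that drives occasion selection.
    """
    spy = series.samples_per_year()
    if not spy:
        raise DegenerateSeriesError(f"{series.assemblage_id}: empty series")
    n_min = min(spy.values())
    if n_min < 1:  # pragma: no cover - spy counts distinct ids, always >= 1
        raise DegenerateSeriesError(f"{series.assemblage_id}: year without occasions")
    return RarefactionPlan(
        retained_years=tuple(sorted(spy)),
        n_min=n_min,
        seed=int(seed),
        iteration_index=int(iteration),
    )


def rarefy(
    series: AssemblageTimeSeries,
    seed: int,
    iteration: int = 1,
    designated_sample: str | None = None,
) -> list[RarefiedYear]:
    """One rarefaction draw on an effort-filtered series.

    For each retained year, ``n_min`` whole sampling occasions are drawn
    uniformly without replacement (the year attaining the minimum contributes
    all of its occasions) and species abundances are summed over the drawn
    occasions. Identical ``(series, seed, iteration)`` give identical output.

    When ``series.is_aggregable`` is False, within-year summation is replaced
    by keeping a single designated occasion per year (the lexicographically
    first, or ``designated_sample`` where present).
    """
    plan = make_plan(series, seed, iteration)
    rng = _rng_for(plan.seed, plan.iteration_index)
    years = list(plan.retained_years)
    n_min = plan.n_min
    mean_year = float(np.mean(years))
    rec = series.records
    out: list[RarefiedYear] = []
    for y in years:
        sub = rec[rec["year"] == y]
        sample_ids = sorted(sub["sample_id"].unique())
        if not series.is_aggregable:
            chosen = [designated_sample] if designated_sample in sample_ids else [sample_ids[0]]
        elif len(sample_ids) == n_min:
            chosen = sample_ids
        else:
            idx = rng.choice(len(sample_ids), size=n_min, replace=False)
            chosen = [sample_ids[i] for i in sorted(idx)]
        kept = sub[sub["sample_id"].isin(chosen)]
        sums = kept.groupby("species_id")["abundance"].sum()
        out.append(
            RarefiedYear(
                assemblage_id=series.assemblage_id,
                year=int(y),
                centered_year=float(y) - mean_year,
                abundances={str(s): int(a) for s, a in sums.items()},
                sample_ids=tuple(chosen),
            )
        )
    return out


def rarefy_iterations(
    series: AssemblageTimeSeries, n_iterations: int = 20, base_seed: int = 0
) -> list[list[RarefiedYear]]:
    """Repeat :func:`rarefy` with independently derived seeds.

    Iteration ``k`` (1-based) uses the stream derived from
    ``(base_seed, k)``; downstream statistics can be recomputed per iteration
    to assess robustness to the random occasion draws.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    return [rarefy(series, base_seed, iteration=k) for k in range(1, n_iterations + 1)]


def rarefied_to_frame(rarefied: list[RarefiedYear], iteration: int = 1):
    """Long DataFrame view of rarefied output (one row per species-year)."""
    import pandas as pd

    rows = [
        (ry.assemblage_id, iteration, ry.year, ry.centered_year, sp, ab)
        for ry in rarefied
        for sp, ab in sorted(ry.abundances.items())
    ]
    return pd.DataFrame(
        rows, columns=["assemblage_id", "iteration", "year", "centered_year", "species_id", "abundance"]
    )
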