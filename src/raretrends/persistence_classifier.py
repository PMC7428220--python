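"""Classify rare-species populations as persistent, immigration, extinction or
multiple from their binary presence strings.

A population is a single species' yearly abundance trajectory within one
assemblage. Populations that were ever rare (abundance 1 or 2 in at least one
standardized year) are converted to presence/absence strings over the sampled
years; 0 -> 1 transitions are immigration events and 1 -> 0 transitions local
extinctions. Because a noisy detection process can fabricate such
transitions, counting is gated by a two-sided Wald-Wolfowitz runs test: only
populations whose run structure departs significantly from a random
arrangement have their transitions interpreted as colonization/extinction
events; everything else is called persistent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from scipy.stats import norm

from .rarefaction import RarefiedYear

CATEGORIES = ("persistent", "immigration", "extinction", "multiple")


@dataclass
class PopulationSeries:
    """One species' trajectory in one assemblage over the sampled years."""

    assemblage_id: str
    species_id: str
    years: list[int]
    abundances: list[int]  # 0 = sampled but absent

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if len(self.years) != len(self.abundances):
            raise ValueError("years and abundances must align")
        if not any(a > 0 for a in self.abundances):
            raise ValueError("species never present in the assemblage")

    @property
    def presence(self) -> str:
        return "".join("1" if a > 0 else "0" for a in self.abundances)


@dataclass
class PersistenceResult:
    assemblage_id: str
    species_id: str
    category: str
    n_immigration_events: int
    n_extinction_events: int
    runs_p: float  # nan when the string has a single level
    string_length: int


def select_rare_populations(rarefied_years: list[RarefiedYear]) -> list[PopulationSeries]:
    """Populations of species that were rare (abundance 1 or 2) in >= 1 year.

    The full trajectory is retained — abundances may rise above 2 in other
    years — and years where the assemblage was sampled but the species absent
    become explicit zeros.
    """
    if len(rarefied_years) < 2:
        raise ValueError("need rarefied data for >= 2 years")
    ordered = sorted(rarefied_years, key=lambda r: r.year)
    years = [r.year for r in ordered]
    species = sorted({s for r in ordered for s in r.abundances})
    out = []
    for sp in species:
        traj = [r.abundances.get(sp, 0) for r in ordered]
        if any(a in (1, 2) for a in traj):
            out.append(PopulationSeries(ordered[0].assemblage_id, sp, list(years), traj))
    return out


def count_transitions(presence: str) -> tuple[int, int]:
    """(number of 0->1 immigrations, number of 1->0 extinctions).

    Only adjacent pairs count; the ends of the string contribute nothing.
    """
    if len(presence) < 1 or set(presence) - {"0", "1"}:
        raise ValueError("presence must be a non-empty string of 0s and 1s")
    imm = sum(1 for a, b in zip(presence, presence[1:]) if (a, b) == ("0", "1"))
    ext = sum(1 for a, b in zip(presence, presence[1:]) if (a, b) == ("1", "0"))
    return imm, ext


def runs_test(presence: str) -> float:
    """Two-sided Wald-Wolfowitz runs test p-value (normal approximation).

    With n1 ones, n0 zeros and R observed runs:
    E[R] = 1 + 2*n1*n0/(n1+n0),
    Var[R] = 2*n1*n0*(2*n1*n0 - n1 - n0) / ((n1+n0)^2 * (n1+n0-1)),
    z = (R - E[R]) / sqrt(Var[R]), p = 2*Phi(-|z|). No continuity
    correction. Returns nan when the string has only one level (the test is
    undefined).
    """
    if len(presence) < 2 or set(presence) - {"0", "1"}:
        raise ValueError("presence must be a binary string of length >= 2")
    n1 = presence.count("1")
    n0 = presence.count("0")
    if n0 == 0 or n1 == 0:
        return math.nan
    n = n0 + n1
    runs = 1 + sum(1 for a, b in zip(presence, presence[1:]) if a != b)
    e_r = 1.0 + 2.0 * n1 * n0 / n
    var_r = 2.0 * n1 * n0 * (2.0 * n1 * n0 - n) / (n * n * (n - 1.0))
    if var_r <= 0:
        return math.nan
    z = (runs - e_r) / math.sqrt(var_r)
    return float(2.0 * norm.sf(abs(z)))


def classify(pop: PopulationSeries, alpha: float = 0.05) -> PersistenceResult:
    """Four-way classification of one rare population.

    Rules, in order: (a) never absent -> persistent; (b) runs test undefined
    or non-significant at ``alpha`` -> persistent (transitions are treated as
    detection noise); (c) otherwise one immigration and no extinction ->
    immigration, one extinction and no immigration -> extinction, two or more
    events in total -> multiple (this includes strings like ``1101`` whose
    single dip is significant).
    """
    s = pop.presence
    imm, ext = count_transitions(s)
    p = runs_test(s) if len(s) >= 2 else math.nan
    if "0" not in s:
        cat = "persistent"
    elif math.isnan(p) or p >= alpha:
        cat = "persistent"
    else:
        total = imm + ext
        if total == 0:
            raise RuntimeError(
                f"internal inconsistency: significant runs test (p={p}) with zero transitions in {s!r}"
            )
        if (imm, ext) == (1, 0):
            cat = "immigration"
        elif (imm, ext) == (0, 1):
            cat = "extinction"
        else:
            cat = "multiple"
    return PersistenceResult(
        assemblage_id=pop.assemblage_id,
        species_id=pop.species_id,
        category=cat,
        n_immigration_events=imm,
        n_extinction_events=ext,
        runs_p=p,
        string_length=len(s),
    )


def tabulate_categories(results: list[PersistenceResult]) -> dict:
    """Counts and proportions per category; counts sum to len(results)."""
    if not results:
        raise ValueError("no results to tabulate")
    counts = Counter(r.category for r in results)
    n = len(results)
    return {
        "n_populations": n,
        "counts": {c: counts.get(c, 0) for c in CATEGORIES},
        "proportions": {c: counts.get(c, 0) / n for c in CATEGORIES},
    }


def results_frame(results: list[PersistenceResult]):
    """Tabular view: one row per classified population."""
    import pandas as pd

    return pd.DataFrame(
        [
            (r.assemblage_id, r.species_id, r.category, r.n_immigration_events,
             r.n_extinction_events, r.runs_p, r.string_length)
            for r in results
        ],
        columns=["assemblage_id", "species_id", "category", "n_immigration_events",
                 "n_extinction_events", "runs_p", "string_length"],
    )
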