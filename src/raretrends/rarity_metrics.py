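"""Per-year assemblage summaries: singletons, singletons+doubletons,
Fisher's log-series alpha, species richness and assemblage size.

Local rarity is operationalized on standardized (rarefied) yearly samples:
a singleton is a species represented by exactly one individual, a doubleton
by exactly two. "Rarity" below means the count of singletons plus doubletons
(species with abundance <= 2). Fisher's alpha is the diversity parameter of
the log-series species-abundance model, the unique positive root of
S = alpha * ln(1 + N/alpha) given richness S and total individuals N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .rarefaction import RarefiedYear

logger = logging.getLogger(__name__)


class DegenerateSADError(ValueError):
    """Fisher's alpha has no finite root (every individual its own species)."""


@dataclass
class YearlyMetrics:
    assemblage_id: str
    year: int
    centered_year: float
    n_singletons: int
    n_rare: int
    fisher_alpha: float  # nan when S == N (degenerate) and sentinel mode on
    richness_S: int
    size_N: int


def count_singletons(abundances: dict[str, int]) -> int:
    """Number of species represented by exactly one individual."""
    return sum(1 for a in abundances.values() if a == 1)


def count_rare(abundances: dict[str, int]) -> int:
    """Number of singletons plus doubletons (abundance 1 or 2)."""
    return sum(1 for a in abundances.values() if a in (1, 2))


def fisher_alpha(richness_S: int, size_N: int, on_degenerate: str = "raise") -> float:
    """Fisher's log-series alpha from richness S and assemblage size N.

    Solves S = alpha * ln(1 + N/alpha) for alpha > 0 by bracketed
    root-finding (relative tolerance 1e-10). The left side increases from 0
    (alpha -> 0) to N (alpha -> inf), so a unique finite root exists iff
    S < N.

    Parameters
    ----------
    on_degenerate
        What to do when S == N (no finite root): ``"raise"`` (default) or
        ``"nan"`` to return a sentinel.
    """
    if not (1 <= richness_S <= size_N):
        raise ValueError(f"need 1 <= S <= N, got S={richness_S}, N={size_N}")
    if richness_S == size_N:
        if on_degenerate == "nan":
            return math.nan
        raise DegenerateSADError(f"S == N == {richness_S}: alpha diverges (all singletons)")
    f = lambda a: a * math.log1p(size_N / a) - richness_S  # noqa: E731
    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e15:  # pragma: no cover - unreachable for S < N
            raise RuntimeError("failed to bracket Fisher's alpha")
    return float(brentq(f, lo, hi, rtol=1e-12, xtol=1e-300, maxiter=200))


def summarize_year(rarefied: RarefiedYear, alpha_on_degenerate: str = "nan") -> YearlyMetrics | None:
    """All yearly metrics from one rarefied assemblage-year.

    Returns None (with a logged warning) for an empty year, which then
    contributes no row to the metrics table.
    """
    ab = rarefied.abundances
    if not ab:
        logger.warning("%s year %d is empty after rarefaction; skipped", rarefied.assemblage_id, rarefied.year)
        return None
    S = len(ab)
    N = sum(ab.values())
    return YearlyMetrics(
        assemblage_id=rarefied.assemblage_id,
        year=rarefied.year,
        centered_year=rarefied.centered_year,
        n_singletons=count_singletons(ab),
        n_rare=count_rare(ab),
        fisher_alpha=fisher_alpha(S, N, on_degenerate=alpha_on_degenerate),
        richness_S=S,
        size_N=N,
    )


def metrics_frame(rarefied_years: list[RarefiedYear], iteration: int = 1):
    """Metrics table (one row per non-empty assemblage-year) as a DataFrame."""
    import numpy as np
    import pandas as pd

    rows = []
    for ry in rarefied_years:
        m = summarize_year(ry)
        if m is None:
            continue
        rows.append(
            (m.assemblage_id, iteration, m.year, m.centered_year, m.n_singletons, m.n_rare,
             m.fisher_alpha, m.richness_S, m.size_N)
        )
    df = pd.DataFrame(
        rows,
        columns=["assemblage_id", "iteration", "year", "centered_year",
                 "n_singletons", "n_rare", "fisher_alpha", "richness_S", "size_N"],
    )
    if len(df):
        df["log10_richness"] = np.log10(df["richness_S"])
        df["log10_size"] = np.log10(df["size_N"])
    return df
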