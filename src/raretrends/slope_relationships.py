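"""Correlations between per-assemblage trend slopes of different biodiversity
facets, with a random-removal sensitivity analysis.

The question "does rarity change track richness change?" is answered by
pairing each assemblage's rate of change in one facet with its rate in
another and computing Pearson's r across assemblages. Robustness to
influential assemblages is probed by recomputing r many times after randomly
removing a fraction of the assemblages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trend_models import TrendFit

#: Facet pairs computed by default: the three headline relationships plus the
#: two metric-agreement checks (alternative rarity measures vs the main one).
DEFAULT_PAIRS = [
    ("n_rare", "log10_richness"),
    ("n_rare", "log10_size"),
    ("log10_richness", "log10_size"),
    ("n_rare", "n_singletons"),
    ("n_rare", "fisher_alpha"),
]


class DegenerateCorrelationError(ValueError):
    """Fewer than 3 pairs, or zero variance in one coordinate."""


@dataclass
class SlopePair:
    """Paired per-assemblage slopes for two facets (assemblages in both fits)."""

    facet_x: str
    facet_y: str
    assemblage_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_fits(cls, fit_x: TrendFit, fit_y: TrendFit) -> "SlopePair":
        common = sorted(set(fit_x.assemblage_slopes) & set(fit_y.assemblage_slopes))
        return cls(
            facet_x=fit_x.response,
            facet_y=fit_y.response,
            assemblage_ids=common,
            x=np.array([fit_x.assemblage_slopes[a] for a in common]),
            y=np.array([fit_y.assemblage_slopes[a] for a in common]),
        )

    @classmethod
    def from_arrays(cls, x, y, facet_x="x", facet_y="y", ids=None) -> "SlopePair":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ids = [str(i) for i in (ids if ids is not None else range(len(x)))]
        return cls(facet_x, facet_y, ids, x, y)

    def __len__(self) -> int:
        return len(self.x)


def correlate_slopes(pair: SlopePair) -> float:
    """Pearson product-moment correlation of the paired slopes."""
    if len(pair) < 3:
        raise DegenerateCorrelationError(f"need >= 3 pairs, got {len(pair)}")
    if np.ptp(pair.x) == 0 or np.ptp(pair.y) == 0:
        raise DegenerateCorrelationError("zero variance in one coordinate")
    return float(stats.pearsonr(pair.x, pair.y).statistic)


@dataclass
class SensitivityResult:
    facet_x: str
    facet_y: str
    drop_fraction: float
    r_full: float
    replicates: np.ndarray  # r per successful replicate
    n_skipped: int          # replicates with < 3 surviving pairs

    @property
    def median(self) -> float:
        return float(np.median(self.replicates))

    @property
    def percentile_band(self) -> tuple[float, float]:
        return tuple(np.percentile(self.replicates, [2.5, 97.5]))

    def summary(self) -> dict:
        lo, hi = self.percentile_band
        return {
            "facet_x": self.facet_x, "facet_y": self.facet_y,
            "drop_fraction": self.drop_fraction, "r_full": self.r_full,
            "n_replicates": int(len(self.replicates)), "n_skipped": self.n_skipped,
            "median": self.median, "p2.5": lo, "p97.5": hi,
        }


def sensitivity_correlations(
    pair: SlopePair, drop_fraction: float, n_reps: int = 200, seed: int = 0
) -> SensitivityResult:
    """Recompute r ``n_reps`` times after removing ``round(f * n)`` pairs
    uniformly at random without replacement.

    Replicates left with fewer than 3 pairs (or zero variance) are skipped
    and counted. Results are reproducible given (seed, n_reps, drop_fraction).
    """
    if not (0.0 < drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(pair)
    r_full = correlate_slopes(pair)
    n_drop = int(round(drop_fraction * n))
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2718)))
    rs, skipped = [], 0
    for _ in range(n_reps):
        drop = rng.choice(n, size=n_drop, replace=False) if n_drop else np.array([], dtype=int)
        keep = np.setdiff1d(np.arange(n), drop)
        sub = SlopePair(pair.facet_x, pair.facet_y,
                        [pair.assemblage_ids[i] for i in keep], pair.x[keep], pair.y[keep])
        try:
            rs.append(correlate_slopes(sub))
        except DegenerateCorrelationError:
            skipped += 1
    return SensitivityResult(pair.facet_x, pair.facet_y, drop_fraction, r_full,
                             np.array(rs), skipped)


def correlation_matrix(fits: dict[str, TrendFit], pairs=None) -> list[dict]:
    """Full-data Pearson r for each facet pair available in ``fits``."""
    pairs = pairs if pairs is not None else DEFAULT_PAIRS
    out = []
    for fx, fy in pairs:
        if fx in fits and fy in fits:
            pair = SlopePair.from_fits(fits[fx], fits[fy])
            out.append({"facet_x": fx, "facet_y": fy, "n": len(pair), "r": correlate_slopes(pair)})
    return out
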