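"""Synthetic multi-assemblage abundance time series with known ground truth.

Each assemblage starts from a log-series species-abundance distribution (the
classic skewed SAD in which most species are rare), every species follows a
log-linear expected-abundance trajectory lambda_s(t) = lambda_s(0) * exp(b_s t),
new species may immigrate as a Poisson process, species may go locally
extinct, and an observation layer distributes yearly expected abundance over
a number of sampling occasions.

Three presets realize the canonical drivers of increasing local rarity:

``fig1a``  decreasing populations, no extinction (expected abundances are
           floored at a small positive value): rarity rises, richness is
           flat, assemblage size falls.
``fig1b``  decreasing populations with abundance-driven local extinction:
           rarity rises while richness and size both fall.
``fig2``   stable resident populations plus net immigration of new species
           arriving at abundance one: rarity and richness rise together and
           size rises slightly.

Ground truth records per-species slopes, arrival and extinction years, and
per-assemblage noise-free trajectories, so pipeline estimates can be scored
against what the generator actually did.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core_io import AbundanceRecord, AssemblageTimeSeries, from_records
from .persistence_classifier import PopulationSeries, runs_test

FIRST_YEAR = 2000


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for one batch of synthetic assemblages.

    ``sad_alpha`` and ``n_species_pool`` fix the initial log-series SAD (the
    implied community size is N = alpha*(exp(S/alpha)-1)). ``trend_mean`` and
    ``trend_sd`` give the per-species log-linear slope distribution (units:
    per year, natural-log scale). ``immigration_rate`` is the expected number
    of new species arriving per assemblage-year, each starting at expected
    abundance ``arrival_abundance``. ``extinction_mode`` is ``"none"``
    (expected abundances floored at ``lambda_floor``) or ``"trend_driven"``
    (a species whose sampled yearly total is zero for ``extinction_runs``
    consecutive years is removed). ``obs_model`` distributes a year's
    expectation over occasions: ``"poisson"`` draws independent
    Poisson(lambda/k) counts per occasion; ``"multinomial"`` fixes the yearly
    total at round(sum lambda) for size-controlled tests.
    """

    n_assemblages: int = 60
    n_years: int = 20
    samples_per_year: tuple[int, int] = (2, 4)
    n_species_pool: int = 150
    sad_alpha: float = 30.0
    trend_mean: float = 0.0
    trend_sd: float = 0.01
    immigration_rate: float = 0.0
    arrival_abundance: int = 1
    extinction_mode: str = "none"       # "none" | "trend_driven"
    extinction_runs: int = 2
    lambda_floor: float = 0.5
    obs_model: str = "poisson"          # "poisson" | "multinomial"
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 2 or self.n_species_pool < 1:
            raise ValueError("need n_years >= 2 and n_species_pool >= 1")
        if self.immigration_rate < 0 or self.trend_sd < 0:
            raise ValueError("rates must be >= 0")
        if self.extinction_mode not in ("none", "trend_driven"):
            raise ValueError(f"unknown extinction_mode {self.extinction_mode!r}")
        if self.obs_model not in ("poisson", "multinomial"):
            raise ValueError(f"unknown obs_model {self.obs_model!r}")


#: Scenario presets. Effort is held constant within the presets so that the
#: standardization step is the identity and ground truth stays directly
#: comparable to the fitted trends. fig2's immigration rate is calibrated so
#: the global log-scale rarity slope is close to +0.01 per year.
PRESETS = {
    "fig1a": ScenarioConfig(trend_mean=-0.03, trend_sd=0.01, immigration_rate=0.0,
                            extinction_mode="none", samples_per_year=(2, 2)),
    "fig1b": ScenarioConfig(trend_mean=-0.03, trend_sd=0.01, immigration_rate=0.0,
                            extinction_mode="trend_driven", samples_per_year=(2, 2)),
    "fig2": ScenarioConfig(trend_mean=0.0, trend_sd=0.01, immigration_rate=0.55,
                           arrival_abundance=1, extinction_mode="none",
                           samples_per_year=(2, 2)),
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """A named scenario preset, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


@dataclass
class GroundTruth:
    """What the generator actually did, per assemblage."""

    years: list[int]
    species_slopes: dict[str, dict[str, float]]
    arrival_years: dict[str, dict[str, int]]      # immigrants only
    extinction_years: dict[str, dict[str, int]]   # trend-driven removals only
    latent: dict[str, np.ndarray]                 # (T, 3): rarity, richness, size
    expected_sampled_rarity: dict[str, np.ndarray]  # (T,) E[# species with count 1 or 2]

    def latent_slopes(self, metric: str) -> dict[str, float]:
        """Per-assemblage OLS slope of a noise-free trajectory vs centered year.

        ``metric``: ``rarity`` (linear scale), ``log_richness`` or ``log_size``
        (log10 scale, mirroring how those facets are modelled).
        """
        col = {"rarity": 0, "log_richness": 1, "log_size": 2}[metric]
        t = np.array(self.years, float)
        t -= t.mean()
        out = {}
        for aid, traj in self.latent.items():
            y = traj[:, col].astype(float)
            if col > 0:
                y = np.log10(np.maximum(y, 1e-9))
            out[aid] = float(np.polyfit(t, y, 1)[0])
        return out

    @property
    def global_log_rarity_slope(self) -> float:
        """OLS slope of log(mean expected sampled rarity) vs centered year.

        This is the estimand of the negative-binomial trend model on these
        data: the yearly proportional change in the expected number of
        singleton-or-doubleton species, averaged over assemblages.
        """
        t = np.array(self.years, float)
        t -= t.mean()
        mean_traj = np.mean(np.stack(list(self.expected_sampled_rarity.values())), axis=0)
        return float(np.polyfit(t, np.log(mean_traj), 1)[0])


def _logseries_x(S: float, alpha: float) -> float:
    # implied community size for a log-series SAD with S species, parameter alpha
    N = alpha * math.expm1(S / alpha)
    return N / (N + alpha)


def _expected_rare(lam: np.ndarray) -> float:
    # E[# species whose Poisson(lambda) yearly total is 1 or 2]
    lam = lam[lam > 0]
    return float(np.sum(np.exp(-lam) * (lam + lam ** 2 / 2.0)))


def generate_scenario(config: ScenarioConfig) -> tuple[list[AbundanceRecord], GroundTruth]:
    """Simulate abundance records plus ground truth for one scenario.

    Deterministic given ``config`` (including its seed); assemblages use
    independently derived substreams.
    """
    records: list[AbundanceRecord] = []
    years = list(range(FIRST_YEAR, FIRST_YEAR + config.n_years))
    gt = GroundTruth(years=years, species_slopes={}, arrival_years={},
                     extinction_years={}, latent={}, expected_sampled_rarity={})
    x = _logseries_x(config.n_species_pool, config.sad_alpha)
    for a in range(config.n_assemblages):
        aid = f"A{a:03d}"
        rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), a)))
        lam0 = stats.logser.rvs(x, size=config.n_species_pool, random_state=rng).astype(float)
        slopes = rng.normal(config.trend_mean, config.trend_sd, size=config.n_species_pool)
        sids = [f"sp{i:04d}" for i in range(config.n_species_pool)]
        arrival = np.zeros(config.n_species_pool, dtype=int)  # residents from the start
        alive = np.ones(config.n_species_pool, dtype=bool)
        zero_run = np.zeros(config.n_species_pool, dtype=int)
        lam_start = lam0.copy()
        gt.arrival_years[aid] = {}
        gt.extinction_years[aid] = {}
        n_imm = 0
        latent = np.zeros((config.n_years, 3))
        exp_rare = np.zeros(config.n_years)
        for tix, year in enumerate(years):
            # immigration: new species arriving this year at low abundance
            if config.immigration_rate > 0 and tix > 0:
                n_new = rng.poisson(config.immigration_rate)
                if n_new:
                    new_ids = [f"imm{n_imm + i:04d}" for i in range(n_new)]
                    n_imm += n_new
                    sids.extend(new_ids)
                    arrival = np.concatenate([arrival, np.full(n_new, tix)])
                    alive = np.concatenate([alive, np.ones(n_new, dtype=bool)])
                    zero_run = np.concatenate([zero_run, np.zeros(n_new, dtype=int)])
                    lam_start = np.concatenate([lam_start, np.full(n_new, float(config.arrival_abundance))])
                    slopes = np.concatenate(
                        [slopes, rng.normal(config.trend_mean, config.trend_sd, size=n_new)]
                    )
                    for sid in new_ids:
                        gt.arrival_years[aid][sid] = year
            # latent expectations this year
            present = alive & (arrival <= tix)
            lam = np.where(present, lam_start * np.exp(slopes * (tix - arrival)), 0.0)
            if config.extinction_mode == "none":
                lam = np.where(present, np.maximum(lam, config.lambda_floor), 0.0)
            latent[tix, 0] = np.sum((lam > 0) & (lam <= 2.0))
            latent[tix, 1] = np.sum(lam > 0)
            latent[tix, 2] = lam.sum()
            exp_rare[tix] = _expected_rare(lam)
            # observation layer
            smin, smax = config.samples_per_year
            k = int(rng.integers(smin, smax + 1)) if smax > smin else smin
            counts = np.zeros((len(sids), k), dtype=np.int64)
            live = lam > 0
            if config.obs_model == "poisson":
                counts[live] = rng.poisson(np.repeat(lam[live, None] / k, k, axis=1))
            else:
                total = int(round(lam.sum()))
                if total > 0:
                    p = np.repeat(lam[:, None] / k, k, axis=1).ravel() / lam.sum()
                    counts = rng.multinomial(total, p).reshape(len(sids), k)
            for i, j in zip(*np.nonzero(counts)):
                records.append(AbundanceRecord(aid, year, f"S{j + 1}", sids[i], int(counts[i, j])))
            # trend-driven local extinction after persistent absence
            if config.extinction_mode == "trend_driven":
                ytot = counts.sum(axis=1)
                zero_run = np.where(live & (ytot == 0), zero_run + 1, 0)
                dying = live & alive & (zero_run >= config.extinction_runs)
                for i in np.nonzero(dying)[0]:
                    gt.extinction_years[aid][sids[i]] = year
                alive[dying] = False
        gt.species_slopes[aid] = {s: float(b) for s, b in zip(sids, slopes)}
        gt.latent[aid] = latent
        gt.expected_sampled_rarity[aid] = exp_rare
    return records, gt


def scenario_series(config: ScenarioConfig) -> tuple[list[AssemblageTimeSeries], GroundTruth]:
    """Like :func:`generate_scenario` but grouped into per-assemblage series."""
    records, gt = generate_scenario(config)
    return from_records(records), gt


# ---------------------------------------------------------------------------
# labelled presence-string fixtures for the persistence classifier
# ---------------------------------------------------------------------------

@dataclass
class LabelledPopulation:
    population: PopulationSeries
    label: str
    gate_limited: bool  # construction cannot reach runs-test significance


def _string_for(label: str, length: int, rng: np.random.Generator) -> str:
    """A presence string whose run structure realizes ``label``.

    Blocks are long and balanced so the runs test is as significant as the
    length allows; short strings may still fall below the gate (flagged by
    the caller).
    """
    if label == "persistent":
        return "1" * length
    half = length // 2
    jit = int(rng.integers(-max(1, length // 8), max(1, length // 8) + 1))
    cut = min(max(2, half + jit), length - 2)
    if label == "immigration":
        return "0" * cut + "1" * (length - cut)
    if label == "extinction":
        return "1" * cut + "0" * (length - cut)
    if label == "multiple":
        q = max(2, length // 4)
        s = ("0" * q + "1" * q) * (length // (2 * q) + 1)
        s = s[:length]
        return s if s[-1] == "1" else s[: length - 1] + "1"
    raise ValueError(f"unknown label {label!r}")


def generate_population_strings(
    n: int,
    event_spec: dict[str, float],
    length: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[LabelledPopulation]:
    """``n`` labelled presence strings drawn from ``event_spec``.

    ``event_spec`` maps labels (persistent / immigration / extinction /
    multiple) to probabilities. Strings whose construction cannot pass the
    runs-test gate at ``alpha`` (short strings) are flagged ``gate_limited``;
    the classifier is expected to call those persistent.
    """
    if length < 4:
        raise ValueError("length must be >= 4")
    labels = sorted(event_spec)
    probs = np.array([event_spec[c] for c in labels], float)
    probs /= probs.sum()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 31)))
    draws = rng.choice(len(labels), size=n, p=probs)
    out = []
    for i, d in enumerate(draws):
        label = labels[d]
        s = _string_for(label, length, rng)
        p = runs_test(s)
        gate_limited = label != "persistent" and (math.isnan(p) or p >= alpha)
        pop = PopulationSeries(
            assemblage_id="SYNTH",
            species_id=f"pop{i:05d}",
            years=list(range(FIRST_YEAR, FIRST_YEAR + length)),
            abundances=[1 if c == "1" else 0 for c in s],
        )
        out.append(LabelledPopulation(pop, label, gate_limited))
    return out
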