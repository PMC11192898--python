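"""Population-fluctuation scenarios and synthetic survey-like datasets.

Four ensemble scenarios probe when the chained geometric-mean index is
and is not biased:

``stationary_arithmetic``
    Each year is an independent Gaussian draw around a stable mean —
    the sampling-error model of an otherwise constant population.
``stationary_log``
    Independent Gaussian draws of log abundance around a stable mean.
``poisson_walk``
    A random walk with +/-Poisson(rate) steps, symmetric on the
    arithmetic scale, with an absorbing boundary at zero.  The ensemble
    mean abundance stays flat while the index declines: increases cannot
    compensate decreases on the log scale.
``log_walk``
    A random walk of log10 abundance — symmetric multiplicative
    fluctuations.  The ensemble mean drifts but the index stays flat.

``two_window_toy`` builds the minimal two-population sampling-error
example (3 -> 5 and 3 -> 1), and ``synth_lpd`` generates heterogeneous
survey-like datasets (ragged windows, irregular sampling, sparse series,
zeros at either end or in the middle) with a truth record for
trend-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import IndexSeries, LpiError, PopulationSeries

SCENARIOS = (
    "stationary_arithmetic",
    "stationary_log",
    "poisson_walk",
    "log_walk",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """One ensemble scenario: 500 populations of 50 individuals over 50 years."""

    scenario: str
    n_populations: int = 500
    n_years: int = 50
    initial_size: float = 50.0
    sd: float = 10.0  # arithmetic-scale gaussian sd
    sd_log: float = 0.2  # log-scale gaussian sd (natural log or log10, per scenario)
    poisson_rate: float = 3.0
    start_year: int = 1970
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise LpiError(f"unknown scenario {self.scenario!r} (choose from {SCENARIOS})")
        if self.n_populations < 1 or self.n_years < 2:
            raise LpiError("need at least 1 population and 2 years")
        if self.initial_size <= 0 or self.poisson_rate <= 0:
            raise LpiError("initial_size and poisson_rate must be positive")


@dataclass
class EnsembleSummary:
    """Per-year community summaries of a simulated ensemble.

    ``equitability`` is proxied by the standard deviation of log10
    abundance among extant (positive) populations; rising values mean a
    widening gap between abundant and rare populations.
    """

    mean_abundance: "pd.Series"
    equitability: "pd.Series"
    index: IndexSeries
    index_slope: float  # least-squares slope of log10 index per year
    abundance_slope: float  # least-squares slope of log10 mean abundance per year


def _series(i: int, years: Sequence[int], values: Sequence[float]) -> PopulationSeries:
    return PopulationSeries(
        population_id=f"sim{i:04d}",
        species=f"sim_species_{i:04d}",
        taxon="birds",
        realm="Palearctic",
        ecosystem="terrestrial",
        observations=dict(zip(years, values)),
    )


def simulate_scenario(config: ScenarioConfig) -> list[PopulationSeries]:
    """Simulate one ensemble; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    n, t = config.n_populations, config.n_years
    years = list(range(config.start_year, config.start_year + t))
    out: list[PopulationSeries] = []

    if config.scenario == "stationary_arithmetic":
        draws = rng.normal(config.initial_size, config.sd, size=(n, t))
        # redraw non-positive values: truncation keeps the distribution stationary
        bad = draws <= 0
        while bad.any():
            draws[bad] = rng.normal(config.initial_size, config.sd, size=int(bad.sum()))
            bad = draws <= 0
        for i in range(n):
            out.append(_series(i, years, draws[i]))
    elif config.scenario == "stationary_log":
        draws = np.exp(
            rng.normal(np.log(config.initial_size), config.sd_log, size=(n, t))
        )
        for i in range(n):
            out.append(_series(i, years, draws[i]))
    elif config.scenario == "log_walk":
        steps = rng.normal(0.0, config.sd_log, size=(n, t - 1))
        log10_n = np.cumsum(
            np.hstack([np.full((n, 1), np.log10(config.initial_size)), steps]), axis=1
        )
        for i in range(n):
            out.append(_series(i, years, 10.0 ** log10_n[i]))
    elif config.scenario == "poisson_walk":
        for i in range(n):
            size = float(round(config.initial_size))
            values = [size]
            for _ in range(t - 1):
                step = rng.poisson(config.poisson_rate) * (1 if rng.random() < 0.5 else -1)
                size = max(0.0, size + step)
                values.append(size)
                if size == 0:  # absorbed: record the zero and truncate
                    break
            out.append(_series(i, years[: len(values)], values))
    return out


def summarize_ensemble(
    populations: Sequence[PopulationSeries], index: IndexSeries
) -> EnsembleSummary:
    """Community mean abundance, equitability proxy and index slope.

    Populations absorbed at zero contribute 0 to the community mean in all
    later years (they are extinct, not missing); the equitability proxy is
    computed over extant populations only.
    """
    if not populations:
        raise LpiError("empty ensemble")
    first = min(p.years[0] for p in populations)
    last = max(p.years[-1] for p in populations)
    years = np.arange(first, last + 1)
    grid = np.zeros((len(populations), len(years)))
    for i, p in enumerate(populations):
        for y, v in p.observations.items():
            grid[i, y - first] = v
        # extinct after an absorbing zero: stays 0 (grid already 0)
    mean_abundance = pd.Series(grid.mean(axis=0), index=years)
    equit = np.full(len(years), np.nan)
    for j in range(len(years)):
        extant = grid[:, j][grid[:, j] > 0]
        equit[j] = np.std(np.log10(extant)) if len(extant) else np.nan
    equitability = pd.Series(equit, index=years)

    def _slope(values: pd.Series) -> float:
        mask = values > 0
        x = values.index.to_numpy(dtype=float)[mask]
        y = np.log10(values.to_numpy()[mask])
        return float(np.polyfit(x, y, 1)[0])

    return EnsembleSummary(
        mean_abundance=mean_abundance,
        equitability=equitability,
        index=index,
        index_slope=_slope(index.values),
        abundance_slope=_slope(mean_abundance),
    )


def two_window_toy(
    same_species: bool = True, start_year: int = 1970
) -> list[PopulationSeries]:
    """The minimal sampling-error example: a stable population of three
    individuals surveyed in two windows, once appearing to grow (3 -> 5)
    and once to shrink (3 -> 1).

    The equal-weight index after one step is 10**((log10(5/3) +
    log10(1/3)) / 2) ~= 0.745: symmetric arithmetic errors read as a
    decline on the log scale.
    """
    species = ["toy_species", "toy_species"] if same_species else ["toy_sp_a", "toy_sp_b"]
    return [
        PopulationSeries(
            population_id="toy_up",
            species=species[0],
            taxon="birds",
            realm="Palearctic",
            ecosystem="terrestrial",
            observations={start_year: 3.0, start_year + 1: 5.0},
        ),
        PopulationSeries(
            population_id="toy_down",
            species=species[1],
            taxon="birds",
            realm="Palearctic",
            ecosystem="terrestrial",
            observations={start_year: 3.0, start_year + 1: 1.0},
        ),
    ]


@dataclass(frozen=True)
class SynthCell:
    """How many species and populations to generate in one taxon-realm cell."""

    ecosystem: str
    realm: str
    taxon: str
    n_species: int = 3
    populations_per_species: int = 2


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a heterogeneous survey-like dataset.

    Per-population log10 trends are drawn Normal(trend_mean, trend_sd);
    observation noise is lognormal.  ``p_two_record`` series keep only
    their first and last observation; other series drop interior years
    independently with ``p_missing``.  Zeros are planted at the start,
    middle or end of a series with the given probabilities.
    """

    cells: tuple[SynthCell, ...]
    year_start: int = 1970
    year_end: int = 2019
    initial_size: float = 100.0
    trend_mean: float = 0.0
    trend_sd: float = 0.02  # log10 units per year
    noise_sd: float = 0.05  # log10 units
    p_two_record: float = 0.2
    p_missing: float = 0.2
    p_zero_start: float = 0.05
    p_zero_middle: float = 0.05
    p_zero_end: float = 0.05
    min_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        if not self.cells:
            raise LpiError("synthetic spec needs at least one cell")
        if self.year_end - self.year_start + 1 < self.min_window:
            raise LpiError("year range shorter than the minimum window")


def synth_lpd(spec: SynthSpec, grouping=None) -> tuple[list[PopulationSeries], dict[str, float]]:
    """Generate a synthetic dataset plus a truth record of generating trends.

    Returns the population list and a map population_id -> log10 trend per
    year, for trend-recovery tests.  Cell labels are validated against the
    grouping when one is supplied.
    """
    rng = np.random.default_rng(spec.seed)
    populations: list[PopulationSeries] = []
    truth: dict[str, float] = {}
    n_years = spec.year_end - spec.year_start + 1
    counter = 0
    for cell in spec.cells:
        for s in range(cell.n_species):
            species = f"{cell.taxon}_{cell.realm}_sp{s:03d}".replace(" ", "_")
            for _p in range(cell.populations_per_species):
                pid = f"syn{counter:05d}"
                counter += 1
                window = int(rng.integers(spec.min_window, n_years + 1))
                offset = int(rng.integers(0, n_years - window + 1))
                years = np.arange(
                    spec.year_start + offset, spec.year_start + offset + window
                )
                trend = float(rng.normal(spec.trend_mean, spec.trend_sd))
                t = np.arange(window, dtype=float)
                values = spec.initial_size * 10.0 ** (
                    trend * t + rng.normal(0.0, spec.noise_sd, size=window)
                )
                if rng.random() < spec.p_two_record:
                    keep = np.zeros(window, dtype=bool)
                    keep[[0, -1]] = True
                else:
                    keep = rng.random(window) >= spec.p_missing
                    keep[[0, -1]] = True
                years, values = years[keep], values[keep]
                if rng.random() < spec.p_zero_start:
                    values[0] = 0.0
                if len(values) > 2 and rng.random() < spec.p_zero_middle:
                    values[int(rng.integers(1, len(values) - 1))] = 0.0
                if rng.random() < spec.p_zero_end:
                    values[-1] = 0.0
                series = PopulationSeries(
                    population_id=pid,
                    species=species,
                    taxon=cell.taxon,
                    realm=cell.realm,
                    ecosystem=cell.ecosystem,
                    observations=dict(zip((int(y) for y in years), values)),
                )
                if grouping is not None:
                    grouping.validate_series(series)
                populations.append(series)
                truth[pid] = trend
    return populations, truth
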