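"""Core data model for the Living Planet Index (LPI) pipeline.

The LPI aggregates vertebrate population time series hierarchically:
populations are averaged into species, species into taxa, taxa into
biogeographical realms (weighted by species richness), realms into
ecosystems, and ecosystems into the global index.  The types here carry
a population's raw observations, the grouping scheme that defines the
hierarchy, the richness weights, and the adjustable knobs of the
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

ECOSYSTEMS = ("terrestrial", "freshwater", "marine")

ZERO_POLICIES = ("replace_one_percent", "remove_and_split")


class LpiError(ValueError):
    """Raised on invalid inputs (negative abundances, unknown labels...)."""


@dataclass(frozen=True)
class PopulationSeries:
    """One population's abundance record plus its taxonomy/geography labels.

    ``observations`` maps calendar year to a non-negative abundance (or any
    abundance proxy: counts, densities, biomass).  Years may be irregular
    and non-contiguous; at least one observation is required.
    """

    population_id: str
    species: str
    taxon: str
    realm: str
    ecosystem: str
    observations: Mapping[int, float]

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise LpiError(f"population {self.population_id!r}: no observations")
        years = list(self.observations)
        if years != sorted(years):
            object.__setattr__(
                self,
                "observations",
                dict(sorted(self.observations.items())),
            )
        for year, value in self.observations.items():
            if not np.isfinite(value) or value < 0:
                raise LpiError(
                    f"population {self.population_id!r}: abundance {value!r} "
                    f"in year {year} is negative or non-finite"
                )
        if self.ecosystem not in ECOSYSTEMS:
            raise LpiError(
                f"population {self.population_id!r}: unknown ecosystem "
                f"{self.ecosystem!r} (expected one of {ECOSYSTEMS})"
            )

    @property
    def years(self) -> list[int]:
        return list(self.observations)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.observations.values()), dtype=float)

    @property
    def n_records(self) -> int:
        """Number of observed (not interpolated) records."""
        return len(self.observations)

    @property
    def span_years(self) -> int:
        """Inclusive span: a 1974-1977 series is 4 years long."""
        years = self.years
        return years[-1] - years[0] + 1

    def with_observations(self, obs: Mapping[int, float], suffix: str = "") -> "PopulationSeries":
        return replace(
            self,
            population_id=self.population_id + suffix,
            observations=dict(obs),
        )


@dataclass(frozen=True)
class GroupingScheme:
    """Realms and taxa recognised per ecosystem, plus label merge rules.

    ``merge`` maps raw labels to merged ones (e.g. Australasia and
    Indo-Malayan into Indo-Pacific, reptiles and amphibians into
    herptiles).  Mapping an already-merged label returns it unchanged.
    """

    name: str
    realms: Mapping[str, tuple[str, ...]]  # ecosystem -> realm labels
    taxa: Mapping[str, tuple[str, ...]]  # ecosystem -> taxon labels
    merge: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "realms", {k: tuple(v) for k, v in self.realms.items()})
        object.__setattr__(self, "taxa", {k: tuple(v) for k, v in self.taxa.items()})
        object.__setattr__(self, "merge", dict(self.merge))

    def canonical(self, label: str) -> str:
        """Apply merge rules; idempotent."""
        return self.merge.get(label, label)

    def valid_realm(self, ecosystem: str, realm: str) -> bool:
        return realm in self.realms.get(ecosystem, ())

    def valid_taxon(self, ecosystem: str, taxon: str) -> bool:
        return taxon in self.taxa.get(ecosystem, ())

    def validate_series(self, series: PopulationSeries) -> None:
        if not self.valid_realm(series.ecosystem, series.realm):
            raise LpiError(
                f"population {series.population_id!r}: realm {series.realm!r} "
                f"not recognised for ecosystem {series.ecosystem!r} under "
                f"grouping {self.name!r}"
            )
        if not self.valid_taxon(series.ecosystem, series.taxon):
            raise LpiError(
                f"population {series.population_id!r}: taxon {series.taxon!r} "
                f"not recognised for ecosystem {series.ecosystem!r} under "
                f"grouping {self.name!r}"
            )


@dataclass(frozen=True)
class WeightTable:
    """Species-richness weights for taxa within realms and realms within ecosystems.

    ``taxon_weights`` maps (realm, taxon) to a weight; within each realm the
    taxon weights sum to 1.  ``realm_weights`` maps (ecosystem, realm) to a
    weight; within each ecosystem the realm weights sum to 1.
    """

    taxon_weights: Mapping[tuple[str, str], float]
    realm_weights: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_weights", dict(self.taxon_weights))
        object.__setattr__(self, "realm_weights", dict(self.realm_weights))

    def validate(self, tol: float = 1e-9) -> None:
        sums: dict[str, float] = {}
        for (realm, _taxon), w in self.taxon_weights.items():
            sums[realm] = sums.get(realm, 0.0) + w
        for realm, total in sums.items():
            if abs(total - 1.0) > tol:
                raise LpiError(f"taxon weights within realm {realm!r} sum to {total}, not 1")
        esums: dict[str, float] = {}
        for (eco, _realm), w in self.realm_weights.items():
            esums[eco] = esums.get(eco, 0.0) + w
        for eco, total in esums.items():
            if abs(total - 1.0) > tol:
                raise LpiError(f"realm weights within ecosystem {eco!r} sum to {total}, not 1")

    @classmethod
    def equal(cls, grouping: GroupingScheme) -> "WeightTable":
        """Equal weights at every level, derived from a grouping scheme.

        Taxon weights are keyed by realm only, so for a realm shared by
        several ecosystems the weight is 1/|union of taxa| over those
        ecosystems; taxa absent from a given ecosystem are dropped and the
        rest renormalised during aggregation.
        """
        taxon_union: dict[str, set[str]] = {}
        realm_w: dict[tuple[str, str], float] = {}
        for eco in grouping.realms:
            realms = grouping.realms[eco]
            for realm in realms:
                realm_w[(eco, realm)] = 1.0 / len(realms)
                taxon_union.setdefault(realm, set()).update(grouping.taxa[eco])
        taxon_w = {
            (realm, taxon): 1.0 / len(taxa)
            for realm, taxa in taxon_union.items()
            for taxon in taxa
        }
        return cls(taxon_w, realm_w)


@dataclass(frozen=True)
class AdjustmentConfig:
    """Adjustable settings of one LPI run.

    ``zero_policy`` selects between the original treatment of zeros (add 1%
    of the non-zero mean to the whole series) and the corrected variant
    (delete zeros and split the series at the gaps).  ``lambda_cap`` clamps
    outlying annual log10 growth rates to [-cap, +cap] when set.
    """

    zero_policy: str = "replace_one_percent"
    min_records: int = 2
    min_span_years: int = 1
    weighted: bool = True
    lambda_cap: Optional[float] = None
    baseline_year: int = 1970
    bootstrap_reps: int = 100
    seed: int = 0
    min_records_for_gam: int = 6
    gam_deviance_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.zero_policy not in ZERO_POLICIES:
            raise LpiError(f"unknown zero policy {self.zero_policy!r}")
        if self.min_records < 2:
            raise LpiError("min_records must be >= 2 (a growth rate needs two values)")
        if self.min_span_years < 1:
            raise LpiError("min_span_years must be >= 1")
        if self.lambda_cap is not None and self.lambda_cap <= 0:
            raise LpiError("lambda_cap must be positive or None")
        if self.bootstrap_reps < 0:
            raise LpiError("bootstrap_reps must be >= 0")


@dataclass(frozen=True)
class ProcessedSeries:
    """Gap-free, strictly positive yearly values for one population.

    Covers every year between the first and last observed year (no
    extrapolation beyond them); produced by the GAM or chain method.
    """

    population_id: str
    method: str  # "gam" or "chain"
    years: np.ndarray  # contiguous calendar years
    values: np.ndarray  # strictly positive
    source: Optional[PopulationSeries] = None

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise LpiError("years and values length mismatch")
        if len(years) and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise LpiError("processed series years must be contiguous")
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            raise LpiError(
                f"processed series {self.population_id!r} has non-positive "
                "or non-finite values"
            )


@dataclass
class LambdaSet:
    """Per-year log10 growth rates for one entity at one hierarchy level.

    ``counts`` is the number of direct children contributing per year (the
    n/d/c/f/h of the nested geometric-mean chain); ``population_counts`` is
    the total number of leaf populations underneath per year.
    """

    level: str  # population|species|taxon|realm|ecosystem|global
    entity_id: str
    lambdas: "pd.Series"  # year -> log10 growth
    counts: "pd.Series"  # year -> direct children contributing
    population_counts: Optional["pd.Series"] = None

    def __post_init__(self) -> None:
        self.lambdas = pd.Series(self.lambdas, dtype=float).sort_index()
        self.lambdas.index = self.lambdas.index.astype(int)
        self.counts = pd.Series(self.counts, dtype=int).reindex(self.lambdas.index)
        if self.population_counts is None:
            self.population_counts = self.counts.copy()
        else:
            self.population_counts = pd.Series(self.population_counts, dtype=int).reindex(
                self.lambdas.index
            )
        if not np.all(np.isfinite(self.lambdas.to_numpy())):
            raise LpiError(f"non-finite lambda in {self.level} {self.entity_id!r}")


@dataclass
class IndexSeries:
    """A chained index trajectory with optional bootstrap confidence bounds.

    The index equals 1 in the baseline year and is multiplied by
    10**lambda for every subsequent year.
    """

    baseline_year: int
    values: "pd.Series"  # year -> index, includes baseline
    ci_low: Optional["pd.Series"] = None
    ci_high: Optional["pd.Series"] = None
    n_populations: Optional["pd.Series"] = None
    carried_forward: tuple[int, ...] = ()  # years with no data, index held flat

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float).sort_index()
        self.values.index = self.values.index.astype(int)
        if self.baseline_year not in self.values.index:
            raise LpiError("baseline year missing from index values")
        if abs(self.values.loc[self.baseline_year] - 1.0) > 1e-12:
            raise LpiError("index at the baseline year must equal 1")

    @property
    def final_value(self) -> float:
        return float(self.values.iloc[-1])

    @property
    def final_year(self) -> int:
        return int(self.values.index[-1])


@dataclass(frozen=True)
class ZeroPolicyReport:
    """Audit record of what a zero policy did to one series."""

    series_id: str
    policy: str
    constant_added: Optional[float]
    fragments: int
    records_dropped: int

    def __post_init__(self) -> None:
        if self.policy == "replace_one_percent" and self.fragments > 1:
            raise LpiError("replace policy cannot split a series")
        if self.policy == "remove_and_split" and self.constant_added is not None:
            raise LpiError("remove_and_split adds no constant")
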