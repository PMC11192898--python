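"""Diagnostics: single-population representatives, leave-out runs,
adjustment grids and grouping comparisons.

A taxon within a realm represented by a single population in some years
gives that one population the full leverage of its taxon in the weighted
realm mean; these analyses find such cases, quantify their effect by
recomputing the index without them, and tabulate how the final index
value responds to the calculation's adjustable settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .groupings import MERGED_5REALM
from .index_core import (
    build_hierarchy,
    chain_index,
    compute_lpi,
    prepare_population_lambdas,
)
from .model import (
    AdjustmentConfig,
    GroupingScheme,
    IndexSeries,
    LpiError,
    PopulationSeries,
    WeightTable,
)


@dataclass(frozen=True)
class RepresentativeRow:
    """A maximal year run in which few populations carry a whole taxon-realm."""

    ecosystem: str
    realm: str
    taxon: str
    year_start: int
    year_end: int
    population_ids: tuple[str, ...]
    species: tuple[str, ...]

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)


def find_single_representatives(
    populations: Sequence[PopulationSeries],
    grouping: GroupingScheme = MERGED_5REALM,
    config: Optional[AdjustmentConfig] = None,
    max_count: int = 1,
) -> list[RepresentativeRow]:
    """Find taxon-realm cells carried by at most ``max_count`` populations.

    Contribution is counted after preprocessing and smoothing — i.e. on
    the growth rates that actually enter the hierarchical mean — and
    maximal consecutive-year runs with the same small contributor set are
    reported.
    """
    config = config or AdjustmentConfig()
    pop_lambdas = prepare_population_lambdas(populations, config, grouping)
    cells: dict[tuple, dict[int, list]] = {}
    for meta, lam in pop_lambdas:
        key = (meta.ecosystem, meta.realm, meta.taxon)
        per_year = cells.setdefault(key, {})
        for year in lam.lambdas.index:
            per_year.setdefault(int(year), []).append(meta)
    rows: list[RepresentativeRow] = []
    for key in sorted(cells):
        per_year = cells[key]
        run: list[int] = []
        run_set: Optional[tuple] = None

        def _flush() -> None:
            if run:
                metas = per_year[run[0]]
                rows.append(
                    RepresentativeRow(
                        ecosystem=key[0],
                        realm=key[1],
                        taxon=key[2],
                        year_start=run[0],
                        year_end=run[-1],
                        population_ids=tuple(m.population_id for m in metas),
                        species=tuple(m.species for m in metas),
                    )
                )

        for year in sorted(per_year):
            metas = per_year[year]
            ids = tuple(sorted(m.population_id for m in metas))
            if len(metas) <= max_count:
                if run and (year != run[-1] + 1 or ids != run_set):
                    _flush()
                    run = []
                run.append(year)
                run_set = ids
            else:
                _flush()
                run = []
                run_set = None
        _flush()
    return rows


@dataclass
class LeaveOutResult:
    """Index with and without a target, plus the divergence between them."""

    with_target: IndexSeries
    without_target: Optional[IndexSeries]
    removed_ids: tuple[str, ...]
    final_difference: Optional[float]  # without - with
    final_ratio: Optional[float]  # without / with
    per_year_difference: Optional["pd.Series"]
    error: Optional[str] = None


def leave_out(
    populations: Sequence[PopulationSeries],
    target: Union[str, RepresentativeRow, Iterable[str]],
    config: Optional[AdjustmentConfig] = None,
    grouping: GroupingScheme = MERGED_5REALM,
    weights: Optional[WeightTable] = None,
    scope: str = "global",
    bootstrap: bool = False,
) -> LeaveOutResult:
    """Recompute the index without the target population(s).

    ``target`` may be a population id, an iterable of ids, or a
    :class:`RepresentativeRow`.  A removal that empties a required level
    is reported in the result, not raised.
    """
    config = config or AdjustmentConfig()
    if isinstance(target, RepresentativeRow):
        ids = set(target.population_ids)
    elif isinstance(target, str):
        ids = {target}
    else:
        ids = set(target)
    known = {p.population_id for p in populations}
    missing = ids - known
    if missing:
        raise LpiError(f"target population(s) not in dataset: {sorted(missing)}")
    with_index = compute_lpi(
        populations, config, grouping, weights, scope=scope, bootstrap=bootstrap
    )
    remaining = [p for p in populations if p.population_id not in ids]
    try:
        without_index = compute_lpi(
            remaining, config, grouping, weights, scope=scope, bootstrap=bootstrap
        )
    except LpiError as exc:
        return LeaveOutResult(
            with_target=with_index,
            without_target=None,
            removed_ids=tuple(sorted(ids)),
            final_difference=None,
            final_ratio=None,
            per_year_difference=None,
            error=str(exc),
        )
    years = with_index.values.index.union(without_index.values.index)
    diff = (
        without_index.values.reindex(years).ffill()
        - with_index.values.reindex(years).ffill()
    )
    return LeaveOutResult(
        with_target=with_index,
        without_target=without_index,
        removed_ids=tuple(sorted(ids)),
        final_difference=float(diff.iloc[-1]),
        final_ratio=float(without_index.final_value / with_index.final_value),
        per_year_difference=diff,
    )


@dataclass
class AdjustmentGrid:
    """Final index values across (configuration, scope) combinations.

    ``differences`` holds adjusted minus baseline per scope: positive
    (green) means the adjusted index declines less than the baseline,
    negative (red) that it declines more.
    """

    final_values: "pd.DataFrame"  # rows: config names, cols: scopes
    differences: "pd.DataFrame"
    baseline: str
    manifest: dict
    errors: dict = dataclasses.field(default_factory=dict)

    def classification(self) -> "pd.DataFrame":
        """'green' where the adjustment lessens the decline, 'red' where it
        deepens it, 'baseline'/blank otherwise."""
        cls = self.differences.map(
            lambda d: "" if pd.isna(d) else ("green" if d > 0 else "red" if d < 0 else "")
        )
        cls.loc[self.baseline] = "baseline"
        return cls

    def to_markdown(self) -> str:
        cells = self.final_values.round(3).astype(str)
        diff = self.differences
        for row in cells.index:
            for col in cells.columns:
                d = diff.loc[row, col]
                if row != self.baseline and pd.notna(d):
                    cells.loc[row, col] += f" ({d:+.3f})"
        return cells.to_markdown()


def adjustment_grid(
    populations: Sequence[PopulationSeries],
    configs: Mapping[str, AdjustmentConfig],
    scopes: Sequence[str] = ("global", "terrestrial", "freshwater", "marine"),
    grouping: GroupingScheme = MERGED_5REALM,
    weights: Optional[WeightTable] = None,
    baseline: Optional[str] = None,
    bootstrap: bool = False,
) -> AdjustmentGrid:
    """Run the full pipeline for every (config, scope) cell.

    The grid reports each cell's final index value and its difference from
    the baseline configuration (the first config, unless named).
    Per-cell failures are recorded in ``errors``; the grid is still
    returned.
    """
    if not configs or not scopes:
        raise LpiError("need at least one config and one scope")
    names = list(configs)
    baseline = baseline or names[0]
    if baseline not in configs:
        raise LpiError(f"baseline config {baseline!r} not among configs")
    finals = pd.DataFrame(np.nan, index=names, columns=list(scopes))
    errors: dict[tuple[str, str], str] = {}
    for name in names:
        for scope in scopes:
            try:
                result = compute_lpi(
                    populations,
                    configs[name],
                    grouping,
                    weights,
                    scope=scope,
                    bootstrap=bootstrap,
                )
                finals.loc[name, scope] = result.final_value
            except LpiError as exc:
                errors[(name, scope)] = str(exc)
    differences = finals.subtract(finals.loc[baseline], axis=1)
    manifest = {name: dataclasses.asdict(cfg) for name, cfg in configs.items()}
    return AdjustmentGrid(
        final_values=finals,
        differences=differences,
        baseline=baseline,
        manifest=manifest,
        errors=errors,
    )


@dataclass
class GroupingComparison:
    """Unweighted indices of the same data under two grouping schemes."""

    index_a: IndexSeries
    index_b: IndexSeries
    grouping_a: str
    grouping_b: str
    final_difference: float  # final(A) - final(B)


def relabel(
    populations: Sequence[PopulationSeries], grouping: GroupingScheme
) -> list[PopulationSeries]:
    """Map series labels through a grouping's merge rules and validate them."""
    out = []
    for p in populations:
        q = replace(p, taxon=grouping.canonical(p.taxon), realm=grouping.canonical(p.realm))
        grouping.validate_series(q)
        out.append(q)
    return out


def compare_groupings(
    populations: Sequence[PopulationSeries],
    grouping_a: GroupingScheme,
    grouping_b: GroupingScheme,
    config: Optional[AdjustmentConfig] = None,
    scope: str = "global",
) -> GroupingComparison:
    """Unweighted index under two groupings plus the final-value difference.

    Comparison is unweighted because richness weights are tied to one
    particular grouping.  Input labels must be mappable under both schemes
    (unmappable labels raise, naming the label).
    """
    config = config or AdjustmentConfig()
    config = replace(config, weighted=False)
    idx_a = compute_lpi(
        relabel(populations, grouping_a), config, grouping_a, scope=scope, bootstrap=False
    )
    idx_b = compute_lpi(
        relabel(populations, grouping_b), config, grouping_b, scope=scope, bootstrap=False
    )
    return GroupingComparison(
        index_a=idx_a,
        index_b=idx_b,
        grouping_a=grouping_a.name,
        grouping_b=grouping_b.name,
        final_difference=float(idx_a.final_value - idx_b.final_value),
    )
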