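"""Annual growth rates and the hierarchical, weighted, chained index.

The pipeline computes, for every population, the annual log10 growth rate

    lambda(y) = log10( N(y) / N(y-1) )

on the gap-free smoothed values, then averages lambdas arithmetically up
the hierarchy population -> species -> taxon -> realm -> ecosystem ->
global.  The arithmetic mean of logs equals the log of the geometric
mean, so the chained index

    I(y) = I(y-1) * 10 ** lambda(y),   I(baseline) = 1

is a product of nested geometric means of population growth ratios.
Taxon-within-realm and realm-within-ecosystem means may be weighted by
species-richness shares; ecosystems always enter the global mean in equal
thirds.  Confidence intervals come from bootstrap resampling of species
within each taxon.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AdjustmentConfig,
    GroupingScheme,
    IndexSeries,
    LambdaSet,
    LpiError,
    PopulationSeries,
    ProcessedSeries,
    WeightTable,
)
from .preprocess import apply_zero_policy_all, filter_by_records, filter_by_span
from .smoothing import smooth_series

log = logging.getLogger("lpicalc")

#: a labeled population-level lambda set: (series metadata, lambdas)
PopulationLambdas = tuple[PopulationSeries, LambdaSet]


def compute_lambdas(proc: ProcessedSeries, cap: Optional[float] = None) -> LambdaSet:
    """Annual log10 growth rates of one processed series.

    The rate for the pair (y-1, y) is assigned to the later year ``y``.
    With ``cap`` set, rates are clamped (not discarded) to [-cap, +cap].
    """
    values = proc.values
    if np.any(values <= 0):
        raise LpiError(f"series {proc.population_id!r}: non-positive processed value")
    lam = np.diff(np.log10(values))
    if cap is not None:
        lam = np.clip(lam, -cap, cap)
    years = proc.years[1:]
    return LambdaSet(
        level="population",
        entity_id=proc.population_id,
        lambdas=pd.Series(lam, index=years),
        counts=pd.Series(1, index=years),
    )


def aggregate(
    children: Sequence[LambdaSet],
    weights: Optional[dict[str, float]] = None,
    level: str = "parent",
    entity_id: str = "",
) -> LambdaSet:
    """(Weighted) arithmetic mean of child lambdas, year by year.

    Only children with a lambda in a given year contribute; when weights
    are supplied the weights of absent children are dropped and the rest
    renormalised to 1 for that year.  Duplicate child ids (bootstrap
    resamples) are kept as distinct contributors.
    """
    if not children:
        raise LpiError("aggregate called with no children")
    if len(children) == 1:
        only = children[0]
        return LambdaSet(
            level=level,
            entity_id=entity_id,
            lambdas=only.lambdas.copy(),
            counts=pd.Series(1, index=only.lambdas.index),
            population_counts=only.population_counts.copy(),
        )
    lam = pd.DataFrame(
        {i: c.lambdas for i, c in enumerate(children)}
    )
    mask = lam.notna()
    if weights is not None:
        w = np.array([weights[c.entity_id] for c in children], dtype=float)
        wmat = mask.to_numpy(dtype=float) * w
        wsum = wmat.sum(axis=1)
        valid = wsum > 0
        values = (np.nan_to_num(lam.to_numpy()) * wmat).sum(axis=1)[valid] / wsum[valid]
    else:
        valid = mask.to_numpy().any(axis=1)
        values = np.nanmean(lam.to_numpy()[valid], axis=1)
    years = lam.index[valid]
    counts = mask.sum(axis=1)[valid]
    pop = pd.DataFrame({i: c.population_counts for i, c in enumerate(children)})
    pop_counts = pop.fillna(0).sum(axis=1).astype(int).reindex(years)
    return LambdaSet(
        level=level,
        entity_id=entity_id,
        lambdas=pd.Series(values, index=years),
        counts=counts,
        population_counts=pop_counts,
    )


def build_hierarchy(
    populations: Sequence[PopulationLambdas],
    grouping: GroupingScheme,
    weights: Optional[WeightTable] = None,
    weighted: bool = True,
    scope: str = "global",
    return_levels: bool = False,
):
    """Average population lambdas up the full hierarchy.

    Populations are averaged within species (a species occurring in two
    realms counts as two independent species-within-realm units), species
    within taxon, taxa within realm (richness-weighted when ``weighted``),
    realms within ecosystem (likewise), and — for global scope —
    ecosystems in equal thirds.  ``scope`` is ``"global"`` or an ecosystem
    name, in which case that ecosystem's lambda set is the top level.
    """
    if weighted and weights is None:
        weights = WeightTable.equal(grouping)
    if scope != "global":
        populations = [p for p in populations if p[0].ecosystem == scope]
    if not populations:
        raise LpiError(f"no populations in scope {scope!r}")
    for meta, _ in populations:
        grouping.validate_series(meta)

    levels: dict[str, list[LambdaSet]] = {}

    # population -> species (within realm), unweighted
    by_species: dict[tuple, list[LambdaSet]] = {}
    for meta, lam in populations:
        key = (meta.ecosystem, meta.realm, meta.taxon, meta.species)
        by_species.setdefault(key, []).append(lam)
    species_sets = {
        key: aggregate(kids, level="species", entity_id="|".join(key))
        for key, kids in by_species.items()
    }
    levels["species"] = list(species_sets.values())

    # species -> taxon, unweighted
    by_taxon: dict[tuple, list[LambdaSet]] = {}
    for key, lam in species_sets.items():
        by_taxon.setdefault(key[:3], []).append(lam)
    taxon_sets = {
        key: aggregate(kids, level="taxon", entity_id=key[2])
        for key, kids in by_taxon.items()
    }
    levels["taxon"] = list(taxon_sets.values())

    # taxon -> realm, richness-weighted when requested
    by_realm: dict[tuple, list[LambdaSet]] = {}
    for key, lam in taxon_sets.items():
        by_realm.setdefault(key[:2], []).append(lam)
    realm_sets = {}
    for (eco, realm), kids in by_realm.items():
        w = None
        if weighted:
            w = {k.entity_id: weights.taxon_weights[(realm, k.entity_id)] for k in kids}
        realm_sets[(eco, realm)] = aggregate(
            kids, weights=w, level="realm", entity_id=realm
        )
    levels["realm"] = list(realm_sets.values())

    # realm -> ecosystem
    by_eco: dict[str, list[LambdaSet]] = {}
    for (eco, _realm), lam in realm_sets.items():
        by_eco.setdefault(eco, []).append(lam)
    eco_sets = {}
    for eco, kids in by_eco.items():
        w = None
        if weighted:
            w = {k.entity_id: weights.realm_weights[(eco, k.entity_id)] for k in kids}
        eco_sets[eco] = aggregate(kids, weights=w, level="ecosystem", entity_id=eco)
    levels["ecosystem"] = list(eco_sets.values())

    if scope != "global":
        top = eco_sets[scope]
    else:
        # ecosystems enter in equal thirds (equal weights among those present)
        top = aggregate(list(eco_sets.values()), level="global", entity_id="global")
    if return_levels:
        return top, levels
    return top


def chain_index(top: LambdaSet, baseline_year: int) -> IndexSeries:
    """Chain a lambda set into an index with the baseline year set to 1.

    Years inside the covered range with no lambda anywhere carry the index
    forward unchanged (lambda treated as 0) and are flagged in
    ``carried_forward``.
    """
    lam = top.lambdas[top.lambdas.index > baseline_year]
    if len(top.lambdas) and len(lam) < len(top.lambdas):
        log.warning(
            "dropping %d lambda years at or before the baseline %d",
            len(top.lambdas) - len(lam),
            baseline_year,
        )
    if len(lam) == 0:
        values = pd.Series([1.0], index=[baseline_year])
        return IndexSeries(baseline_year, values, n_populations=pd.Series([0], index=[baseline_year]))
    years = np.arange(baseline_year, int(lam.index.max()) + 1)
    full = lam.reindex(years[1:])
    carried = tuple(int(y) for y in full.index[full.isna()])
    if carried:
        log.warning("no data in years %s; index carried forward", carried)
    lam_filled = full.fillna(0.0).to_numpy()
    index = np.concatenate([[1.0], 10.0 ** np.cumsum(lam_filled)])
    npop = top.population_counts.reindex(years).fillna(0).astype(int)
    if len(lam):
        npop.loc[baseline_year] = int(top.population_counts.iloc[0])
    return IndexSeries(
        baseline_year,
        pd.Series(index, index=years),
        n_populations=npop,
        carried_forward=carried,
    )


def prepare_population_lambdas(
    populations: Iterable[PopulationSeries],
    config: AdjustmentConfig,
    grouping: GroupingScheme,
) -> list[PopulationLambdas]:
    """Preprocess, smooth and differentiate raw series into labeled lambda sets."""
    for series in populations:
        grouping.validate_series(series)
    survivors, _reports = apply_zero_policy_all(populations, config.zero_policy)
    survivors = filter_by_records(survivors, config.min_records)
    survivors = filter_by_span(survivors, config.min_span_years)
    out: list[PopulationLambdas] = []
    for series in survivors:
        proc = smooth_series(
            series,
            min_records_for_gam=config.min_records_for_gam,
            deviance_threshold=config.gam_deviance_threshold,
        )
        out.append((series, compute_lambdas(proc, cap=config.lambda_cap)))
    return out


def _resample_species(
    populations: Sequence[PopulationLambdas], rng: np.random.Generator
) -> list[PopulationLambdas]:
    """Resample species (with all their populations) within every taxon cell."""
    cells: dict[tuple, dict[str, list[PopulationLambdas]]] = {}
    for meta, lam in populations:
        cell = (meta.ecosystem, meta.realm, meta.taxon)
        cells.setdefault(cell, {}).setdefault(meta.species, []).append((meta, lam))
    out: list[PopulationLambdas] = []
    for cell, species_map in sorted(cells.items()):
        names = sorted(species_map)
        draws = rng.integers(0, len(names), size=len(names))
        for j, idx in enumerate(draws):
            for meta, lam in species_map[names[idx]]:
                # distinct species label per draw so duplicates count twice
                meta2 = PopulationSeries(
                    population_id=f"{meta.population_id}~b{j}",
                    species=f"{meta.species}~b{j}",
                    taxon=meta.taxon,
                    realm=meta.realm,
                    ecosystem=meta.ecosystem,
                    observations=meta.observations,
                )
                out.append((meta2, lam))
    return out


def bootstrap_ci(
    populations: Sequence[PopulationLambdas],
    grouping: GroupingScheme,
    weights: Optional[WeightTable],
    config: AdjustmentConfig,
    scope: str = "global",
    central: Optional[IndexSeries] = None,
) -> IndexSeries:
    """Percentile bootstrap confidence intervals of the chained index.

    Each replicate resamples species (keeping each species' populations
    together) within every taxon with replacement, rebuilds the hierarchy
    and re-chains the index; the interval is the 2.5/97.5 percentile per
    year.  Deterministic under a fixed config seed.
    """
    if central is None:
        top = build_hierarchy(populations, grouping, weights, config.weighted, scope)
        central = chain_index(top, config.baseline_year)
    if scope != "global":
        populations = [p for p in populations if p[0].ecosystem == scope]
    rng = np.random.default_rng(config.seed)
    years = central.values.index
    reps = np.empty((config.bootstrap_reps, len(years)))
    was_disabled = log.disabled
    log.disabled = True  # replicates repeat the central run's coverage warnings
    try:
        for r in range(config.bootstrap_reps):
            sample = _resample_species(populations, rng)
            top_r = build_hierarchy(sample, grouping, weights, config.weighted, scope)
            idx_r = chain_index(top_r, config.baseline_year)
            reps[r] = idx_r.values.reindex(years).ffill().to_numpy()
    finally:
        log.disabled = was_disabled
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return IndexSeries(
        baseline_year=central.baseline_year,
        values=central.values,
        ci_low=pd.Series(lo, index=years),
        ci_high=pd.Series(hi, index=years),
        n_populations=central.n_populations,
        carried_forward=central.carried_forward,
    )


def compute_lpi(
    populations: Iterable[PopulationSeries],
    config: Optional[AdjustmentConfig] = None,
    grouping: Optional[GroupingScheme] = None,
    weights: Optional[WeightTable] = None,
    scope: str = "global",
    bootstrap: Optional[bool] = None,
) -> IndexSeries:
    """Full pipeline: zero policy, filters, smoothing, lambdas, hierarchy, chaining.

    ``bootstrap`` defaults to running confidence intervals whenever
    ``config.bootstrap_reps > 0``; pass ``False`` to skip them.
    """
    from .groupings import MERGED_5REALM

    config = config or AdjustmentConfig()
    grouping = grouping or MERGED_5REALM
    pop_lambdas = prepare_population_lambdas(list(populations), config, grouping)
    if not pop_lambdas:
        raise LpiError("no series survived preprocessing")
    top = build_hierarchy(pop_lambdas, grouping, weights, config.weighted, scope)
    central = chain_index(top, config.baseline_year)
    run_boot = config.bootstrap_reps > 0 if bootstrap is None else bootstrap
    if run_boot and config.bootstrap_reps > 0:
        return bootstrap_ci(
            pop_lambdas, grouping, weights, config, scope=scope, central=central
        )
    return central
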