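"""Reading and writing the wide population-series CSV, weights and results.

The wide dialect mirrors the Living Planet Database export format: one row
per population with metadata columns (``population_id``, ``species``,
``taxon``, ``ecosystem``, ``realm``) followed by one column per calendar
year.  Empty cells and the tokens ``NULL`` and ``NA`` mark missing years;
any other non-numeric cell is an error (fail loud over silent coercion).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .model import GroupingScheme, IndexSeries, LpiError, PopulationSeries, WeightTable

log = logging.getLogger("lpicalc")

META_COLUMNS = ("population_id", "species", "taxon", "ecosystem", "realm")
MISSING_TOKENS = ("", "NULL", "NA")


def read_lpd_wide(
    path: Union[str, Path], grouping: GroupingScheme
) -> list[PopulationSeries]:
    """Read a wide-format population CSV into ``PopulationSeries`` records.

    Raw realm/taxon labels are mapped through the grouping's merge rules
    (e.g. ``reptiles`` -> ``herptiles``).  Rows with no observed years are
    skipped with a warning; negative abundances and labels unknown to the
    grouping are hard errors naming the offending cell.
    """
    frame = pd.read_csv(
        path, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    missing_meta = [c for c in META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise LpiError(f"{path}: missing metadata columns {missing_meta}")
    year_cols = [c for c in frame.columns if c not in META_COLUMNS]
    bad = [c for c in year_cols if not (c.isdigit() and len(c) == 4)]
    if bad:
        raise LpiError(f"{path}: non-year data columns {bad}")
    years = [int(c) for c in year_cols]

    out: list[PopulationSeries] = []
    for _, row in frame.iterrows():
        pid = row["population_id"]
        obs: dict[int, float] = {}
        for col, year in zip(year_cols, years):
            cell = row[col].strip()
            if cell in MISSING_TOKENS:
                continue
            try:
                value = float(cell)
            except ValueError:
                raise LpiError(
                    f"{path}: population {pid!r}, year {year}: "
                    f"cannot parse abundance {cell!r}"
                ) from None
            if value < 0:
                raise LpiError(
                    f"{path}: population {pid!r}, year {year}: "
                    f"negative abundance {value}"
                )
            obs[year] = value
        if not obs:
            warnings.warn(
                f"{path}: population {pid!r} has no observations; skipped",
                stacklevel=2,
            )
            continue
        series = PopulationSeries(
            population_id=pid,
            species=row["species"],
            taxon=grouping.canonical(row["taxon"]),
            realm=grouping.canonical(row["realm"]),
            ecosystem=row["ecosystem"],
            observations=obs,
        )
        grouping.validate_series(series)
        out.append(series)
    return out


def write_lpd_wide(
    populations: Iterable[PopulationSeries], path: Union[str, Path]
) -> None:
    """Write populations back to the wide CSV dialect (missing years blank)."""
    populations = list(populations)
    if not populations:
        raise LpiError("nothing to write")
    all_years = sorted({y for p in populations for y in p.years})
    rows = []
    for p in populations:
        row: dict[str, object] = {
            "population_id": p.population_id,
            "species": p.species,
            "taxon": p.taxon,
            "ecosystem": p.ecosystem,
            "realm": p.realm,
        }
        for y in all_years:
            row[str(y)] = repr(float(p.observations[y])) if y in p.observations else ""
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(META_COLUMNS) + [str(y) for y in all_years])
    frame.to_csv(path, index=False)


def load_weights(
    path: Optional[Union[str, Path]],
    grouping: GroupingScheme,
    auto_normalize: bool = False,
) -> WeightTable:
    """Load species-richness weights, or return equal weights if no file given.

    The CSV has columns ``ecosystem, realm, taxon, weight``; rows with a
    blank taxon carry realm-within-ecosystem weights, the others
    taxon-within-realm weights.  Weights at each level must sum to 1
    (within 1e-6) unless ``auto_normalize`` is set.
    """
    if path is None:
        return WeightTable.equal(grouping)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    required = {"ecosystem", "realm", "taxon", "weight"}
    if not required.issubset(frame.columns):
        raise LpiError(f"{path}: weights file needs columns {sorted(required)}")

    taxon_w: dict[tuple[str, str], float] = {}
    realm_w: dict[tuple[str, str], float] = {}
    for _, row in frame.iterrows():
        weight = float(row["weight"])
        if weight < 0:
            raise LpiError(f"{path}: negative weight {weight}")
        realm = grouping.canonical(row["realm"].strip())
        taxon = row["taxon"].strip()
        if taxon:
            taxon_w[(realm, grouping.canonical(taxon))] = weight
        else:
            realm_w[(row["ecosystem"].strip(), realm)] = weight

    def _check(groups: dict, keyfn, kind: str) -> dict:
        sums: dict[str, float] = {}
        for key, w in groups.items():
            sums[keyfn(key)] = sums.get(keyfn(key), 0.0) + w
        for level, total in sums.items():
            if abs(total - 1.0) > 1e-6:
                if not auto_normalize:
                    raise LpiError(
                        f"{path}: {kind} weights within {level!r} sum to "
                        f"{total}, not 1 (pass auto_normalize to rescale)"
                    )
        if auto_normalize:
            return {k: w / sums[keyfn(k)] for k, w in groups.items()}
        return groups

    taxon_w = _check(taxon_w, lambda k: k[0], "taxon")
    realm_w = _check(realm_w, lambda k: k[0], "realm")
    table = WeightTable(taxon_w, realm_w)
    return table


def write_index(result: IndexSeries, path: Union[str, Path]) -> None:
    """Write an index trajectory to CSV.

    Columns: ``year, lpi, ci_low, ci_high, n_populations``.  When no
    bootstrap was run the confidence columns repeat the index value.
    """
    if len(result.values) == 0:
        raise LpiError("empty index series")
    years = result.values.index
    lpi = result.values
    lo = result.ci_low if result.ci_low is not None else lpi
    hi = result.ci_high if result.ci_high is not None else lpi
    npop = (
        result.n_populations
        if result.n_populations is not None
        else pd.Series(0, index=years)
    )
    frame = pd.DataFrame(
        {
            "year": years,
            "lpi": lpi.to_numpy(),
            "ci_low": pd.Series(lo).reindex(years).to_numpy(),
            "ci_high": pd.Series(hi).reindex(years).to_numpy(),
            "n_populations": pd.Series(npop).reindex(years).fillna(0).astype(int).to_numpy(),
        }
    )
    frame.to_csv(path, index=False)


def read_index(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    return frame.set_index("year")
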