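"""Zero handling and record/span filtering applied before smoothing.

The annual growth rate log10(N[t+1]/N[t]) is undefined when either year is
zero.  Two policies are offered:

``replace_one_percent``
    The original treatment: if a series contains a zero anywhere, add a
    constant equal to 1% of the mean of its non-zero values to every
    observation.  All-zero series are removed.

``remove_and_split``
    The corrected variant: delete the zero observations and split the
    series at the deleted positions into independent fragments; fragments
    left with fewer than two records are discarded (no growth rate can be
    formed from a single value).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .model import LpiError, PopulationSeries, ZeroPolicyReport


def apply_zero_policy(
    series: PopulationSeries, policy: str
) -> tuple[list[PopulationSeries], ZeroPolicyReport]:
    """Apply a zero policy to one series.

    Returns the surviving series (possibly none, possibly several
    fragments) and an audit report.  Degenerate outcomes (all-zero series,
    fragments too short) are reported, never raised.
    """
    values = series.values
    if policy == "replace_one_percent":
        if not np.any(values == 0):
            return [series], ZeroPolicyReport(series.population_id, policy, None, 1, 0)
        nonzero = values[values > 0]
        if len(nonzero) == 0:
            # all-zero series carry no growth information; drop them
            return [], ZeroPolicyReport(series.population_id, policy, None, 0, series.n_records)
        constant = 0.01 * float(nonzero.mean())
        shifted = {y: v + constant for y, v in series.observations.items()}
        return (
            [series.with_observations(shifted)],
            ZeroPolicyReport(series.population_id, policy, constant, 1, 0),
        )

    if policy == "remove_and_split":
        items = list(series.observations.items())
        fragments: list[list[tuple[int, float]]] = [[]]
        dropped = 0
        for year, value in items:
            if value == 0:
                dropped += 1
                if fragments[-1]:
                    fragments.append([])
            else:
                fragments[-1].append((year, value))
        survivors: list[PopulationSeries] = []
        kept = [f for f in fragments if len(f) >= 2]
        for i, frag in enumerate(kept):
            suffix = "" if (len(kept) == 1 and dropped == 0) else f"#z{i + 1}"
            survivors.append(series.with_observations(dict(frag), suffix=suffix))
        dropped += sum(len(f) for f in fragments if 0 < len(f) < 2)
        return survivors, ZeroPolicyReport(
            series.population_id, policy, None, len(survivors), dropped
        )

    raise LpiError(f"unknown zero policy {policy!r}")


def apply_zero_policy_all(
    populations: Iterable[PopulationSeries], policy: str
) -> tuple[list[PopulationSeries], list[ZeroPolicyReport]]:
    out: list[PopulationSeries] = []
    reports: list[ZeroPolicyReport] = []
    for series in populations:
        survivors, report = apply_zero_policy(series, policy)
        out.extend(survivors)
        reports.append(report)
    return out, reports


def filter_by_records(
    populations: Sequence[PopulationSeries], min_records: int
) -> list[PopulationSeries]:
    """Keep series with at least ``min_records`` observed (not interpolated) records."""
    if min_records < 2:
        raise LpiError("min_records must be >= 2")
    return [p for p in populations if p.n_records >= min_records]


def filter_by_span(
    populations: Sequence[PopulationSeries], min_span_years: int
) -> list[PopulationSeries]:
    """Keep series spanning at least ``min_span_years`` calendar years.

    Span is inclusive: records in 1974 and 1977 span 4 years.
    """
    if min_span_years < 1:
        raise LpiError("min_span_years must be >= 1")
    return [p for p in populations if p.span_years >= min_span_years]
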