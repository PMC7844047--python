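"""Locus-level and sample-level polymorphism statistics.

The reference length of each locus is the population median repeat length:
the lower median of the called allele multiset, which is always an element
of the multiset and hence an integer.  A locus is polymorphic when at least
one called allele differs from that median; its polymorphism rate is the
fraction of called alleles that differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genotype_io import CallSet


class NoDataError(ValueError):
    """Raised when a statistic is requested for an all-missing locus."""


@dataclass(frozen=True)
class LocusPopulationSummary:
    locus_id: str
    median_units: int
    min_units: int
    max_units: int
    polymorphic: bool
    polymorphism_rate: float
    call_rate: float
    n_alleles: int


@dataclass(frozen=True)
class SampleSummary:
    sample: str
    fraction_polymorphic_loci: float
    largest_allele: int


def locus_median(alleles: Sequence[int]) -> int:
    """Lower median of an allele multiset (an element of the multiset)."""
    if not alleles:
        raise NoDataError("no called alleles")
    ordered = sorted(alleles)
    return ordered[(len(ordered) - 1) // 2]


def summarize_locus(
    locus_id: str, alleles: Sequence[int], n_expected_alleles: int | None = None
) -> LocusPopulationSummary:
    """Population summary for one locus from its called alleles.

    ``n_expected_alleles`` (2 × samples) sets the call-rate denominator;
    when omitted the call rate is reported as 1.0 over the called alleles.
    """
    med = locus_median(alleles)
    n = len(alleles)
    n_diff = sum(1 for a in alleles if a != med)
    denom = n_expected_alleles if n_expected_alleles else n
    return LocusPopulationSummary(
        locus_id=locus_id,
        median_units=med,
        min_units=min(alleles),
        max_units=max(alleles),
        polymorphic=n_diff > 0,
        polymorphism_rate=n_diff / n,
        call_rate=n / denom,
        n_alleles=n,
    )


def summarize_callset(
    callset: CallSet,
) -> tuple[dict[str, LocusPopulationSummary], list[str]]:
    """Summaries for every locus with data, plus the list of all-missing loci."""
    summaries: dict[str, LocusPopulationSummary] = {}
    no_data: list[str] = []
    n_expected = 2 * len(callset.samples)
    for locus in callset.loci:
        alleles = callset.alleles_at(locus)
        if not alleles:
            no_data.append(locus)
            continue
        summaries[locus] = summarize_locus(locus, alleles, n_expected)
    return summaries, no_data


def summarize_sample(
    sample: str,
    callset: CallSet,
    summaries: Mapping[str, LocusPopulationSummary],
) -> SampleSummary:
    """Fraction of the sample's called loci carrying an allele off the
    population median, and the sample's largest allele."""
    n_called = 0
    n_poly = 0
    largest = 0
    for locus, summary in summaries.items():
        call = callset.get(sample, locus)
        if call.allele_units is None:
            continue
        n_called += 1
        a, b = call.allele_units
        largest = max(largest, b)
        if a != summary.median_units or b != summary.median_units:
            n_poly += 1
    frac = n_poly / n_called if n_called else 0.0
    return SampleSummary(sample=sample, fraction_polymorphic_loci=frac, largest_allele=largest)


def deviation_table(
    callset: CallSet, summaries: Mapping[str, LocusPopulationSummary]
) -> pd.DataFrame:
    """One row per called allele at polymorphic loci; deviation = allele − median."""
    rows = []
    for locus, summary in summaries.items():
        if not summary.polymorphic:
            continue
        for allele in callset.alleles_at(locus):
            rows.append(
                {
                    "locus_id": locus,
                    "median_units": summary.median_units,
                    "allele_units": allele,
                    "deviation": allele - summary.median_units,
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "median_units", "allele_units", "deviation"])


def polymorphic_fraction_by_median(
    summaries: Iterable[LocusPopulationSummary], bin_width: int = 1
) -> dict[int, float]:
    """Fraction of polymorphic loci per median value (``bin_width=1``) or per
    median bin start (larger ``bin_width``)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    totals: dict[int, int] = {}
    poly: dict[int, int] = {}
    for s in summaries:
        key = (s.median_units // bin_width) * bin_width
        totals[key] = totals.get(key, 0) + 1
        poly[key] = poly.get(key, 0) + int(s.polymorphic)
    return {k: poly[k] / totals[k] for k in sorted(totals)}


def write_locus_summaries(
    summaries: Mapping[str, LocusPopulationSummary], path: str | Path
) -> None:
    df = pd.DataFrame([vars(s) for s in summaries.values()])
    df.to_csv(path, sep="\t", index=False)


def write_sample_summaries(samples: Iterable[SampleSummary], path: str | Path) -> None:
    df = pd.DataFrame([vars(s) for s in samples])
    df.to_csv(path, sep="\t", index=False)
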