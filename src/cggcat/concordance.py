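"""Comparison taxonomy for two STR genotypers' call sets.

Each genotype's alleles are sorted ascending and paired by index; every
allele pair is placed in exactly one category by sign, magnitude and
missingness.  The published interpretation of each category (incomplete
trailing units for single-unit offsets, interruption handling and read
compounding for larger ones) is documentation only — the rule itself is
purely numeric.  The consistency metric is the identical plus off-by-one
fraction over allele pairs where genotyper A made a call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genotype_io import CallSet

CATEGORIES = (
    "identical",
    "off_by_one",
    "a_larger",
    "b_larger",
    "b_no_call",
    "a_no_call",
    "both_no_call",
)

#: Categories included in the reported denominator (A made a call).
DENOMINATOR_CATEGORIES = ("identical", "off_by_one", "a_larger", "b_larger", "b_no_call")


@dataclass(frozen=True)
class ConcordanceRecord:
    sample: str
    locus_id: str
    allele_index: int  # 1 or 2 after ascending sort
    units_a: int | None
    units_b: int | None
    category: str


@dataclass
class ConcordanceSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    consistency: float
    n_pairs_denominator: int
    n_shared_samples: int
    n_shared_loci: int
    records: list[ConcordanceRecord] = field(default_factory=list)


def categorize_allele_pair(units_a: int | None, units_b: int | None) -> str:
    """Assign one allele pair to its concordance category."""
    if units_a is not None and units_a < 0 or units_b is not None and units_b < 0:
        raise ValueError("repeat unit counts must be non-negative")
    if units_a is None and units_b is None:
        return "both_no_call"
    if units_a is None:
        return "a_no_call"
    if units_b is None:
        return "b_no_call"
    diff = units_a - units_b
    if diff == 0:
        return "identical"
    if abs(diff) == 1:
        return "off_by_one"
    return "a_larger" if diff > 0 else "b_larger"


def concordance_summary(
    callset_a: CallSet, callset_b: CallSet, keep_records: bool = True
) -> ConcordanceSummary:
    """Categorize every allele pair on the shared sample × locus grid.

    Fractions are reported over allele pairs where A is called (so they sum
    to 1 over that denominator); ``a_no_call`` and ``both_no_call`` counts
    are retained outside it.
    """
    samples = [s for s in callset_a.samples if s in set(callset_b.samples)]
    loci = [l for l in callset_a.loci if l in set(callset_b.loci)]
    if not samples or not loci:
        raise ValueError("no shared samples/loci between the two call sets")
    counts = {c: 0 for c in CATEGORIES}
    records: list[ConcordanceRecord] = []
    for locus in loci:
        for sample in samples:
            ga = callset_a.get(sample, locus).allele_units
            gb = callset_b.get(sample, locus).allele_units
            for idx in (0, 1):
                ua = ga[idx] if ga is not None else None
                ub = gb[idx] if gb is not None else None
                cat = categorize_allele_pair(ua, ub)
                counts[cat] += 1
                if keep_records:
                    records.append(
                        ConcordanceRecord(sample, locus, idx + 1, ua, ub, cat)
                    )
    denom = sum(counts[c] for c in DENOMINATOR_CATEGORIES)
    if denom == 0:
        raise ValueError("genotyper A made no calls on the shared grid")
    fractions = {c: counts[c] / denom for c in DENOMINATOR_CATEGORIES}
    return ConcordanceSummary(
        counts=counts,
        fractions=fractions,
        consistency=fractions["identical"] + fractions["off_by_one"],
        n_pairs_denominator=denom,
        n_shared_samples=len(samples),
        n_shared_loci=len(loci),
        records=records,
    )


def write_records(records: Iterable[ConcordanceRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def write_summary(summary: ConcordanceSummary, path: str | Path) -> None:
    payload = {
        "counts": summary.counts,
        "fractions": summary.fractions,
        "consistency": summary.consistency,
        "n_pairs_denominator": summary.n_pairs_denominator,
        "n_shared_samples": summary.n_shared_samples,
        "n_shared_loci": summary.n_shared_loci,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
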