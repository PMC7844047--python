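"""Reading/writing STR genotype call sets and locus-exclusion rules.

Understands the repeat-count FORMAT dialects of ExpansionHunter (``REPCN``
as ``"a/b"``) and GangSTR (``REPCN`` as ``"a,b"``).  Read-class evidence is
taken from the ``ADSP`` / ``ADIR`` / ``ADFL`` FORMAT fields when present;
when absent it is recorded as unknown and never triggers locus exclusion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam

logger = logging.getLogger(__name__)

_SEP = re.compile(r"[/,|]")


@dataclass(frozen=True)
class GenotypeCall:
    """A per-sample, per-locus diploid repeat-unit genotype.

    ``allele_units`` is either an ascending (a1, a2) pair or ``None`` for a
    missing call.  Evidence counts are ``None`` when the source VCF carried
    no read-class fields.
    """

    sample: str
    locus_id: str
    allele_units: tuple[int, int] | None
    spanning_reads: int | None = None
    inrepeat_reads: int | None = None
    flanking_reads: int | None = None

    def __post_init__(self) -> None:
        if self.allele_units is not None:
            a, b = self.allele_units
            if a < 0 or b < 0:
                raise ValueError("allele units must be non-negative")
            if a > b:
                object.__setattr__(self, "allele_units", (b, a))

    @property
    def is_missing(self) -> bool:
        return self.allele_units is None


@dataclass
class CallSet:
    """All calls of one genotyper over a sample × locus grid."""

    samples: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("CallSet requires at least one sample")

    def get(self, sample: str, locus_id: str) -> GenotypeCall:
        key = (sample, locus_id)
        if key in self.calls:
            return self.calls[key]
        return GenotypeCall(sample=sample, locus_id=locus_id, allele_units=None)

    def alleles_at(self, locus_id: str) -> list[int]:
        """All called allele unit-counts at one locus, across samples."""
        out: list[int] = []
        for s in self.samples:
            call = self.get(s, locus_id)
            if call.allele_units is not None:
                out.extend(call.allele_units)
        return out


def _parse_repcn(value) -> tuple[int, int] | None:
    """Parse a REPCN-style value into an ascending allele pair.

    Accepts "a/b", "a,b", bare "a" (haploid → duplicated), tuples from
    pysam, and "." / None for missing.  Raises ValueError when malformed.
    """
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        parts = [str(v) for v in value if v is not None]
        value = "/".join(parts)
    text = str(value).strip()
    if text in ("", ".", "./.", ".,."):
        return None
    parts = [p for p in _SEP.split(text)]
    if any(p == "." or p == "" for p in parts):
        return None
    nums = [int(p) for p in parts]
    if len(nums) == 1:
        nums = nums * 2
    if len(nums) != 2:
        raise ValueError(f"expected 1 or 2 allele counts, got {text!r}")
    if min(nums) < 0:
        raise ValueError(f"negative repeat count in {text!r}")
    return (min(nums), max(nums))


def _parse_evidence(value) -> int | None:
    """Evidence fields may be a plain integer or an "a/b" per-allele string;
    per-allele values are summed."""
    if value is None:
        return None
    if isinstance(value, int):
        return max(value, 0)
    if isinstance(value, (tuple, list)):
        vals = [v for v in value if v is not None]
        if not vals:
            return None
        return sum(int(v) for v in vals)
    text = str(value).strip()
    if text in ("", "."):
        return None
    return sum(int(p) for p in _SEP.split(text) if p not in ("", "."))


def read_str_vcf(
    vcf_path: str | Path, sample_filter: Iterable[str] | None = None
) -> CallSet:
    """Load a repeat-genotype VCF into a :class:`CallSet`.

    Locus ids come from the VCF ID column when set, else ``<chrom>_<pos>``.
    Malformed REPCN values produce a warning and a missing call.
    """
    wanted = set(sample_filter) if sample_filter is not None else None
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {vcf_path}: {exc}") from exc
    samples = [s for s in vf.header.samples if wanted is None or s in wanted]
    if not samples:
        raise ValueError(f"no samples selected from {vcf_path}")
    loci: list[str] = []
    calls: dict[tuple[str, str], GenotypeCall] = {}
    for rec in vf:
        locus_id = rec.id or f"{rec.chrom}_{rec.pos}"
        loci.append(locus_id)
        for sample in samples:
            fmt = rec.samples[sample]
            try:
                alleles = _parse_repcn(fmt.get("REPCN"))
            except (ValueError, TypeError) as exc:
                logger.warning("malformed REPCN at %s sample %s: %s", locus_id, sample, exc)
                alleles = None
            calls[(sample, locus_id)] = GenotypeCall(
                sample=sample,
                locus_id=locus_id,
                allele_units=alleles,
                spanning_reads=_parse_evidence(fmt.get("ADSP")),
                inrepeat_reads=_parse_evidence(fmt.get("ADIR")),
                flanking_reads=_parse_evidence(fmt.get("ADFL")),
            )
    vf.close()
    return CallSet(samples=samples, loci=loci, calls=calls)


def exclude_uncovered_loci(
    callset: CallSet,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Apply the read-evidence locus-exclusion rules.

    A locus is excluded as ``no_coverage`` when every sample has zero
    spanning and zero in-repeat reads (and evidence is known), and as
    ``flanking_only`` when additionally every sample's only evidence is
    flanking reads.  Unknown evidence keeps the locus.
    """
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for locus in callset.loci:
        evidence = [callset.get(s, locus) for s in callset.samples]
        known = all(
            c.spanning_reads is not None and c.inrepeat_reads is not None
            for c in evidence
        )
        if not known:
            kept.append(locus)
            continue
        no_span_ir = all(
            (c.spanning_reads or 0) == 0 and (c.inrepeat_reads or 0) == 0
            for c in evidence
        )
        if not no_span_ir:
            kept.append(locus)
        elif all((c.flanking_reads or 0) > 0 for c in evidence):
            excluded.append((locus, "flanking_only"))
        else:
            excluded.append((locus, "no_coverage"))
    return kept, excluded


def allele_call_rate(callset: CallSet, loci: Iterable[str] | None = None) -> float:
    """Fraction of genotyped alleles over 2 × samples × loci."""
    loci = list(loci) if loci is not None else callset.loci
    if not loci or not callset.samples:
        raise ValueError("call rate undefined for empty callset")
    called = 0
    for locus in loci:
        for sample in callset.samples:
            if not callset.get(sample, locus).is_missing:
                called += 2
    return called / (2 * len(callset.samples) * len(loci))


def write_call_table(callset: CallSet, path: str | Path) -> None:
    """TSV export: sample, locus, a1, a2 ('.' for missing)."""
    with open(path, "w") as fh:
        fh.write("sample\tlocus_id\ta1\ta2\n")
        for locus in callset.loci:
            for sample in callset.samples:
                call = callset.get(sample, locus)
                if call.is_missing:
                    fh.write(f"{sample}\t{locus}\t.\t.\n")
                else:
                    a, b = call.allele_units  # type: ignore[misc]
                    fh.write(f"{sample}\t{locus}\t{a}\t{b}\n")


def read_call_table(path: str | Path) -> CallSet:
    samples: list[str] = []
    loci: list[str] = []
    calls: dict[tuple[str, str], GenotypeCall] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["sample", "locus_id", "a1", "a2"]:
            raise ValueError(f"unexpected call-table header in {path}")
        for line in fh:
            sample, locus, a1, a2 = line.rstrip("\n").split("\t")[:4]
            if sample not in samples:
                samples.append(sample)
            if locus not in loci:
                loci.append(locus)
            units = None if "." in (a1, a2) else (int(a1), int(a2))
            calls[(sample, locus)] = GenotypeCall(sample, locus, units)
    return CallSet(samples=samples, loci=loci, calls=calls)
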