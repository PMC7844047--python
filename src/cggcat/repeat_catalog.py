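"""Detection, refinement and filtering of CGG-class tandem repeats.

The detector is motif-class restricted: candidate intervals are seeded by
exact frame trinucleotides, merged, scored by wraparound dynamic programming
against a periodic extension of the motif, refined by local alignment against
a pure repeat, and filtered on score, purity and unit count.

Coordinates are 0-based half-open internally.  BED output is 0-based
half-open; the variant-catalog JSON uses 1-based inclusive regions.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidMotifError(ValueError):
    """Raised for motifs containing characters outside ACGT."""


class RefinementFailedError(ValueError):
    """Raised when a region contains no copy of any motif frame."""


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (e.g. duplicate sequence names)."""


@dataclass(frozen=True)
class DetectionParams:
    """Scoring and filtering knobs for the candidate detector.

    ``mismatch_penalty`` and ``indel_penalty`` are positive penalties
    subtracted from the score, so a pure 4-unit trinucleotide repeat scores
    exactly ``min_score`` 24 under the defaults.
    """

    match_score: int = 2
    mismatch_penalty: int = 5
    indel_penalty: int = 17
    max_period: int = 20
    min_score: int = 24
    max_length: int = 1000
    pm: int = 80
    pi: int = 10
    min_units: int = 4

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_penalty < 0 or self.indel_penalty < 0:
            raise ValueError("penalties must be non-negative")
        if self.min_units < 1:
            raise ValueError("min_units must be >= 1")
        if not (0 <= self.pm <= 100 and 0 <= self.pi <= 100):
            raise ValueError("pm/pi must be percentages in [0, 100]")
        if self.max_period < 1:
            raise ValueError("max_period must be >= 1")


@dataclass(frozen=True)
class AlignParams:
    """Local-alignment parameters used by :func:`refine_locus`."""

    align_match: int = 2
    align_mismatch: int = 2
    gap_open: int = 5
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.align_match <= 0:
            raise ValueError("align_match must be positive")
        if min(self.align_mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


@dataclass(frozen=True)
class MotifClass:
    """A motif together with all rotations of itself and its reverse
    complement, i.e. every frame under which the same repeat can be read."""

    base_motif: str
    frames: frozenset[str]

    def __post_init__(self) -> None:
        assert self.base_motif in self.frames

    @property
    def length(self) -> int:
        return len(self.base_motif)


@dataclass(frozen=True)
class RepeatLocus:
    """A catalogued tandem-repeat interval."""

    chrom: str
    start: int
    end: int
    motif: str
    units: float
    interruptions: int
    score: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.interruptions < 0:
            raise ValueError("interruptions must be >= 0")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}_{self.start + 1}"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif_frames(base_motif: str) -> MotifClass:
    """All distinct rotations of ``base_motif`` and of its reverse complement.

    >>> sorted(canonical_motif_frames("CGG").frames)
    ['CCG', 'CGC', 'CGG', 'GCC', 'GCG', 'GGC']
    """
    if not base_motif or any(c not in "ACGT" for c in base_motif):
        raise InvalidMotifError(f"motif must be non-empty uppercase ACGT: {base_motif!r}")
    frames: set[str] = set()
    for m in (base_motif, reverse_complement(base_motif)):
        for i in range(len(m)):
            frames.add(m[i:] + m[:i])
    return MotifClass(base_motif=base_motif, frames=frozenset(frames))


def scan_candidates(
    sequence: str,
    motif_class: MotifClass,
    params: DetectionParams,
    merge_gap: int | None = None,
) -> list[tuple[int, int]]:
    """Seed-and-merge scan for candidate repeat intervals.

    Every position where an exact frame k-mer occurs is a seed; seeds whose
    intervals overlap or lie within ``merge_gap`` bases (default: one motif
    length, so single-base interruptions do not split a run) are merged.
    Merged intervals shorter than ``min_units`` motif copies cannot reach
    ``min_score`` and are dropped; intervals longer than ``max_length`` are
    truncated.
    """
    k = motif_class.length
    n = len(sequence)
    if n < k:
        return []
    if merge_gap is None:
        merge_gap = k
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    hit = np.zeros(n - k + 1, dtype=bool)
    for frame in motif_class.frames:
        m = np.ones(n - k + 1, dtype=bool)
        for off, ch in enumerate(frame):
            m &= arr[off : off + n - k + 1] == ord(ch)
        hit |= m
    pos = np.flatnonzero(hit)
    if pos.size == 0:
        return []
    # split where the gap between consecutive seed intervals exceeds merge_gap
    breaks = np.flatnonzero(np.diff(pos) > k + merge_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))
    out: list[tuple[int, int]] = []
    min_len = params.min_units * k
    for si, ei in zip(starts, ends):
        s, e = int(pos[si]), int(pos[ei]) + k
        if e - s > params.max_length:
            e = s + params.max_length
        if e - s >= min_len:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class AlignmentScore:
    score: int
    matches: int
    mismatches: int
    indels: int


def score_repeat_alignment(
    candidate_seq: str, motif: str, params: DetectionParams
) -> AlignmentScore:
    """Optimal wraparound alignment of a candidate against a periodic motif.

    A ring dynamic program over motif phases: the start and end phase are
    free, every consumed candidate base is a match (+match_score) or mismatch
    (-mismatch_penalty), and every inserted or deleted base costs
    ``indel_penalty``.  ``N`` never matches.  Deterministic: ties prefer
    match/mismatch over insertion over deletion, then the lowest phase.
    """
    if len(motif) > params.max_period:
        raise ValueError(f"motif longer than max_period {params.max_period}")
    m = len(motif)
    n = len(candidate_seq)
    if n == 0:
        return AlignmentScore(0, 0, 0, 0)
    NEG = -(10**9)
    ms, mp, ip = params.match_score, params.mismatch_penalty, params.indel_penalty
    # dp[j] = best score with current prefix consumed, next motif index j
    dp = [0] * m
    # backpointers: bp[i][j] = (op, prev_j); ops: 'M' match, 'X' mismatch,
    # 'I' insertion (candidate base unaligned), 'D' deletion (motif base skipped)
    bps: list[list[tuple[str, int] | None]] = [[None] * m]
    for i in range(1, n + 1):
        c = candidate_seq[i - 1]
        ndp = [NEG] * m
        nbp: list[tuple[str, int] | None] = [None] * m
        for j in range(m):
            pj = (j - 1) % m
            diag = dp[pj] + (ms if c == motif[pj] else -mp)
            ins = dp[j] - ip
            if diag >= ins:
                ndp[j] = diag
                nbp[j] = ("M" if c == motif[pj] else "X", pj)
            else:
                ndp[j] = ins
                nbp[j] = ("I", j)
        # within-column deletion relaxation around the phase ring; two
        # sweeps suffice because all deletion costs are equal
        for _ in range(2):
            for j in range(m):
                pj = (j - 1) % m
                cand = ndp[pj] - ip
                if cand > ndp[j]:
                    ndp[j] = cand
                    nbp[j] = ("D", pj)
        dp = ndp
        bps.append(nbp)
    best_j = max(range(m), key=lambda j: (dp[j], -j))
    score = dp[best_j]
    # traceback to count operations
    i, j = n, best_j
    matches = mismatches = indels = 0
    while i > 0:
        op, pj = bps[i][j]  # type: ignore[misc]
        if op == "M":
            matches += 1
            i -= 1
        elif op == "X":
            mismatches += 1
            i -= 1
        elif op == "I":
            indels += 1
            i -= 1
        else:  # deletion: no candidate base consumed
            indels += 1
        j = pj
    return AlignmentScore(score, matches, mismatches, indels)


@dataclass(frozen=True)
class RefinedSpan:
    offset_start: int
    offset_end: int
    units: float
    interruptions: int
    score: float


def _make_aligner(align_params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = align_params.align_match
    aligner.mismatch_score = -align_params.align_mismatch
    aligner.open_gap_score = -align_params.gap_open
    aligner.extend_gap_score = -align_params.gap_extend
    return aligner


def refine_locus(
    region_seq: str, motif: str, align_params: AlignParams
) -> RefinedSpan:
    """Trim a candidate region to its best local alignment against a pure
    periodic repeat of ``motif`` (reference longer than the region, so the
    repeat is never length-limited).

    Returns offsets into ``region_seq``, units (span / motif length, one
    decimal) and interruptions (mismatched plus inserted positions inside
    the span).  Raises :class:`RefinementFailedError` when no frame of the
    motif class occurs in the region.
    """
    frames = canonical_motif_frames(motif).frames
    if not any(f in region_seq for f in frames):
        raise RefinementFailedError(
            f"no copy of any frame of {motif} in region of length {len(region_seq)}"
        )
    m = len(motif)
    ref = motif * (len(region_seq) // m + 2)
    aligner = _make_aligner(align_params)
    aln = aligner.align(region_seq, ref)[0]
    blocks_t, blocks_q = aln.aligned
    offset_start = int(blocks_t[0][0])
    offset_end = int(blocks_t[-1][1])
    mismatches = 0
    inserted = 0
    prev_t_end: int | None = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            inserted += int(ts) - prev_t_end
        prev_t_end = int(te)
        for a, b in zip(region_seq[ts:te], ref[qs:qe]):
            if a != b:
                mismatches += 1
    span = offset_end - offset_start
    units = round(span / m, 1)
    return RefinedSpan(offset_start, offset_end, units, mismatches + inserted, float(aln.score))


def _passes_purity(aln: AlignmentScore, params: DetectionParams) -> bool:
    aligned = aln.matches + aln.mismatches + aln.indels
    if aligned == 0:
        return False
    return (
        100.0 * aln.matches / aligned >= params.pm
        and 100.0 * aln.indels / aligned <= params.pi
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an uppercase name→sequence
    mapping.  Duplicate names are a format error."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seqs: dict[str, str] = {}
    try:
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in seqs:
                    raise FastaFormatError(f"duplicate sequence name {rec.id!r}")
                seqs[rec.id] = str(rec.seq).upper()
    except OSError as exc:
        raise OSError(f"cannot read FASTA {path}: {exc}") from exc
    return seqs


def build_catalog(
    genome: Mapping[str, str] | str | Path,
    motif_class: MotifClass,
    params: DetectionParams | None = None,
    align_params: AlignParams | None = None,
) -> list[RepeatLocus]:
    """Run the full detection pipeline over a genome.

    scan → wraparound score (drop < min_score, purity filter) → local
    refinement → unit filter → overlap deduplication (higher score, then
    longer, then leftmost), sorted by (chrom, start).
    """
    params = params or DetectionParams()
    align_params = align_params or AlignParams()
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    k = motif_class.length
    loci: list[RepeatLocus] = []
    for chrom in genome:
        seq = genome[chrom]
        for cand_start, cand_end in scan_candidates(seq, motif_class, params):
            cand_seq = seq[cand_start:cand_end]
            motif = cand_seq[:k] if cand_seq[:k] in motif_class.frames else motif_class.base_motif
            first = score_repeat_alignment(cand_seq, motif, params)
            if first.score < params.min_score:
                continue
            try:
                ref = refine_locus(cand_seq, motif, align_params)
            except RefinementFailedError as exc:
                logger.info("dropping candidate %s:%d-%d: %s", chrom, cand_start, cand_end, exc)
                continue
            start = cand_start + ref.offset_start
            end = cand_start + ref.offset_end
            refined_seq = seq[start:end]
            final = score_repeat_alignment(refined_seq, motif, params)
            if final.score < params.min_score:
                continue
            if not _passes_purity(final, params):
                continue
            if int(ref.units) < params.min_units:
                continue
            locus_motif = refined_seq[:k] if refined_seq[:k] in motif_class.frames else motif
            loci.append(
                RepeatLocus(
                    chrom=chrom,
                    start=start,
                    end=end,
                    motif=locus_motif,
                    units=ref.units,
                    interruptions=ref.interruptions,
                    score=final.score,
                )
            )
    return _dedup_overlaps(loci)


def _dedup_overlaps(loci: Sequence[RepeatLocus]) -> list[RepeatLocus]:
    """Among overlapping refined loci keep the best: higher score, then
    longer span, then leftmost."""
    by_chrom: dict[str, list[RepeatLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    kept: list[RepeatLocus] = []
    for chrom in sorted(by_chrom):
        ranked = sorted(
            by_chrom[chrom],
            key=lambda l: (-l.score, -(l.end - l.start), l.start),
        )
        chosen: list[RepeatLocus] = []
        for loc in ranked:
            if all(loc.end <= c.start or loc.start >= c.end for c in chosen):
                chosen.append(loc)
        kept.extend(sorted(chosen, key=lambda l: l.start))
    return sorted(kept, key=lambda l: (l.chrom, l.start))


def write_bed(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    """BED4+ with motif, units, interruptions and score columns."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.motif}"
                f"\t{loc.units}\t{loc.interruptions}\t{loc.score}\n"
            )


def read_bed(path: str | Path) -> list[RepeatLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            loci.append(
                RepeatLocus(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    motif=f[3] if len(f) > 3 else "CGG",
                    units=float(f[4]) if len(f) > 4 else (int(f[2]) - int(f[1])) / 3,
                    interruptions=int(f[5]) if len(f) > 5 else 0,
                    score=int(float(f[6])) if len(f) > 6 else 0,
                )
            )
    return loci


def write_variant_catalog(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    """ExpansionHunter-style variant-catalog JSON (1-based inclusive regions)."""
    entries = [
        {
            "LocusId": loc.locus_id,
            "LocusStructure": f"({loc.motif})*",
            "ReferenceRegion": f"{loc.chrom}:{loc.start + 1}-{loc.end}",
            "VariantType": "Repeat",
        }
        for loc in loci
    ]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
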