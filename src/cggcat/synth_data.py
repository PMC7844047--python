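"""Synthetic genomes, cohorts, genotype VCFs and gene models.

Stand-ins for a reference genome and a sequenced cohort: a background
sequence scrubbed of accidental CGG-class runs with repeats of known
coordinates planted into it, a diploid allele simulator whose per-allele
mutation probability grows linearly with the central repeat length, a
VCF emitter with read-length censoring, and a toy gene-model generator
that realizes every region label.

The allele-length model (linear instability in units, geometric step
sizes) is an explicit stand-in chosen for testability, not a claim about
mutational biology.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_catalog import (
    AlignParams,
    DetectionParams,
    MotifClass,
    build_catalog,
    canonical_motif_frames,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: flanks this wide around every planted locus are drawn from {A, T} so no
#: CGG-class frame (all C/G) can straddle or abut a planted boundary
GUARD_BP = 6


class ConfigurationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class PlantedLocus:
    """A repeat to insert into the synthetic genome.

    ``interruptions`` are base offsets within the repeat span that are
    replaced by ``T`` (an A/T base keeps straddling triplets out of the
    CGG frame class).
    """

    chrom: str
    position: int
    motif: str
    units: int
    interruptions: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.units * len(self.motif)

    @property
    def end(self) -> int:
        return self.position + self.length

    def sequence(self) -> str:
        seq = list(self.motif * self.units)
        for off in self.interruptions:
            if not 0 <= off < len(seq):
                raise ConfigurationError(f"interruption offset {off} outside repeat")
            seq[off] = "T"
        return "".join(seq)


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.5
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    n_samples: int = 50
    instability_floor: float = 0.02
    instability_slope: float = 0.004
    step_geom_p: float = 0.6
    censor_cap: int | str | None = None  # int, "auto" (read_length // 3), or None
    read_length: int = 150
    missing_rate: float = 0.0
    zero_coverage_loci: list[str] = field(default_factory=list)
    flanking_only_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("gc_content", "instability_floor", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.step_geom_p <= 1.0:
            raise ConfigurationError("step_geom_p must be in (0, 1]")
        if self.instability_slope < 0:
            raise ConfigurationError("instability_slope must be >= 0")

    @property
    def effective_censor_cap(self) -> int | None:
        """The soft limit in units: the configured cap, or the number of
        motif copies that fit fully within one read when ``censor_cap`` is
        the string ``"auto"``; ``None`` disables censoring."""
        if self.censor_cap == "auto":
            return self.read_length // 3
        return self.censor_cap

    def mutation_probability(self, central_units: int) -> float:
        return min(1.0, self.instability_floor + self.instability_slope * central_units)


@dataclass(frozen=True)
class TruthRecord:
    """Planted truth for one locus, carried alongside generated artifacts."""

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    units: int
    n_interruptions: int
    central_units: int
    expected_polymorphism_rate: float


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def plant_random_loci(
    rng: np.random.Generator,
    n_loci: int,
    genome_length: int,
    units_range: tuple[int, int] = (4, 60),
    interrupted_fraction: float = 0.3,
    max_interruptions: int = 2,
    min_spacing: int = 50,
    chrom: str = "chr1",
    motif: str = "CGG",
) -> list[PlantedLocus]:
    """Draw non-overlapping planted loci with ≥ ``min_spacing`` bp between
    them.  Interruptions are only planted in repeats of ≥ 8 units, in
    interior units, at least two units apart, so every interrupted repeat
    still clears the default detection score and purity thresholds.
    """
    frames = sorted(canonical_motif_frames(motif).frames)
    lo, hi = units_range
    units = rng.integers(lo, hi + 1, size=n_loci)
    lengths = units * len(motif)
    total = int(lengths.sum()) + (n_loci + 1) * (min_spacing + 2 * GUARD_BP)
    if total > genome_length:
        raise ConfigurationError(
            f"cannot pack {n_loci} loci into {genome_length} bp with spacing {min_spacing}"
        )
    # distribute the slack between loci uniformly
    slack = genome_length - int(lengths.sum()) - 2 * GUARD_BP * n_loci
    gaps = rng.multinomial(slack - (n_loci + 1) * min_spacing, [1 / (n_loci + 1)] * (n_loci + 1))
    gaps = gaps + min_spacing
    loci: list[PlantedLocus] = []
    pos = 0
    for i in range(n_loci):
        pos += int(gaps[i]) + GUARD_BP
        u = int(units[i])
        frame = frames[int(rng.integers(len(frames)))]
        interruptions: tuple[int, ...] = ()
        if u >= 8 and rng.random() < interrupted_fraction:
            k = int(rng.integers(1, max_interruptions + 1))
            # interior units, >= 2 units apart
            candidates = list(range(1, u - 1))
            chosen: list[int] = []
            rng.shuffle(candidates)
            for c in candidates:
                if all(abs(c - x) >= 2 for x in chosen):
                    chosen.append(c)
                if len(chosen) == k:
                    break
            interruptions = tuple(
                sorted(c * len(frame) + int(rng.integers(len(frame))) for c in chosen)
            )
        loci.append(PlantedLocus(chrom, pos, frame, u, interruptions))
        pos += u * len(motif) + GUARD_BP
    return loci


def generate_genome(
    config: SimulationConfig,
    detection_params: DetectionParams | None = None,
    align_params: AlignParams | None = None,
    motif: str = "CGG",
    max_scrub_rounds: int = 25,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Build the synthetic genome and its truth table.

    Background bases are i.i.d. at ``gc_content``; planted repeats are
    inserted verbatim with AT-only guard flanks; then the background is
    rejection-scrubbed until the full detector finds exactly the planted
    loci and nothing else.  Deterministic given ``config.seed``.
    """
    detection_params = detection_params or DetectionParams()
    align_params = align_params or AlignParams()
    rng = np.random.default_rng(config.seed)
    motif_class = canonical_motif_frames(motif)
    chroms = sorted({p.chrom for p in config.planted_loci}) or ["chr1"]
    by_chrom: dict[str, list[PlantedLocus]] = {c: [] for c in chroms}
    for p in config.planted_loci:
        by_chrom[p.chrom].append(p)
    genome: dict[str, str] = {}
    for chrom in chroms:
        planted = sorted(by_chrom[chrom], key=lambda p: p.position)
        _check_packing(planted, config.genome_length)
        arr = _random_background(rng, config.genome_length, config.gc_content)
        protected = np.zeros(config.genome_length, dtype=bool)
        for p in planted:
            seq = np.frombuffer(p.sequence().encode(), dtype=np.uint8)
            arr[p.position : p.end] = seq
            protected[p.position : p.end] = True
            for lo, hi in (
                (p.position - GUARD_BP, p.position),
                (p.end, p.end + GUARD_BP),
            ):
                lo, hi = max(lo, 0), min(hi, config.genome_length)
                arr[lo:hi] = rng.choice(
                    np.frombuffer(b"AT", dtype=np.uint8), size=hi - lo
                )
                protected[lo:hi] = True
        genome[chrom] = _scrub_background(
            arr, protected, planted, motif_class, detection_params, align_params,
            rng, max_scrub_rounds,
        )
    truth = [
        TruthRecord(
            locus_id=f"{p.chrom}_{p.position + 1}",
            chrom=p.chrom,
            start=p.position,
            end=p.end,
            motif=p.motif,
            units=p.units,
            n_interruptions=len(p.interruptions),
            central_units=p.units,
            expected_polymorphism_rate=config.mutation_probability(p.units),
        )
        for p in sorted(config.planted_loci, key=lambda p: (p.chrom, p.position))
    ]
    return genome, truth


def _check_packing(planted: Sequence[PlantedLocus], genome_length: int) -> None:
    prev_end = -10**9
    for p in planted:
        if p.position < GUARD_BP or p.end + GUARD_BP > genome_length:
            raise ConfigurationError(f"locus at {p.position} does not fit in genome")
        if p.position - prev_end < 50:
            raise ConfigurationError("planted loci must be >= 50 bp apart")
        prev_end = p.end


def _scrub_background(
    arr: np.ndarray,
    protected: np.ndarray,
    planted: Sequence[PlantedLocus],
    motif_class: MotifClass,
    detection_params: DetectionParams,
    align_params: AlignParams,
    rng: np.random.Generator,
    max_rounds: int,
) -> str:
    """Re-randomize background bases until the detector reports exactly the
    planted loci."""
    planted_ivs = [(p.position, p.end) for p in planted]
    for _ in range(max_rounds):
        seq = arr.tobytes().decode("ascii")
        found = build_catalog({"scrub": seq}, motif_class, detection_params, align_params)
        spurious = [
            (loc.start, loc.end)
            for loc in found
            if not any(loc.start < e and s < loc.end for s, e in planted_ivs)
        ]
        if not spurious:
            return seq
        for s, e in spurious:
            idx = np.arange(max(s - 3, 0), min(e + 3, arr.size))
            idx = idx[~protected[idx]]
            arr[idx] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=idx.size)
    raise ConfigurationError("background scrubbing did not converge")


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_table(truth: Iterable[TruthRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truth]).to_csv(path, sep="\t", index=False)


def simulate_population(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Draw true diploid allele lengths for every sample × locus.

    Per allele, with probability ``instability_floor + slope × central``
    the allele moves off the central length by a geometric step of random
    sign (truncated below at 1 unit); otherwise it equals the central
    length.  Returns columns sample, locus_id, a1, a2 (unsorted truth).
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    rows = []
    for t in truth:
        p = config.mutation_probability(t.central_units)
        mut = rng.random((config.n_samples, 2)) < p
        steps = rng.geometric(config.step_geom_p, size=(config.n_samples, 2))
        signs = rng.choice([-1, 1], size=(config.n_samples, 2))
        alleles = np.full((config.n_samples, 2), t.central_units, dtype=int)
        alleles = np.where(mut, np.maximum(t.central_units + signs * steps, 1), alleles)
        for i, sample in enumerate(samples):
            rows.append(
                {
                    "sample": sample,
                    "locus_id": t.locus_id,
                    "a1": int(alleles[i, 0]),
                    "a2": int(alleles[i, 1]),
                }
            )
    return pd.DataFrame(rows)


def apply_censoring(true_units: int, cap: int | None) -> int:
    """Soft-limit model: lengths in (cap, 3·cap) are reported at the cap;
    far beyond it, fully in-read repeats make the true length visible again."""
    if cap is not None and cap < true_units < 3 * cap:
        return cap
    return true_units


def emit_vcf(
    allele_table: pd.DataFrame,
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    path: str | Path,
    dialect: str = "eh",
) -> Path:
    """Write a genotyper-style VCF with REPCN genotypes and read evidence.

    ``dialect`` selects the allele separator: ``"eh"`` → ``a/b``,
    ``"gangstr"`` → ``a,b``.  Each allele is independently dropped with
    ``missing_rate``; a call with any dropped allele is written missing.
    Loci named in ``zero_coverage_loci`` / ``flanking_only_loci`` are
    emitted with the corresponding evidence patterns.
    """
    if dialect not in ("eh", "gangstr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "/" if dialect == "eh" else ","
    rng = np.random.default_rng(config.seed + 2)
    samples = list(dict.fromkeys(allele_table["sample"]))
    cap = config.effective_censor_cap
    zero_cov = set(config.zero_coverage_loci)
    flank_only = set(config.flanking_only_loci)
    indexed = allele_table.set_index(["locus_id", "sample"])
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">\n')
        fh.write('##INFO=<ID=REF_UNITS,Number=1,Type=Integer,Description="Reference repeat units">\n')
        fh.write('##FORMAT=<ID=REPCN,Number=1,Type=String,Description="Repeat unit counts">\n')
        fh.write('##FORMAT=<ID=ADSP,Number=1,Type=Integer,Description="Spanning reads">\n')
        fh.write('##FORMAT=<ID=ADIR,Number=1,Type=Integer,Description="In-repeat reads">\n')
        fh.write('##FORMAT=<ID=ADFL,Number=1,Type=Integer,Description="Flanking reads">\n')
        chroms = sorted({t.chrom for t in truth})
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write("\t" + "\t".join(samples) + "\n")
        for t in sorted(truth, key=lambda t: (t.chrom, t.start)):
            cols = [
                t.chrom,
                str(t.start + 1),
                t.locus_id,
                "C",
                ".",
                ".",
                "PASS",
                f"RU={t.motif};REF_UNITS={t.units}",
                "REPCN:ADSP:ADIR:ADFL",
            ]
            for sample in samples:
                a1, a2 = indexed.loc[(t.locus_id, sample), ["a1", "a2"]]
                missing = (
                    config.missing_rate > 0
                    and bool((rng.random(2) < config.missing_rate).any())
                )
                if t.locus_id in zero_cov:
                    ev = "0:0:0"
                elif t.locus_id in flank_only:
                    ev = "0:0:3"
                else:
                    ev = "10:5:2"
                if missing:
                    cols.append(f".:{ev}")
                else:
                    r1 = apply_censoring(int(a1), cap)
                    r2 = apply_censoring(int(a2), cap)
                    lo, hi = sorted((r1, r2))
                    cols.append(f"{lo}{sep}{hi}:{ev}")
            fh.write("\t".join(cols) + "\n")
    return path


def generate_gene_models(
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    gff_path: str | Path,
    panel_path: str | Path | None = None,
    universe_path: str | Path | None = None,
    panel_odds_ratio: float = 1.0,
    panel_base_rate: float = 0.2,
    n_extra_genes: int = 0,
    flank_bp: int = 1000,
) -> dict[str, str]:
    """Place toy genes so every region label is realized by planted loci.

    Labels are assigned round-robin over the 8 categories (loci labelled
    ``intergenic`` get no gene).  Requires planted loci to be ≥ 2·(flank_bp
    + 300) apart so genes built for one locus never come within ``flank_bp``
    of another.  Also writes a gene universe and a panel list whose
    membership odds for repeat-associated genes are multiplied by
    ``panel_odds_ratio``.  Returns the intended locus → label mapping.
    """
    labels = [
        "upstream", "five_utr", "exonic", "intronic",
        "three_utr", "downstream", "intergenic", "ncRNA",
    ]
    ordered = sorted(truth, key=lambda t: (t.chrom, t.start))
    prev_by_chrom: dict[str, int] = {}
    min_gap = 2 * (flank_bp + 300)
    for t in ordered:
        if t.chrom in prev_by_chrom and t.start - prev_by_chrom[t.chrom] < min_gap:
            raise ConfigurationError(
                f"loci too close for gene placement (need >= {min_gap} bp)"
            )
        prev_by_chrom[t.chrom] = t.end
    rng = np.random.default_rng(config.seed + 3)
    intended: dict[str, str] = {}
    genes: list[dict] = []
    for i, t in enumerate(ordered):
        label = labels[i % len(labels)]
        intended[t.locus_id] = label
        if label == "intergenic":
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_place_gene(f"GENE{i:04d}", t, label, strand))
    for j in range(n_extra_genes):
        genes.append({"name": f"BGGENE{j:04d}", "features": None})
    _write_gff3(genes, gff_path)
    universe = [g["name"] for g in genes]
    repeat_assoc = {g["name"] for g in genes if g.get("features") and g.get("target")}
    if universe_path is not None:
        Path(universe_path).write_text("".join(n + "\n" for n in universe))
    if panel_path is not None:
        odds0 = panel_base_rate / (1 - panel_base_rate)
        odds1 = odds0 * panel_odds_ratio
        p1 = odds1 / (1 + odds1)
        panel = [
            n
            for n in universe
            if rng.random() < (p1 if n in repeat_assoc else panel_base_rate)
        ]
        Path(panel_path).write_text("".join(n + "\n" for n in panel))
    return intended


def _place_gene(name: str, t: TruthRecord, label: str, strand: str) -> dict:
    """Construct exon/CDS geometry putting locus ``t`` in region ``label``."""
    s, e = t.start, t.end
    five_left = strand == "+"
    feats: dict[str, object] = {"strand": strand, "biotype": "protein_coding"}
    if label == "exonic":
        feats.update(tx=(s - 200, e + 200), exons=[(s - 200, e + 200)], cds=(s - 100, e + 100))
    elif label == "five_utr":
        if five_left:
            feats.update(tx=(s - 150, e + 250), exons=[(s - 150, e + 250)], cds=(e + 10, e + 240))
        else:
            feats.update(tx=(s - 250, e + 150), exons=[(s - 250, e + 150)], cds=(s - 240, s - 10))
    elif label == "three_utr":
        if five_left:
            feats.update(tx=(s - 250, e + 150), exons=[(s - 250, e + 150)], cds=(s - 240, s - 10))
        else:
            feats.update(tx=(s - 150, e + 250), exons=[(s - 150, e + 250)], cds=(e + 10, e + 240))
    elif label == "intronic":
        feats.update(
            tx=(s - 300, e + 300),
            exons=[(s - 300, s - 250), (e + 250, e + 300)],
            cds=(s - 290, e + 260),
        )
    elif label == "upstream":
        if five_left:
            feats.update(tx=(e + 500, e + 1200), exons=[(e + 500, e + 1200)], cds=(e + 550, e + 1150))
        else:
            feats.update(tx=(s - 1200, s - 500), exons=[(s - 1200, s - 500)], cds=(s - 1150, s - 550))
    elif label == "downstream":
        if five_left:
            feats.update(tx=(s - 1200, s - 500), exons=[(s - 1200, s - 500)], cds=(s - 1150, s - 550))
        else:
            feats.update(tx=(e + 500, e + 1200), exons=[(e + 500, e + 1200)], cds=(e + 550, e + 1150))
    elif label == "ncRNA":
        feats.update(tx=(s - 100, e + 100), exons=[(s - 100, e + 100)], cds=None, biotype="lncRNA")
    else:
        raise ValueError(f"unexpected label {label}")
    return {"name": name, "chrom": t.chrom, "target": t.locus_id, "features": feats}


def _write_gff3(genes: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            feats = g.get("features")
            if not feats:
                # background gene with no placement: park it on its own contig
                fh.write(
                    f"bg_{g['name']}\tsynth\tgene\t1\t100\t.\t+\t.\t"
                    f"ID={g['name']};Name={g['name']};biotype=protein_coding\n"
                )
                continue
            chrom = g["chrom"]
            txs, txe = feats["tx"]
            strand = feats["strand"]
            bt = feats["biotype"]
            fh.write(
                f"{chrom}\tsynth\tgene\t{txs + 1}\t{txe}\t.\t{strand}\t.\t"
                f"ID={g['name']};Name={g['name']};biotype={bt}\n"
            )
            for k, (es, ee) in enumerate(feats["exons"]):
                fh.write(
                    f"{chrom}\tsynth\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                    f"ID={g['name']}.exon{k};Parent={g['name']}\n"
                )
            cds = feats.get("cds")
            if cds:
                cs, ce = cds
                for k, (es, ee) in enumerate(feats["exons"]):
                    os_, oe = max(es, cs), min(ee, ce)
                    if os_ < oe:
                        fh.write(
                            f"{chrom}\tsynth\tCDS\t{os_ + 1}\t{oe}\t.\t{strand}\t0\t"
                            f"ID={g['name']}.cds{k};Parent={g['name']}\n"
                        )
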