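"""Gene-region annotation of repeat loci, gene association tables, and the
2×2 panel-enrichment chi-squared test.

Region labels follow a fixed precedence when a locus touches several
features or genes: exonic (CDS) > five_utr > three_utr > ncRNA > intronic >
upstream > downstream > intergenic.  Upstream/downstream are strand-aware
windows (default 1 kb) off the transcript ends; a locus overlapping any gene
body is never labelled upstream/downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .repeat_catalog import RepeatLocus

logger = logging.getLogger(__name__)

REGION_LABELS = (
    "upstream",
    "five_utr",
    "exonic",
    "intronic",
    "three_utr",
    "downstream",
    "intergenic",
    "ncRNA",
)

#: lower rank wins when a locus overlaps multiple features/genes
_PRECEDENCE = {
    "exonic": 0,
    "five_utr": 1,
    "three_utr": 2,
    "ncRNA": 3,
    "intronic": 4,
    "upstream": 5,
    "downstream": 6,
    "intergenic": 7,
}

INTRAGENIC_LABELS = frozenset({"five_utr", "exonic", "intronic", "three_utr", "ncRNA"})
FLANKING_LABELS = frozenset({"upstream", "downstream"})


@dataclass(frozen=True)
class GeneModel:
    """A transcript-level gene model (0-based half-open coordinates)."""

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError("exon outside transcript bounds")
        if self.cds_start is not None and self.cds_end is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError("CDS outside transcript bounds")


@dataclass(frozen=True)
class AnnotatedLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    region: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.region not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region!r}")
        if self.region != "intergenic" and not self.genes:
            raise ValueError("non-intergenic locus must have associated genes")


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p_value: float
    n_overlap: int


def load_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via an in-memory gffutils database.

    Transcript bounds come from ``gene`` features; exon and CDS children are
    collected by parentage.  ``biotype`` (or ``gene_biotype``) attributes of
    ``protein_coding`` (or a present CDS) mark coding genes; everything else
    is ncRNA.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", gene.attributes.get("gene_name", [gene.id]))[0]
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        for child in db.children(gene.id):
            iv = (child.start - 1, child.end)  # GFF3 is 1-based inclusive
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
        biotype = gene.attributes.get(
            "biotype", gene.attributes.get("gene_biotype", [""])
        )[0]
        coding = bool(cds) or biotype == "protein_coding"
        tx_start, tx_end = gene.start - 1, gene.end
        if not exons:
            exons = [(tx_start, tx_end)]
        models.append(
            GeneModel(
                gene_name=name,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=min(s for s, _ in cds) if cds else None,
                cds_end=max(e for _, e in cds) if cds else None,
                exons=tuple(sorted(exons)),
                biotype="coding" if coding else "ncRNA",
            )
        )
    return models


def load_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED12 (thickStart/thickEnd as CDS bounds)."""
    models: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            thick_s = int(f[6]) if len(f) > 6 else start
            thick_e = int(f[7]) if len(f) > 7 else end
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            else:
                exons = ((start, end),)
            coding = thick_e > thick_s
            models.append(
                GeneModel(
                    gene_name=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    cds_start=thick_s if coding else None,
                    cds_end=thick_e if coding else None,
                    exons=exons,
                    biotype="coding" if coding else "ncRNA",
                )
            )
    return models


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def _coding_sublabel(locus_start: int, locus_end: int, gene: GeneModel) -> str:
    """Region label for a locus overlapping a coding gene body."""
    cs, ce = gene.cds_start, gene.cds_end
    for es, ee in gene.exons:
        if cs is not None and ce is not None:
            if _overlaps(locus_start, locus_end, max(es, cs), min(ee, ce)):
                return "exonic"
    for es, ee in gene.exons:
        if cs is None or ce is None:
            continue
        # exon portions outside the CDS span are UTR, sided by strand
        left = (es, min(ee, cs))
        right = (max(es, ce), ee)
        for (us, ue), side in ((left, "left"), (right, "right")):
            if us < ue and _overlaps(locus_start, locus_end, us, ue):
                if gene.strand == "+":
                    return "five_utr" if side == "left" else "three_utr"
                return "three_utr" if side == "left" else "five_utr"
    return "intronic"


def assign_region(
    locus: RepeatLocus,
    gene_models: Sequence[GeneModel],
    flank_bp: int = 1000,
) -> AnnotatedLocus:
    """Label one locus with its gene-region category and associated genes."""
    on_chrom = [g for g in gene_models if g.chrom == locus.chrom]
    if not on_chrom and gene_models:
        logger.warning("chromosome %s absent from gene models", locus.chrom)
    labelled: list[tuple[str, str]] = []  # (label, gene)
    for gene in on_chrom:
        if _overlaps(locus.start, locus.end, gene.tx_start, gene.tx_end):
            if gene.biotype != "coding":
                labelled.append(("ncRNA", gene.gene_name))
            else:
                labelled.append((_coding_sublabel(locus.start, locus.end, gene), gene.gene_name))
    if not labelled:
        for gene in on_chrom:
            five_left = gene.strand == "+"
            gap_left = gene.tx_start - locus.end  # locus entirely left of gene
            gap_right = locus.start - gene.tx_end  # locus entirely right of gene
            if 0 <= gap_left <= flank_bp:
                labelled.append(("upstream" if five_left else "downstream", gene.gene_name))
            elif 0 <= gap_right <= flank_bp:
                labelled.append(("downstream" if five_left else "upstream", gene.gene_name))
    if not labelled:
        return AnnotatedLocus(locus.locus_id, locus.chrom, locus.start, locus.end, "intergenic", ())
    best = min((label for label, _ in labelled), key=_PRECEDENCE.__getitem__)
    genes = tuple(sorted({g for label, g in labelled if label == best}))
    return AnnotatedLocus(locus.locus_id, locus.chrom, locus.start, locus.end, best, genes)


def annotate_loci(
    loci: Iterable[RepeatLocus],
    gene_models: Sequence[GeneModel],
    flank_bp: int = 1000,
) -> list[AnnotatedLocus]:
    return [assign_region(loc, gene_models, flank_bp) for loc in loci]


def gene_association_table(
    annotated_loci: Iterable[AnnotatedLocus],
    gene_models: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per-gene counts of intragenic and 1-kb-flanking repeat loci."""
    intragenic: dict[str, int] = {g.gene_name: 0 for g in gene_models}
    flanking: dict[str, int] = {g.gene_name: 0 for g in gene_models}
    for al in annotated_loci:
        if al.region in INTRAGENIC_LABELS:
            for g in al.genes:
                intragenic[g] = intragenic.get(g, 0) + 1
        elif al.region in FLANKING_LABELS:
            for g in al.genes:
                flanking[g] = flanking.get(g, 0) + 1
    names = sorted(set(intragenic) | set(flanking))
    return pd.DataFrame(
        {
            "gene": names,
            "n_intragenic": [intragenic.get(n, 0) for n in names],
            "n_flanking_1kb": [flanking.get(n, 0) for n in names],
            "any_repeat": [
                intragenic.get(n, 0) + flanking.get(n, 0) > 0 for n in names
            ],
        }
    )


def enrichment_chi2(
    repeat_genes: set[str],
    panel_genes: set[str],
    universe: set[str],
    yates: bool = False,
) -> EnrichmentResult:
    """Pearson chi-squared on the 2×2 panel × repeat-associated table.

    Computed by the closed-form n(ad−bc)²/(r1·r2·c1·c2), 1 degree of
    freedom, no continuity correction unless ``yates`` is set.  Genes count
    once regardless of how many repeats they carry.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not panel_genes <= universe or not repeat_genes <= universe:
        raise ValueError("panel and repeat gene sets must be subsets of the universe")
    a = len(panel_genes & repeat_genes)
    b = len(panel_genes - repeat_genes)
    c = len(repeat_genes - panel_genes)
    d = len(universe) - a - b - c
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate margin in 2x2 table")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(stat, df=1))
    return EnrichmentResult(
        table=((a, b), (c, d)), chi2=float(stat), p_value=p, n_overlap=a
    )


def join_gene_scores(genes: Iterable[str], score_table: pd.DataFrame) -> pd.DataFrame:
    """Flag genes by intolerance scores: HI < 40 and pLI > 0.75, strict;
    genes absent from the table get missing (NA) flags."""
    cols = {c.lower(): c for c in score_table.columns}
    gene_col = cols.get("gene", score_table.columns[0])
    hi_col = cols.get("hi")
    pli_col = cols.get("pli")
    indexed = score_table.set_index(gene_col)
    rows = []
    for gene in genes:
        if gene in indexed.index:
            hi = indexed.at[gene, hi_col] if hi_col else pd.NA
            pli = indexed.at[gene, pli_col] if pli_col else pd.NA
            rows.append(
                {
                    "gene": gene,
                    "hi_low": (hi < 40) if pd.notna(hi) else pd.NA,
                    "pli_high": (pli > 0.75) if pd.notna(pli) else pd.NA,
                }
            )
        else:
            rows.append({"gene": gene, "hi_low": pd.NA, "pli_high": pd.NA})
    out = pd.DataFrame(rows)
    out["hi_low"] = out["hi_low"].astype("boolean")
    out["pli_high"] = out["pli_high"].astype("boolean")
    return out


def write_annotated_loci(annotated: Iterable[AnnotatedLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tregion\tgenes\n")
        for al in annotated:
            fh.write(
                f"{al.locus_id}\t{al.chrom}\t{al.start}\t{al.end}\t{al.region}"
                f"\t{','.join(al.genes)}\n"
            )


def write_enrichment(result: EnrichmentResult, path: str | Path) -> None:
    payload = {
        "table": [list(result.table[0]), list(result.table[1])],
        "chi2": result.chi2,
        "p_value": result.p_value,
        "n_overlap": result.n_overlap,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
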