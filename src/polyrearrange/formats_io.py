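"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open. GFF3 is
1-based inclusive on disk; conversion happens only at the file boundary.
SAM positions come from pysam (already 0-based). Insert sizes are recomputed
from mate coordinates as the outer span between the leftmost mapped base and
the rightmost mapped base of a pair — the TLEN field is never trusted, since
its sign/convention varies by aligner.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pysam

from polyrearrange.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

Strand = Literal["+", "-"]

#: Repeat superfamily vocabulary (LTR order superfamilies plus the other
#: major classes seen in plant genomes).
SUPERFAMILIES = (
    "Gypsy",
    "Copia",
    "TRIM_LARD",
    "LINE",
    "SINE",
    "TIR",
    "Helitron",
    "Unknown",
)

#: Superfamilies counted as LTR retrotransposons.
LTR_SUPERFAMILIES = ("Gypsy", "Copia", "TRIM_LARD")


@dataclass(frozen=True)
class GeneRecord:
    """A located, stranded gene with a subgenome label.

    ``rank`` is the 0-based ordinal of the gene along its chromosome after
    sorting by start — the gene-order coordinate used by collinearity.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    genome_label: str
    subgenome: str = "none"  # {"A", "B", "none"}
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair joining two gene orders."""

    gene_q: str
    gene_s: str
    score: float
    evalue: float


@dataclass(frozen=True)
class AlignedPair:
    """A mapped read pair.

    ``insert`` is the outer span: rightmost mapped base of the rightmost mate
    minus leftmost mapped base of the leftmost mate. It is None when the two
    mates map to different chromosomes.
    """

    read_id: str
    chrom1: str
    pos1: int
    end1: int
    chrom2: str
    pos2: int
    end2: int
    mapq1: int
    mapq2: int
    insert: int | None
    proper: bool


@dataclass(frozen=True)
class RepeatCopy:
    """One annotated copy of a transposable-element family."""

    family: str
    superfamily: str
    chrom: str
    start: int
    end: int
    complete: bool
    genome_label: str
    subgenome: str = "none"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"repeat {self.family}@{self.chrom}:{self.start}: start >= end"
            )
        if self.superfamily not in SUPERFAMILIES:
            raise ValidationError(
                f"unknown superfamily {self.superfamily!r}; expected one of "
                f"{SUPERFAMILIES}"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(
    path: str | Path,
    kind: Literal["gene", "repeat"],
    genome_label: str = "",
    subgenome_map: dict[str, str] | None = None,
) -> list[GeneRecord] | list[RepeatCopy]:
    """Read gene or repeat records from a GFF3 file.

    Coordinates are converted 1-based inclusive -> 0-based half-open. For
    ``kind="gene"`` only rows with type ``gene`` are used and ranks are
    assigned per chromosome by start order. For ``kind="repeat"``, family /
    superfamily / completeness are read from the ``Family``, ``Superfamily``
    and ``Complete`` attributes.

    ``subgenome_map`` maps chromosome name -> subgenome label; chromosomes
    not in the map get subgenome ``"none"``.
    """
    path = Path(path)
    subgenome_map = subgenome_map or {}
    genes: list[GeneRecord] = []
    repeats: list[RepeatCopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = (
                fields
            )
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end {end1} < start {start1}")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attrs_s)
            sub = subgenome_map.get(chrom, attrs.get("Subgenome", "none"))
            if kind == "gene":
                if ftype != "gene":
                    continue
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene row without ID attribute")
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand="-" if strand == "-" else "+",
                        genome_label=genome_label,
                        subgenome=sub,
                    )
                )
            else:
                family = attrs.get("Family", attrs.get("ID", "unknown"))
                superfamily = attrs.get("Superfamily", "Unknown")
                complete = attrs.get("Complete", "false").lower() in ("true", "1", "yes")
                repeats.append(
                    RepeatCopy(
                        family=family,
                        superfamily=superfamily,
                        chrom=chrom,
                        start=start,
                        end=end,
                        complete=complete,
                        genome_label=genome_label,
                        subgenome=sub,
                    )
                )
    if kind == "gene":
        return assign_ranks(genes)
    return repeats


def assign_ranks(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Return genes with ``rank`` = 0-based index after sorting by start,
    per chromosome. Duplicate gene ids within one genome are rejected."""
    seen: set[tuple[str, str]] = set()
    for g in genes:
        key = (g.genome_label, g.gene_id)
        if key in seen:
            raise ValidationError(f"duplicate gene id {g.gene_id!r} in {g.genome_label!r}")
        seen.add(key)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneRecord] = []
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(chrom_genes):
            out.append(
                GeneRecord(
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    genome_label=g.genome_label,
                    subgenome=g.subgenome,
                    rank=rank,
                )
            )
    out.sort(key=lambda g: (g.chrom, g.rank))
    return out


def write_gff3(
    records: Iterable[GeneRecord] | Iterable[RepeatCopy],
    path: str | Path,
) -> None:
    """Write gene or repeat records as GFF3 (0-based half-open -> 1-based
    inclusive at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            if isinstance(rec, GeneRecord):
                attrs = f"ID={rec.gene_id};Subgenome={rec.subgenome}"
                fh.write(
                    f"{rec.chrom}\tpolyrearrange\tgene\t{rec.start + 1}\t{rec.end}\t."
                    f"\t{rec.strand}\t.\t{attrs}\n"
                )
            else:
                attrs = (
                    f"Family={rec.family};Superfamily={rec.superfamily};"
                    f"Complete={'true' if rec.complete else 'false'};"
                    f"Subgenome={rec.subgenome}"
                )
                fh.write(
                    f"{rec.chrom}\tpolyrearrange\trepeat_region\t{rec.start + 1}"
                    f"\t{rec.end}\t.\t+\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


def read_blast_tab(path: str | Path, max_evalue: float = 1e-10) -> list[AnchorPair]:
    """Read homologous gene pairs from 12-column BLAST tabular output.

    Rows above ``max_evalue`` and self-pairs (qseqid == sseqid) are dropped.
    """
    path = Path(path)
    anchors: list[AnchorPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 BLAST columns, got {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad evalue/bitscore") from exc
            if qseqid == sseqid:
                continue
            if evalue > max_evalue:
                continue
            anchors.append(
                AnchorPair(gene_q=qseqid, gene_s=sseqid, score=bitscore, evalue=evalue)
            )
    return anchors


def write_blast_tab(anchors: Iterable[AnchorPair], path: str | Path) -> None:
    """Write anchors in 12-column BLAST tabular form (placeholder alignment
    statistics; identity/coords are not used downstream)."""
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(
                f"{a.gene_q}\t{a.gene_s}\t100.0\t100\t0\t0\t1\t100\t1\t100"
                f"\t{a.evalue:g}\t{a.score:g}\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def read_sam(path: str | Path, min_mapq: int = 20) -> list[AlignedPair]:
    """Read paired alignments from a SAM/BAM file.

    Mates are matched by read id. A pair is excluded when either mate's MAPQ
    is below ``min_mapq`` (both mates must pass, as with per-read ``-q``
    filtering applied to both files of a pair). The insert is the outer span
    recomputed from coordinates, defined only for same-chromosome pairs.
    Unpaired reads left at EOF are dropped with a warning.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPair] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            name = rec.query_name
            mate = pending.pop(name, None)
            if mate is None:
                pending[name] = rec
                continue
            pairs.append(_make_pair(mate, rec, name))
    if pending:
        logger.warning("%d unpaired reads dropped from %s", len(pending), path)
    return [p for p in pairs if min(p.mapq1, p.mapq2) >= min_mapq]


def _make_pair(a: pysam.AlignedSegment, b: pysam.AlignedSegment, name: str) -> AlignedPair:
    # order mates by (chrom, pos) so pair construction is input-order invariant
    ka = (a.reference_name, a.reference_start)
    kb = (b.reference_name, b.reference_start)
    if kb < ka:
        a, b = b, a
    end_a = a.reference_end if a.reference_end is not None else a.reference_start + 1
    end_b = b.reference_end if b.reference_end is not None else b.reference_start + 1
    if a.reference_name == b.reference_name:
        insert = max(end_a, end_b) - min(a.reference_start, b.reference_start)
    else:
        insert = None
    return AlignedPair(
        read_id=name,
        chrom1=a.reference_name,
        pos1=a.reference_start,
        end1=end_a,
        chrom2=b.reference_name,
        pos2=b.reference_start,
        end2=end_b,
        mapq1=a.mapping_quality,
        mapq2=b.mapping_quality,
        insert=insert,
        proper=bool(a.is_proper_pair and b.is_proper_pair),
    )


def write_sam(
    pairs: Iterable[tuple[str, str, int, int, str, int, int, int, bool]],
    path: str | Path,
    chrom_lengths: dict[str, int],
) -> None:
    """Write placed read pairs as a SAM file.

    Each item is (read_id, chrom1, pos1, len1, chrom2, pos2, len2, mapq,
    proper). Reads carry an all-match CIGAR and ``*`` sequence: the pipeline
    consumes placements, not bases.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_lengths.items())],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        hdr = out.header
        for read_id, c1, p1, l1, c2, p2, l2, mapq, proper in pairs:
            for idx, (c, p, ln, mc, mp) in enumerate(
                [(c1, p1, l1, c2, p2), (c2, p2, l2, c1, p1)]
            ):
                seg = pysam.AlignedSegment(hdr)
                seg.query_name = read_id
                seg.reference_name = c
                seg.reference_start = p
                seg.mapping_quality = mapq
                seg.cigartuples = [(0, ln)]
                seg.flag = 0x1 | (0x40 if idx == 0 else 0x80)
                if proper:
                    seg.flag |= 0x2
                seg.next_reference_name = mc
                seg.next_reference_start = mp
                out.write(seg)


# ---------------------------------------------------------------------------
# FASTA / TSV
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_marker_table(path: str | Path):
    """Read a genetic-map marker table (TSV: marker, linkage_group, cm)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "linkage_group": str})
    required = {"marker", "linkage_group", "cm"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing marker-table columns {sorted(missing)}")
    return df


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
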