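"""Readers and writers for the formats the pipeline touches.

All genomic coordinates are normalized at this boundary to 0-based,
half-open intervals (the BED convention); GFF3 input (1-based, closed) is
converted on read and back on write.  Alignments come either from a
SAM-dialect text table or from a simplified 7-column TSV; both yield the
same :class:`AlignedRead` records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

FEATURE_CLASSES = ("ER", "iR", "PR", "5UR", "3UR", "known_sncRNA", "repeat")

_COMPLEMENT = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed input records; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A span on a contig: 0-based start (inclusive), end (exclusive), strand.

    Strand "." means unstranded and matches either strand in overlap tests.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.contig != other.contig:
            return False
        if stranded and not strands_compatible(self.strand, other.strand):
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


def strands_compatible(a: str, b: str) -> bool:
    """"." is treated as matching both strands."""
    return a == "." or b == "." or a == b


@dataclass
class AlignedRead:
    """One mapped read; spliced alignments carry more than one block."""

    read_id: str
    sample: str
    blocks: list[GenomicInterval]
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no aligned blocks")
        contigs = {b.contig for b in self.blocks}
        strands = {b.strand for b in self.blocks}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(f"read {self.read_id}: blocks span contigs/strands")
        starts = [b.start for b in self.blocks]
        if starts != sorted(starts):
            raise ValueError(f"read {self.read_id}: blocks not sorted")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id}: overlapping blocks")

    @property
    def contig(self) -> str:
        return self.blocks[0].contig

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)


@dataclass(frozen=True)
class FeatureRecord:
    interval: GenomicInterval
    feature_class: str
    gene_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


# ---------------------------------------------------------------------------
# alignments

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_blocks(pos0: int, cigar: str) -> list[tuple[int, int]]:
    """Walk a CIGAR string from a 0-based reference start into aligned blocks.

    M/=/X and D consume reference within the current block; N ends the block
    and skips reference (an intron); S/I/H/P consume no reference.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or sum(int(n) for n, _ in ops) == 0:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    blocks: list[tuple[int, int]] = []
    ref = pos0
    block_start: int | None = None
    for n_str, op in ops:
        n = int(n_str)
        if op in "M=XD":
            if block_start is None:
                block_start = ref
            ref += n
        elif op == "N":
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            ref += n
        # S, I, H, P: no reference consumed
    if block_start is not None:
        blocks.append((block_start, ref))
    return [b for b in blocks if b[1] > b[0]]


def _read_from_sam_fields(fields: list[str], lineno: int, default_sample: str) -> AlignedRead | None:
    if len(fields) < 11:
        raise ParseError(f"line {lineno}: SAM record has {len(fields)} fields, expected >= 11")
    qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
    try:
        flag, pos, mapq = int(flag_s), int(pos_s), int(mapq_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric SAM field ({exc})") from None
    if flag & 0x4 or rname == "*" or cigar == "*":
        return None  # unmapped
    strand = "-" if flag & 0x10 else "+"
    sample = default_sample
    for tag in fields[11:]:
        if tag.startswith(("RG:Z:", "SM:Z:")):
            sample = tag.split(":", 2)[2]
    try:
        blocks = cigar_blocks(pos - 1, cigar)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    return AlignedRead(
        read_id=qname,
        sample=sample,
        blocks=[GenomicInterval(rname, s, e, strand) for s, e in blocks],
        mapq=mapq,
    )


def _read_from_tsv_fields(fields: list[str], lineno: int) -> AlignedRead:
    if len(fields) != 7:
        raise ParseError(f"line {lineno}: expected 7 columns, got {len(fields)}")
    read_id, sample, contig, strand, starts_s, ends_s, mapq_s = fields
    try:
        starts = [int(x) for x in starts_s.split(",") if x != ""]
        ends = [int(x) for x in ends_s.split(",") if x != ""]
        mapq = int(mapq_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric coordinate ({exc})") from None
    if len(starts) != len(ends) or not starts:
        raise ParseError(
            f"line {lineno}: block_starts/block_ends count mismatch "
            f"({len(starts)} vs {len(ends)})"
        )
    try:
        blocks = [GenomicInterval(contig, s, e, strand) for s, e in zip(starts, ends)]
        return AlignedRead(read_id, sample, blocks, mapq)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def read_alignments(path: str | Path, min_mapq: int = 0) -> list[AlignedRead]:
    """Read a SAM text file or the simplified 7-column alignment TSV.

    The dialect is sniffed per file: a header line starting with ``@`` or a
    first record with >= 11 columns whose 2nd/4th/5th fields are numeric is
    SAM; otherwise the TSV layout
    (read_id, sample, contig, strand, block_starts, block_ends, mapq).
    Reads with ``mapq < min_mapq`` and unmapped records are dropped.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    sam: bool | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                sam = True
                continue
            fields = line.split("\t")
            if sam is None:
                sam = len(fields) >= 11 and all(
                    fields[i].lstrip("-").isdigit() for i in (1, 3, 4)
                )
            if fields[0] in ("read_id",):  # TSV header
                continue
            read = (
                _read_from_sam_fields(fields, lineno, default_sample=path.stem)
                if sam
                else _read_from_tsv_fields(fields, lineno)
            )
            if read is not None and read.mapq >= min_mapq:
                reads.append(read)
    return reads


def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tsample\tcontig\tstrand\tblock_starts\tblock_ends\tmapq\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.sample}\t{r.contig}\t{r.strand}\t"
                f"{','.join(str(b.start) for b in r.blocks)}\t"
                f"{','.join(str(b.end) for b in r.blocks)}\t{r.mapq}\n"
            )


def write_alignments_sam(
    reads: Iterable[AlignedRead], path: str | Path, contig_lengths: Mapping[str, int]
) -> None:
    """Write reads as SAM with M/N CIGARs; sequence/quality columns are '*'."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for r in reads:
            flag = 16 if r.strand == "-" else 0
            parts = []
            for i, b in enumerate(r.blocks):
                if i:
                    parts.append(f"{b.start - r.blocks[i - 1].end}N")
                parts.append(f"{len(b)}M")
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig}\t{r.start + 1}\t{r.mapq}\t"
                f"{''.join(parts)}\t*\t0\t0\t*\t*\tSM:Z:{r.sample}\n"
            )


# ---------------------------------------------------------------------------
# annotation

_GFF_FEATURE_MAP = {
    "exon": "ER",
    "intron": "iR",
    "promoter": "PR",
    "five_prime_UTR": "5UR",
    "three_prime_UTR": "3UR",
    "ncRNA": "known_sncRNA",
    "repeat_region": "repeat",
}
_FEATURE_GFF_MAP = {v: k for k, v in _GFF_FEATURE_MAP.items()}


def _gff_attr(attrs: Mapping[str, Sequence[str]], key: str) -> str | None:
    vals = attrs.get(key)
    return vals[0] if vals else None


def read_annotation(
    gff_path: str | Path | None = None,
    bed_paths: Mapping[str, str | Path] | None = None,
    promoter_window: int = 1000,
) -> list[FeatureRecord]:
    """Load feature records from GFF3 and/or per-class BED6 files.

    GFF3 (1-based closed) is converted to 0-based half-open.  Introns are
    derived as the gaps between consecutive exons of each transcript when the
    file carries none; promoters as the ``promoter_window`` nt upstream of
    each transcript start (strand-aware) when no explicit promoter features
    or PR BED file are present.
    """
    import gffutils

    records: list[FeatureRecord] = []
    bed_classes = set(bed_paths or {})
    if gff_path is not None:
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        have_introns = any(True for _ in db.features_of_type("intron"))
        have_promoters = any(True for _ in db.features_of_type("promoter"))
        for feat in db.all_features():
            cls = _GFF_FEATURE_MAP.get(feat.featuretype)
            if cls is None:
                continue
            if feat.end < feat.start:
                raise ParseError(f"GFF3 feature {feat.id}: end < start")
            records.append(
                FeatureRecord(
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or "."),
                    cls,
                    gene_id=_gff_attr(feat.attributes, "gene_id"),
                    name=feat.id or "",
                )
            )
        for tx in db.features_of_type(("transcript", "mRNA")):
            gene_id = _gff_attr(tx.attributes, "gene_id")
            exons = sorted(
                db.children(tx, featuretype="exon"), key=lambda f: f.start
            )
            if not have_introns and "iR" not in bed_classes:
                for a, b in zip(exons, exons[1:]):
                    if b.start - 1 > a.end:  # non-adjacent exons
                        records.append(
                            FeatureRecord(
                                GenomicInterval(tx.seqid, a.end, b.start - 1, tx.strand or "."),
                                "iR",
                                gene_id=gene_id,
                                name=f"{tx.id}.intron",
                            )
                        )
            if not have_promoters and "PR" not in bed_classes:
                if tx.strand == "-":
                    pr_start, pr_end = tx.end, tx.end + promoter_window
                else:
                    pr_start, pr_end = tx.start - 1 - promoter_window, tx.start - 1
                pr_start = max(pr_start, 0)
                if pr_end > pr_start:
                    records.append(
                        FeatureRecord(
                            GenomicInterval(tx.seqid, pr_start, pr_end, tx.strand or "."),
                            "PR",
                            gene_id=gene_id,
                            name=f"{tx.id}.promoter",
                        )
                    )
    for cls, bed in (bed_paths or {}).items():
        if cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class key {cls!r}")
        records.extend(read_bed(bed, cls))
    return records


def read_bed(path: str | Path, feature_class: str) -> list[FeatureRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 BED columns")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            records.append(
                FeatureRecord(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), strand),
                    feature_class,
                    name=name,
                )
            )
    return records


def write_bed(records: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            iv = r.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{r.name or '.'}\t0\t{iv.strand}\n")


def write_annotation_gff3(records: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write feature records back to GFF3 (coordinates re-converted to 1-based)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(records, start=1):
            iv = r.interval
            ftype = _FEATURE_GFF_MAP[r.feature_class]
            attrs = f"ID={r.name or f'feat{i}'}"
            if r.gene_id:
                attrs += f";gene_id={r.gene_id}"
            fh.write(
                f"{iv.contig}\t.\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# candidates

CANDIDATE_TSV_COLUMNS = [
    "candidate_id", "contig", "start", "end", "strand", "read_count",
    "max_depth", "context", "sequence", "sno_class", "homology_subject",
    "homology_family", "homology_identity", "host_gene_id",
]


def write_candidates(candidates: Sequence, path: str | Path) -> None:
    """Write candidates as BED6 plus a ``<path>.tsv`` sidecar with annotations.

    Round-trips losslessly through :func:`read_candidates`.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in candidates:
            iv = c.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{c.candidate_id}\t"
                f"{c.read_count}\t{iv.strand}\n"
            )
    rows = []
    for c in candidates:
        hom = getattr(c, "homology", None)
        sno = getattr(c, "sno_class", None)
        rows.append({
            "candidate_id": c.candidate_id,
            "contig": c.interval.contig,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "read_count": c.read_count,
            "max_depth": c.max_depth,
            "context": c.context,
            "sequence": c.sequence or "",
            "sno_class": sno.label if sno is not None else "",
            "homology_subject": hom.subject_id if hom is not None else "",
            "homology_family": hom.subject_family if hom is not None else "",
            "homology_identity": f"{hom.identity:.6f}" if hom is not None else "",
            "host_gene_id": getattr(c, "host_gene_id", None) or "",
        })
    pd.DataFrame(rows, columns=CANDIDATE_TSV_COLUMNS).to_csv(
        path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False
    )


def read_candidates(path: str | Path) -> list:
    from .cluster_call import Candidate
    from .homology import HomologyHit
    from .sno_annotate import SnoClassCall

    path = Path(path)
    tsv = path.with_suffix(path.suffix + ".tsv")
    df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        sno = SnoClassCall(label=row["sno_class"]) if row["sno_class"] else None
        hom = None
        if row["homology_subject"]:
            hom = HomologyHit(
                query_id=row["candidate_id"],
                subject_id=row["homology_subject"],
                subject_family=row["homology_family"],
                identity=float(row["homology_identity"]),
                query_coverage=0.0,
                alignment_score=0,
                strand="+",
            )
        out.append(
            Candidate(
                candidate_id=row["candidate_id"],
                interval=GenomicInterval(
                    row["contig"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                read_count=int(row["read_count"]),
                max_depth=int(row["max_depth"]),
                context=row["context"],
                sequence=row["sequence"] or None,
                sno_class=sno,
                homology=hom,
                host_gene_id=row["host_gene_id"] or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTA helpers

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into {id: sequence}; descriptions are kept separately
    by :func:`read_fasta_with_descriptions` when family tags are needed."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_descriptions(path: str | Path) -> dict[str, tuple[str, str]]:
    from Bio import SeqIO

    out: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = (str(rec.seq), rec.description)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
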