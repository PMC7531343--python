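"""Readers and writers for the formats the editome pipeline touches.

All coordinates are held 1-based inclusive internally (the VCF/GTF
convention, in which editing sites are point events such as
``chrX:151358319``).  BED input, which is 0-based half-open, is converted
at the boundary and converted back on write.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# reference genome


@dataclass
class ReferenceGenome:
    """Named chromosome sequences over the alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("genome has no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"illegal characters {sorted(bad)} in {name!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequences[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"{chrom}:{pos} outside contig of length {len(seq)}")
        return seq[pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        return self.sequences[chrom][start - 1 : end]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file; sequences case-folded to upper, names unique."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate sequence name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by start
    cds: list[tuple[int, int]] = field(default_factory=list)
    frame: int = 0  # frame of the transcript-order first CDS segment
    biotype: str = "coding"  # 'coding' | 'ncRNA'

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site in genomic coordinates."""
        return self.start if self.strand == "+" else self.end

    def utr_intervals(self) -> list[tuple[int, int]]:
        """Exonic intervals outside the CDS (empty for non-coding)."""
        if not self.cds:
            return []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        utrs = []
        for s, e in self.exons:
            if s < cds_lo:
                utrs.append((s, min(e, cds_lo - 1)))
            if e > cds_hi:
                utrs.append((max(s, cds_hi + 1), e))
        return utrs


@dataclass(frozen=True)
class SpliceJunction:
    chrom: str
    pos: int  # boundary base of the flanking exon (1-based)
    side: str  # 'donor' | 'acceptor'


@dataclass
class RepeatInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    name: str

    @property
    def family(self) -> str:
        """'Alu' for RepeatMasker-style Alu names, else 'other'."""
        return "Alu" if self.name.startswith("Alu") else "other"


class SnpSet(set):
    """Set of known variant records (chrom, pos, ref, alt).

    ``n_skipped_indels`` counts input records dropped because ref/alt were
    not single bases.
    """

    n_skipped_indels: int = 0

    def positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _r, _a in self}


@dataclass
class AnnotationBundle:
    """Everything the pipeline knows about the genome besides its sequence."""

    transcripts: list[Transcript] = field(default_factory=list)
    splice_junctions: set[SpliceJunction] = field(default_factory=set)
    repeats: list[RepeatInterval] = field(default_factory=list)
    known_snps: SnpSet = field(default_factory=SnpSet)
    flank_bp: int = 1000

    def repeat_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees of repeats (end-exclusive internally)."""
        trees: dict[str, IntervalTree] = {}
        for rep in self.repeats:
            trees.setdefault(rep.chrom, IntervalTree()).addi(
                rep.start, rep.end + 1, rep.family
            )
        return trees

    def junction_positions(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j in self.splice_junctions:
            out.setdefault(j.chrom, []).append(j.pos)
        for chrom in out:
            out[chrom].sort()
        return out


def derive_junctions(transcripts: Iterable[Transcript]) -> set[SpliceJunction]:
    """Splice junctions from internal exon boundaries.

    Transcript ends are not junctions; on the minus strand the donor lies at
    the higher-coordinate side of each intron.
    """
    junctions: set[SpliceJunction] = set()
    for tx in transcripts:
        exons = tx.exons
        for i in range(len(exons) - 1):
            left, right = exons[i][1], exons[i + 1][0]
            if tx.strand == "+":
                junctions.add(SpliceJunction(tx.chrom, left, "donor"))
                junctions.add(SpliceJunction(tx.chrom, right, "acceptor"))
            else:
                junctions.add(SpliceJunction(tx.chrom, left, "acceptor"))
                junctions.add(SpliceJunction(tx.chrom, right, "donor"))
    return junctions


def read_gtf(path: str | Path) -> tuple[list[Transcript], set[SpliceJunction]]:
    """Parse gene models from GTF and derive splice junctions.

    A transcript is 'coding' iff it has CDS features; its frame is taken
    from the transcript-order first CDS segment.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: list[Transcript] = []
    for feat in db.features_of_type("transcript"):
        exons = [
            (e.start, e.end)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        cds = [
            (c.start, c.end, c.frame)
            for c in db.children(feat, featuretype="CDS", order_by="start")
        ]
        if not exons:
            raise FormatError(f"transcript {feat.id!r} has no exons")
        frame = 0
        if cds:
            first = cds[0] if feat.strand == "+" else cds[-1]
            frame = int(first[2]) if first[2] not in (".", None) else 0
        biotype = feat.attributes.get("transcript_biotype", [None])[0]
        if biotype is None:
            biotype = "coding" if cds else "ncRNA"
        transcripts.append(
            Transcript(
                transcript_id=feat.id,
                gene_id=feat.attributes.get("gene_id", [feat.id])[0],
                chrom=feat.seqid,
                strand=feat.strand,
                exons=exons,
                cds=[(s, e) for s, e, _f in cds],
                frame=frame,
                biotype=biotype,
            )
        )
    return transcripts, derive_junctions(transcripts)


def write_gtf(transcripts: Sequence[Transcript], path: str | Path) -> None:
    def row(chrom, src, ftype, start, end, strand, frame, attrs):
        return (
            f"{chrom}\t{src}\t{ftype}\t{start}\t{end}\t.\t{strand}\t{frame}\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            fh.write(
                row(tx.chrom, "editome", "transcript", tx.start, tx.end, tx.strand, ".", attrs)
            )
            for s, e in tx.exons:
                fh.write(row(tx.chrom, "editome", "exon", s, e, tx.strand, ".", attrs))
            cds = tx.cds if tx.strand == "+" else tx.cds[::-1]
            frame = tx.frame
            for s, e in cds:
                fh.write(row(tx.chrom, "editome", "CDS", s, e, tx.strand, frame, attrs))
                frame = (3 - ((e - s + 1 - frame) % 3)) % 3
            for s, e in tx.utr_intervals():
                fh.write(row(tx.chrom, "editome", "UTR", s, e, tx.strand, ".", attrs))


def read_repeats_bed(path: str | Path) -> list[RepeatInterval]:
    """BED (0-based half-open) with the repeat name in column 4.

    Coordinates are converted to 1-based inclusive; names beginning 'Alu'
    are the Alu family, everything else is 'other'.
    """
    repeats: list[RepeatInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{line_no}: expected ≥4 BED columns")
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            if start >= end:
                raise FormatError(f"{path}:{line_no}: start {start} ≥ end {end}")
            repeats.append(RepeatInterval(chrom, start + 1, end, name))
    return repeats


def write_repeats_bed(repeats: Sequence[RepeatInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            fh.write(f"{rep.chrom}\t{rep.start - 1}\t{rep.end}\t{rep.name}\n")


def read_known_sites(path: str | Path) -> SnpSet:
    """Known-variant sites from VCF or a 4-column TSV (chrom, pos, ref, alt).

    Multiallelic VCF records expand to one tuple per ALT; indels are skipped
    (counted on the returned set, and logged), not an error.
    """
    path = Path(path)
    snps = SnpSet()
    skipped = 0
    with open(path) as fh:
        first = fh.readline()
    is_vcf = first.startswith("##") or path.suffix.lower() in (".vcf", ".gz")

    def add(chrom: str, pos: int, ref: str, alt: str) -> None:
        nonlocal skipped
        if len(ref) == 1 and len(alt) == 1 and ref != alt:
            snps.add((chrom, pos, ref.upper(), alt.upper()))
        else:
            skipped += 1

    if is_vcf:
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    add(rec.chrom, rec.pos, rec.ref or "", alt)
    else:
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 4:
                    raise FormatError(f"{path}:{line_no}: expected 4 TSV columns")
                add(cols[0], int(cols[1]), cols[2], cols[3])
    snps.n_skipped_indels = skipped
    if skipped:
        log.info("read_known_sites: skipped %d indel/other records", skipped)
    return snps


def write_known_sites_vcf(
    snps: Iterable[tuple[str, int, str, str]],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(snps):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# pileups


@dataclass
class PileupColumn:
    """One genomic position in one sample.

    ``bases[i]`` is the base observed on read *i* and ``offsets[i]`` its
    1-based position within that read in sequencing order (the quantity the
    random-hexamer read-start filter acts on).
    """

    chrom: str
    pos: int
    ref: str
    bases: str
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.offsets):
            raise FormatError(
                f"{self.chrom}:{self.pos}: {len(self.bases)} bases but "
                f"{len(self.offsets)} offsets"
            )

    @property
    def depth(self) -> int:
        return len(self.bases)


def read_pileup(path: str | Path) -> Iterator[PileupColumn]:
    """Stream a simplified pileup TSV: chrom, pos, ref, depth, bases, offsets."""
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{line_no}: expected 6 columns")
            chrom, pos, ref, depth, bases, offstr = cols[:6]
            offsets = tuple(int(x) for x in offstr.split(",") if x != "")
            col = PileupColumn(chrom, int(pos), ref, bases, offsets)
            if col.depth != int(depth):
                raise FormatError(
                    f"{path}:{line_no}: depth field {depth} but {col.depth} observations"
                )
            yield col


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        for col in columns:
            offstr = ",".join(str(o) for o in col.offsets)
            fh.write(
                f"{col.chrom}\t{col.pos}\t{col.ref}\t{col.depth}\t{col.bases}\t{offstr}\n"
            )


# ---------------------------------------------------------------------------
# site/call tables


@dataclass(frozen=True)
class SiteCall:
    """Per-sample, per-site filtered depths and the editing ratio.

    ``editing_ratio`` is alt_depth/total_depth, or NaN when total_depth is 0.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    editing_ratio: float

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise ValueError("alt_depth exceeds total_depth")


SITE_TABLE_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "total_depth",
    "alt_depth",
    "editing_ratio",
]


def write_site_table(records: Iterable[SiteCall], path: str | Path) -> None:
    """TSV with a fixed header; undefined ratios serialized as 'NA'."""
    df = pd.DataFrame([r.__dict__ for r in records], columns=SITE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_site_table(path: str | Path) -> list[SiteCall]:
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"sample": str}
    )
    unknown = set(df.columns) - set(SITE_TABLE_COLUMNS)
    if unknown:
        raise FormatError(f"unknown site-table columns: {sorted(unknown)}")
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing site-table columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ratio = float(row.editing_ratio) if pd.notna(row.editing_ratio) else math.nan
        out.append(
            SiteCall(
                sample=str(row.sample),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                total_depth=int(row.total_depth),
                alt_depth=int(row.alt_depth),
                editing_ratio=ratio,
            )
        )
    return out


def read_manifest(path: str | Path) -> dict[str, str]:
    """Sample→group manifest TSV with columns 'sample' and 'group'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError("manifest needs 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


def write_manifest(manifest: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in manifest.items():
            fh.write(f"{sample}\t{group}\n")
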