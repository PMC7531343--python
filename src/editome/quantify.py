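"""Per-sample editing quantification and event classification.

The editing ratio at a site in a sample is the alternate allelic depth
divided by the total depth, both counted after the read-position trim.  A
call is a *putative (high-confidence) editing event* in a sample when its
total depth is at least 10 reads and its editing ratio exceeds 0.2.

Events are classified along four axes: substitution family (A-to-I =
A>G/T>C, the ADAR signature; C-to-U = C>T/G>A, the APOBEC signature),
genomic region (CDS-exonic, UTR, ncRNA, intronic, 5′ flank, intergenic,
in that precedence), repeat context (Alu, non-Alu repeat, non-repeat) and,
for CDS sites, the coding effect (missense/synonymous with the amino-acid
change, strand-aware).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .formats_io import (
    AnnotationBundle,
    PileupColumn,
    ReferenceGenome,
    SiteCall,
    Transcript,
)
from .screen import CandidateSite, apply_read_position_filter

REGIONS = ["exonic", "UTR", "ncRNA", "intronic", "5'flank", "intergenic"]
REPEAT_CLASSES = ["Alu", "non-Alu repeat", "non-repeat"]
FAMILIES = ["A-to-I", "C-to-U", "other"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def compute_editing_ratio(alt_depth: int, total_depth: int) -> float:
    """alt/total; NaN when total is zero."""
    if not 0 <= alt_depth <= (total_depth if total_depth >= 0 else -1):
        raise ValueError(f"bad depths alt={alt_depth} total={total_depth}")
    if total_depth == 0:
        return math.nan
    return alt_depth / total_depth


def quantify_sites(
    pileups: dict[str, list[PileupColumn]],
    sites: list[CandidateSite],
    trim: int = 6,
) -> list[SiteCall]:
    """One SiteCall per (sample, site); depth 0 / NaN ratio when uncovered."""
    wanted = {(s.chrom, s.pos): s for s in sites}
    calls: list[SiteCall] = []
    for sample in sorted(pileups):
        found: dict[tuple[str, int], PileupColumn] = {}
        for col in pileups[sample]:
            key = (col.chrom, col.pos)
            if key in wanted:
                found[key] = apply_read_position_filter(col, trim)
        for key, site in sorted(wanted.items()):
            col = found.get(key)
            total = col.depth if col else 0
            alt = col.bases.count(site.alt) if col else 0
            calls.append(
                SiteCall(
                    sample=sample,
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    total_depth=total,
                    alt_depth=alt,
                    editing_ratio=compute_editing_ratio(alt, total),
                )
            )
    return calls


def select_high_confidence(
    calls: list[SiteCall], min_depth: int = 10, min_ratio: float = 0.2
) -> list[SiteCall]:
    """Keep calls with depth ≥ min_depth and ratio strictly > min_ratio."""
    return [
        c
        for c in calls
        if c.total_depth >= min_depth
        and not math.isnan(c.editing_ratio)
        and c.editing_ratio > min_ratio
    ]


# ---------------------------------------------------------------------------
# classification


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Return (substitution class, family).

    The family rule is unsigned: A>G and T>C are both the ADAR (A-to-I)
    signature, C>T and G>A the APOBEC (C-to-U) signature — gene strand is
    consulted only for coding effects, so intergenic sites stay classifiable.
    """
    if ref == alt:
        raise ValueError("ref equals alt")
    cls = f"{ref}>{alt}"
    if cls in ("A>G", "T>C"):
        return cls, "A-to-I"
    if cls in ("C>T", "G>A"):
        return cls, "C-to-U"
    return cls, "other"


class RegionIndex:
    """Interval-tree lookup implementing the region precedence
    exonic(CDS) > UTR > ncRNA > intronic > 5'flank > intergenic."""

    def __init__(self, annotations: AnnotationBundle):
        self.flank_bp = annotations.flank_bp
        self._cds: dict[str, IntervalTree] = {}
        self._utr: dict[str, IntervalTree] = {}
        self._nc_exon: dict[str, IntervalTree] = {}
        self._span: dict[str, IntervalTree] = {}
        self._flank: dict[str, IntervalTree] = {}
        for tx in annotations.transcripts:
            add = lambda trees, s, e, data=None: trees.setdefault(  # noqa: E731
                tx.chrom, IntervalTree()
            ).addi(s, e + 1, data)
            add(self._span, tx.start, tx.end, tx)
            for s, e in tx.cds:
                add(self._cds, s, e)
            for s, e in tx.utr_intervals():
                add(self._utr, s, e)
            if tx.biotype != "coding":
                for s, e in tx.exons:
                    add(self._nc_exon, s, e)
            if tx.strand == "+":
                fs, fe = tx.start - self.flank_bp, tx.start - 1
            else:
                fs, fe = tx.end + 1, tx.end + self.flank_bp
            if fe >= max(fs, 1):
                add(self._flank, max(fs, 1), fe)

    @staticmethod
    def _hit(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
        tree = trees.get(chrom)
        return bool(tree and tree.overlaps(pos))

    def classify(self, chrom: str, pos: int) -> str:
        if self._hit(self._cds, chrom, pos):
            return "exonic"
        if self._hit(self._utr, chrom, pos):
            return "UTR"
        if self._hit(self._nc_exon, chrom, pos):
            return "ncRNA"
        if self._hit(self._span, chrom, pos):
            return "intronic"
        if self._hit(self._flank, chrom, pos):
            return "5'flank"
        return "intergenic"

    def coding_transcripts_at(self, chrom: str, pos: int) -> list[Transcript]:
        tree = self._span.get(chrom)
        if not tree:
            return []
        txs = [
            iv.data
            for iv in tree[pos]
            if iv.data.biotype == "coding"
            and any(s <= pos <= e for s, e in iv.data.cds)
        ]
        return sorted(txs, key=lambda t: t.transcript_id)

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._span.get(chrom)
        if not tree:
            return []
        return sorted({iv.data.gene_id for iv in tree[pos]})


def classify_region(
    site: CandidateSite, annotations: AnnotationBundle, index: RegionIndex | None = None
) -> str:
    index = index or RegionIndex(annotations)
    return index.classify(site.chrom, site.pos)


def classify_repeat(
    site: CandidateSite,
    annotations: AnnotationBundle,
    trees: dict[str, IntervalTree] | None = None,
) -> str:
    """Alu beats non-Alu repeat beats non-repeat when intervals overlap."""
    trees = trees if trees is not None else annotations.repeat_trees()
    tree = trees.get(site.chrom)
    if not tree:
        return "non-repeat"
    families = {iv.data for iv in tree[site.pos]}
    if "Alu" in families:
        return "Alu"
    if families:
        return "non-Alu repeat"
    return "non-repeat"


@dataclass(frozen=True)
class CodingEffect:
    kind: str  # 'missense' | 'synonymous'
    aa_ref: str
    protein_pos: int  # 1-based
    aa_alt: str
    transcript_id: str

    def hgvs_p(self) -> str:
        return f"p{self.aa_ref}{self.protein_pos}{self.aa_alt}"


def _spliced_cds(tx: Transcript, genome: ReferenceGenome) -> tuple[str, list[int]]:
    """CDS sequence in transcript orientation plus the genomic position of
    each of its bases."""
    seq_parts: list[str] = []
    positions: list[int] = []
    for s, e in tx.cds:
        seq_parts.append(genome.slice(tx.chrom, s, e))
        positions.extend(range(s, e + 1))
    cds_seq = "".join(seq_parts)
    if tx.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        positions = positions[::-1]
    return cds_seq, positions


def annotate_coding_effect(
    site: CandidateSite,
    annotations: AnnotationBundle,
    genome: ReferenceGenome,
    index: RegionIndex | None = None,
) -> CodingEffect | None:
    """Amino-acid consequence of the edit on the first coding transcript
    whose CDS covers the site; None when the site is not in any CDS.

    The codon is rebuilt from the spliced CDS on the transcript strand, so
    a genomic T>C in a minus-strand gene is evaluated as the transcript
    A>G it really is.
    """
    index = index or RegionIndex(annotations)
    for tx in index.coding_transcripts_at(site.chrom, site.pos):
        cds_seq, positions = _spliced_cds(tx, genome)
        cds_seq = cds_seq[tx.frame :]
        positions = positions[tx.frame :]
        try:
            idx = positions.index(site.pos)
        except ValueError:
            continue
        if cds_seq[idx] != (site.ref if tx.strand == "+" else _COMPLEMENT[site.ref]):
            raise ValueError(
                f"{site.chrom}:{site.pos}: CDS base disagrees with site ref"
            )
        codon_idx = idx // 3
        codon_start = codon_idx * 3
        codon = cds_seq[codon_start : codon_start + 3]
        if len(codon) < 3:
            continue  # trailing partial codon
        alt_tx = site.alt if tx.strand == "+" else _COMPLEMENT[site.alt]
        alt_codon = codon[: idx % 3] + alt_tx + codon[idx % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        return CodingEffect(
            kind="synonymous" if aa_ref == aa_alt else "missense",
            aa_ref=aa_ref,
            protein_pos=codon_idx + 1,
            aa_alt=aa_alt,
            transcript_id=tx.transcript_id,
        )
    return None


@dataclass(frozen=True)
class EditingEvent:
    site: CandidateSite
    substitution: str
    family: str
    region: str
    repeat: str
    coding: CodingEffect | None
    gene_ids: tuple[str, ...]

    @property
    def coding_effect(self) -> str:
        return self.coding.kind if self.coding else "noncoding"


def classify_events(
    sites: list[CandidateSite],
    annotations: AnnotationBundle,
    genome: ReferenceGenome,
) -> list[EditingEvent]:
    index = RegionIndex(annotations)
    rep_trees = annotations.repeat_trees()
    events = []
    for site in sites:
        cls, family = classify_substitution(site.ref, site.alt)
        region = index.classify(site.chrom, site.pos)
        coding = (
            annotate_coding_effect(site, annotations, genome, index)
            if region == "exonic"
            else None
        )
        events.append(
            EditingEvent(
                site=site,
                substitution=cls,
                family=family,
                region=region,
                repeat=classify_repeat(site, annotations, rep_trees),
                coding=coding,
                gene_ids=tuple(index.genes_at(site.chrom, site.pos)),
            )
        )
    return events


# ---------------------------------------------------------------------------
# summaries


def _fraction_table(labels: list[str], order: list[str] | None = None) -> pd.DataFrame:
    counts = pd.Series(labels).value_counts()
    if order:
        counts = counts.reindex([o for o in order if o in counts.index])
    return pd.DataFrame(
        {"count": counts.astype(int), "fraction": counts / counts.sum()}
    )


def distribution_summary(events: list[EditingEvent]) -> dict[str, pd.DataFrame]:
    """Fractions of events by repeat class, region, substitution class and
    family, plus family×region and family×repeat cross-tables.

    Fractions in each table sum to 1.
    """
    if not events:
        raise ValueError("no events to summarize")
    out = {
        "repeat": _fraction_table([e.repeat for e in events], REPEAT_CLASSES),
        "region": _fraction_table([e.region for e in events], REGIONS),
        "substitution": _fraction_table([e.substitution for e in events]),
        "family": _fraction_table([e.family for e in events], FAMILIES),
    }
    df = pd.DataFrame(
        {
            "family": [e.family for e in events],
            "region": [e.region for e in events],
            "repeat": [e.repeat for e in events],
        }
    )
    out["family_by_region"] = pd.crosstab(df["family"], df["region"], normalize="all")
    out["family_by_repeat"] = pd.crosstab(df["family"], df["repeat"], normalize="all")
    return out


def ratio_cdf(groups: dict[str, list[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical CDFs of editing ratios on the pooled grid, plus pairwise
    Mann–Whitney p-values between groups."""
    from .differential import mann_whitney_u

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {}
    for name, values in groups.items():
        vals = [v for v in values if not math.isnan(v)]
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        clean[name] = np.sort(vals)
    grid = np.unique(np.concatenate(list(clean.values())))
    ecdf = pd.DataFrame(
        {name: np.searchsorted(v, grid, side="right") / len(v) for name, v in clean.items()},
        index=pd.Index(grid, name="ratio"),
    )
    names = sorted(clean)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        res = mann_whitney_u(list(clean[a]), list(clean[b]))
        pmat.loc[a, b] = pmat.loc[b, a] = res.p
    return ecdf, pmat
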