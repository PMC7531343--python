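"""Candidate editing-site calling and the artifact-filter cascade.

From per-sample pileups, a naive mismatch caller proposes candidate sites,
which are then passed through the filters that remove the classic sources
of spurious "editing": known germline polymorphisms, random-hexamer
priming errors at read starts, splice-junction alignment artifacts,
homopolymer slippage, and paralogous (multi-locus) sequence.

Each filter is a contraction (output ⊆ input) and idempotent; a
:class:`FilterTrace` records which filter removed each site so that counts
are conserved across the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    AnnotationBundle,
    PileupColumn,
    ReferenceGenome,
    SnpSet,
    revcomp,
)

BASES = "ACGT"


@dataclass(frozen=True, order=True)
class CandidateSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"bases must be one of {BASES}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ScreenConfig:
    min_alt_reads: int = 2
    read_trim: int = 6  # discard observations in the first N bases of a read
    splice_window: int = 4  # remove sites within N bp of a splice junction
    homopolymer_min: int = 5  # minimal run length that disqualifies a site
    homopolymer_adjacent: bool = True  # also remove sites flanking (±1) a run
    multilocus_flank: int = 50
    multilocus_max_mismatches: int = 2
    multilocus_seed_k: int = 20
    snp_match_mode: str = "position"  # 'position' (stricter) or 'allele'


FILTER_ORDER = ("known_snp", "read_position", "splice_proximal", "homopolymer", "multilocus")


@dataclass
class FilterTrace:
    """Per-run audit: which filter removed which site.

    ``n_input`` counts candidate sites before any filtering; removals plus
    survivors always reconstruct it.
    """

    n_input: int = 0
    removed: dict[str, list[CandidateSite]] = field(
        default_factory=lambda: {name: [] for name in FILTER_ORDER}
    )
    survivors: list[CandidateSite] = field(default_factory=list)

    def removal_counts(self) -> dict[str, int]:
        return {name: len(sites) for name, sites in self.removed.items()}

    def check_conservation(self) -> bool:
        return self.n_input == sum(self.removal_counts().values()) + len(self.survivors)

    def removing_filter(self, site: CandidateSite) -> str | None:
        for name, sites in self.removed.items():
            if site in sites:
                return name
        return None


# ---------------------------------------------------------------------------
# calling


def apply_read_position_filter(column: PileupColumn, trim: int = 6) -> PileupColumn:
    """Drop observations from the first ``trim`` bases of their read.

    Mismatches there are dominated by random-hexamer priming errors; both
    reference and alternate support are trimmed alike, leaving the editing
    ratio unbiased.
    """
    if trim <= 0:
        return column
    keep = [i for i, off in enumerate(column.offsets) if off > trim]
    return PileupColumn(
        column.chrom,
        column.pos,
        column.ref,
        "".join(column.bases[i] for i in keep),
        tuple(column.offsets[i] for i in keep),
    )


def _alt_counts(column: PileupColumn) -> dict[str, int]:
    counts: dict[str, int] = {}
    for b in column.bases:
        if b != column.ref and b in BASES:  # N observations ignored
            counts[b] = counts.get(b, 0) + 1
    return counts


def call_candidates(
    columns: list[PileupColumn],
    genome: ReferenceGenome | None = None,
    min_alt_reads: int = 2,
    trim: int = 6,
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Naive per-alt mismatch caller for one sample.

    Returns ``(candidates, trim_casualties)``: sites whose alternate support
    reaches ``min_alt_reads`` after the read-position filter, and sites that
    reached it only before trimming (attributed to the read-position filter
    by :func:`run_screen`).
    """
    candidates: list[CandidateSite] = []
    casualties: list[CandidateSite] = []
    for col in columns:
        if genome is not None and col.ref != genome.base(col.chrom, col.pos):
            raise ValueError(
                f"{col.chrom}:{col.pos}: pileup ref {col.ref!r} disagrees with genome"
            )
        if col.ref not in BASES:
            continue
        pre = _alt_counts(col)
        if not pre:
            continue
        post = _alt_counts(apply_read_position_filter(col, trim))
        for alt, n_pre in pre.items():
            if post.get(alt, 0) >= min_alt_reads:
                candidates.append(CandidateSite(col.chrom, col.pos, col.ref, alt))
            elif n_pre >= min_alt_reads:
                casualties.append(CandidateSite(col.chrom, col.pos, col.ref, alt))
    return candidates, casualties


# ---------------------------------------------------------------------------
# site-level filters


def filter_known_snps(
    sites: list[CandidateSite], known: SnpSet, mode: str = "position"
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Subtract known germline polymorphisms (dbSNP-style lists).

    'position' mode (default, stricter) removes any candidate at a known
    position; 'allele' mode requires the (ref, alt) pair to match too.
    """
    if mode not in ("position", "allele"):
        raise ValueError(f"unknown snp match mode {mode!r}")
    if mode == "position":
        known_keys = known.positions()
        hit = lambda s: (s.chrom, s.pos) in known_keys  # noqa: E731
    else:
        hit = lambda s: (s.chrom, s.pos, s.ref, s.alt) in known  # noqa: E731
    kept = [s for s in sites if not hit(s)]
    removed = [s for s in sites if hit(s)]
    return kept, removed


def junction_distance(
    chrom: str, pos: int, junction_positions: dict[str, list[int]]
) -> float:
    """Distance in bases to the nearest splice-junction boundary (inf if none)."""
    positions = junction_positions.get(chrom)
    if not positions:
        return float("inf")
    arr = np.asarray(positions)
    i = int(np.searchsorted(arr, pos))
    best = float("inf")
    for j in (i - 1, i):
        if 0 <= j < len(arr):
            best = min(best, abs(pos - int(arr[j])))
    return best


def filter_splice_proximal(
    sites: list[CandidateSite], annotations: AnnotationBundle, window: int = 4
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Remove sites within ``window`` bp (inclusive) of any splice junction."""
    junctions = annotations.junction_positions()
    kept, removed = [], []
    for s in sites:
        (removed if junction_distance(s.chrom, s.pos, junctions) <= window else kept).append(s)
    return kept, removed


def homopolymer_hit(
    genome: ReferenceGenome,
    chrom: str,
    pos: int,
    min_run: int = 5,
    adjacent: bool = True,
) -> bool:
    """True iff the position lies inside (or, with ``adjacent``, within ±1 of)
    a maximal run of ≥ ``min_run`` identical reference bases."""
    seq = genome[chrom]
    n = len(seq)
    if not 1 <= pos <= n:
        raise IndexError(f"{chrom}:{pos} outside contig")
    probe = (pos - 1, pos, pos + 1) if adjacent else (pos,)
    for p in probe:
        if not 1 <= p <= n:
            continue
        base = seq[p - 1]
        lo = p
        while lo > 1 and seq[lo - 2] == base:
            lo -= 1
        hi = p
        while hi < n and seq[hi] == base:
            hi += 1
        if hi - lo + 1 >= min_run:
            return True
    return False


def filter_homopolymer(
    sites: list[CandidateSite],
    genome: ReferenceGenome,
    min_run: int = 5,
    adjacent: bool = True,
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    kept, removed = [], []
    for s in sites:
        (removed if homopolymer_hit(genome, s.chrom, s.pos, min_run, adjacent) else kept).append(s)
    return kept, removed


class MultilocusIndex:
    """Exact k-mer seed index over the genome for duplicate-window detection.

    Stand-in for a BLAT similarity search: a site is multi-locus if the
    window around it re-occurs elsewhere in the genome (either strand) with
    at most ``max_mismatches`` substitutions.  Non-overlapping k-mer seeds
    guarantee detection: with ≤2 mismatches in a ~100 bp window at k=20, at
    least one seed is untouched.
    """

    def __init__(self, genome: ReferenceGenome, k: int = 20):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def _window(self, chrom: str, pos: int, flank: int) -> tuple[str, int]:
        """Window around pos, shrunk symmetrically at contig edges.

        Returns (sequence, 0-based start).
        """
        seq = self.genome[chrom]
        w = min(flank, pos - 1, len(seq) - pos)
        start = pos - 1 - w
        return seq[start : pos + w], start

    def has_second_locus(
        self, chrom: str, pos: int, flank: int = 50, max_mismatches: int = 2
    ) -> bool:
        window, w_start = self._window(chrom, pos, flank)
        wlen = len(window)
        if wlen < self.k:
            return False
        seed_starts = list(range(0, wlen - self.k + 1, self.k))
        if seed_starts[-1] != wlen - self.k:
            seed_starts.append(wlen - self.k)

        def near_self(c: str, cand_start: int) -> bool:
            return c == chrom and cand_start < w_start + wlen and cand_start + wlen > w_start

        for probe, is_rc in ((window, False), (revcomp(window), True)):
            checked: set[tuple[str, int]] = set()
            for o in seed_starts:
                for c, i in self._index.get(probe[o : o + self.k], ()):
                    cand_start = i - o
                    if cand_start < 0 or (c, cand_start) in checked:
                        continue
                    checked.add((c, cand_start))
                    if near_self(c, cand_start):
                        continue  # the site's own locus never counts
                    seg = self.genome[c][cand_start : cand_start + wlen]
                    if len(seg) < wlen:
                        continue
                    mism = sum(a != b for a, b in zip(seg, probe))
                    if mism <= max_mismatches:
                        return True
        return False


def filter_multilocus(
    sites: list[CandidateSite],
    genome: ReferenceGenome,
    flank: int = 50,
    max_mismatches: int = 2,
    k: int = 20,
    index: MultilocusIndex | None = None,
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    if index is None:
        index = MultilocusIndex(genome, k=k)
    kept, removed = [], []
    for s in sites:
        if index.has_second_locus(s.chrom, s.pos, flank, max_mismatches):
            removed.append(s)
        else:
            kept.append(s)
    return kept, removed


# ---------------------------------------------------------------------------
# the cascade


def run_screen(
    pileups: dict[str, list[PileupColumn]],
    annotations: AnnotationBundle,
    genome: ReferenceGenome,
    config: ScreenConfig | None = None,
) -> tuple[list[CandidateSite], FilterTrace]:
    """Call candidates across samples and run the full filter cascade.

    Candidates are the union over samples of per-sample calls; a site whose
    alternate support survives trimming in no sample, but reached the
    calling threshold before trimming in some sample, is attributed to the
    read-position filter.  Filters then run in the fixed order
    known-SNP → read-position → splice-proximal → homopolymer → multi-locus.
    """
    cfg = config or ScreenConfig()
    called: set[CandidateSite] = set()
    pre_only: set[CandidateSite] = set()
    for _sample, columns in sorted(pileups.items()):
        cands, casualties = call_candidates(
            columns, genome, cfg.min_alt_reads, cfg.read_trim
        )
        called.update(cands)
        pre_only.update(casualties)
    pre_only -= called

    trace = FilterTrace(n_input=len(called) + len(pre_only))
    sites = sorted(called)

    sites, removed = filter_known_snps(sites, annotations.known_snps, cfg.snp_match_mode)
    trace.removed["known_snp"] = removed
    # pre-trim-only candidates that are also known SNPs were caught above;
    # the rest fell to the read-position filter
    trim_removed, _ = filter_known_snps(
        sorted(pre_only), annotations.known_snps, cfg.snp_match_mode
    )
    trace.removed["known_snp"].extend(sorted(pre_only - set(trim_removed)))
    trace.removed["read_position"] = trim_removed

    sites, removed = filter_splice_proximal(sites, annotations, cfg.splice_window)
    trace.removed["splice_proximal"] = removed

    sites, removed = filter_homopolymer(
        sites, genome, cfg.homopolymer_min, cfg.homopolymer_adjacent
    )
    trace.removed["homopolymer"] = removed

    sites, removed = filter_multilocus(
        sites,
        genome,
        cfg.multilocus_flank,
        cfg.multilocus_max_mismatches,
        cfg.multilocus_seed_k,
    )
    trace.removed["multilocus"] = removed

    trace.survivors = sites
    assert trace.check_conservation()
    return sites, trace
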