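"""Synthetic control-vs-tumor editing cohort with planted ground truth.

Generates a toy genome (multi-exon coding genes on both strands, ncRNA
genes, diverged Alu-like repeat copies including inverted pairs, non-Alu
repeats, homopolymer runs, one exactly duplicated locus pair), plants
editing sites, germline SNPs and one artifact site class per filter, and
simulates per-sample pileups with read-level noise.

The defaults emulate the cohort structure this pipeline targets: heavily
edited control samples (per-sample true ratios ~ Beta(8,2), mean 0.8)
versus tumor samples with a strong loss of editing (Beta(2,6), mean 0.25,
most samples below the 0.2 high-confidence gate),
editing sites concentrated in Alu elements, heterozygous SNPs at allelic
ratio 0.5 in carriers, and sequencing depth that is negative-binomially
overdispersed around 30×.

Everything is deterministic under a fixed seed; each stage draws from an
independently forked stream so toggling one stage does not perturb
another's draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    AnnotationBundle,
    PileupColumn,
    ReferenceGenome,
    RepeatInterval,
    SnpSet,
    Transcript,
    revcomp,
    write_fasta,
    write_gtf,
    write_known_sites_vcf,
    write_manifest,
    write_pileup,
    write_repeats_bed,
)
from .screen import CandidateSite, homopolymer_hit, junction_distance

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent deterministic stream for one pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass
class SimConfig:
    seed: int = 0
    n_control: int = 20
    n_tumor: int = 20
    n_chroms: int = 2
    chrom_length: int = 100_000
    # genome features
    n_coding_genes: int = 6
    n_ncrna_genes: int = 2
    alu_density: float = 0.15
    alu_divergence: float = 0.10
    n_other_repeats: int = 8
    n_homopolymer_runs: int = 24
    dup_locus_length: int = 200
    # planted signal
    n_edit_sites: int = 100
    n_coding_edit_sites: int = 4
    alu_bias: float = 0.9
    ctou_fraction: float = 0.0
    control_beta: tuple[float, float] = (8.0, 2.0)
    tumor_beta: tuple[float, float] = (2.0, 6.0)
    n_snps: int = 30
    snp_carrier_frequency: float = 0.3
    n_artifact_splice: int = 20
    n_artifact_homopolymer: int = 20
    n_artifact_multilocus: int = 20
    n_artifact_hexamer: int = 20
    artifact_beta: tuple[float, float] = (8.0, 2.0)
    n_background_sites: int = 200
    # read-level model
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    base_error_rate: float = 0.001
    read_length: int = 100
    flank_bp: int = 1000

    def __post_init__(self) -> None:
        errors = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("n_") and (not isinstance(v, int) or v < 0):
                errors.append(f"{f.name} must be a non-negative integer")
        for name in ("alu_density", "alu_bias", "ctou_fraction",
                     "snp_carrier_frequency", "base_error_rate", "alu_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1]")
        for name in ("control_beta", "tumor_beta", "artifact_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                errors.append(f"{name} parameters must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            errors.append("depth distribution parameters must be positive")
        if self.chrom_length < 5000:
            errors.append("chrom_length must be at least 5000")
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def samples(self) -> list[str]:
        return [f"control_{i+1:02d}" for i in range(self.n_control)] + [
            f"tumor_{i+1:02d}" for i in range(self.n_tumor)
        ]

    @property
    def manifest(self) -> dict[str, str]:
        return {
            s: ("control" if s.startswith("control") else "tumor")
            for s in self.samples
        }


@dataclass
class GenomeLayout:
    """Bookkeeping the planting step needs about the built genome."""

    homopolymer_runs: list[tuple[str, int, int]] = field(default_factory=list)
    dup_loci: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based
    intron_intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    genome: ReferenceGenome
    annotations: AnnotationBundle
    layout: GenomeLayout


# ---------------------------------------------------------------------------
# genome construction


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


class _Occupancy:
    """Per-chromosome interval bookkeeping (0-based half-open)."""

    def __init__(self) -> None:
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        self._iv.setdefault(chrom, []).append((start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self._iv.get(chrom, []))


def _make_gene(
    rng: np.random.Generator, chrom: str, cursor: int, idx: int, coding: bool, strand: str
) -> tuple[Transcript, int]:
    if coding:
        n_exons = int(rng.integers(3, 6))
        exon_lens = rng.integers(150, 300, n_exons)
        intron_lens = rng.integers(500, 1200, n_exons - 1)
        start = cursor
        exons = []
        p = start
        for i, el in enumerate(exon_lens):
            exons.append((p, p + int(el) - 1))
            p = exons[-1][1] + 1
            if i < n_exons - 1:
                p += int(intron_lens[i])
        utr = 60
        cds_lo = exons[0][0] + utr
        cds_hi = exons[-1][1] - utr
        cds = [(max(s, cds_lo), min(e, cds_hi)) for s, e in exons]
        cds = [(s, e) for s, e in cds if s <= e]
        total = sum(e - s + 1 for s, e in cds)
        trim = total % 3
        if trim:  # keep CDS length divisible by 3
            s, e = cds[-1]
            cds[-1] = (s, e - trim)
        tx = Transcript(
            transcript_id=f"TX{idx}",
            gene_id=f"GENE{idx}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=cds,
            frame=0,
            biotype="coding",
        )
    else:
        n_exons = int(rng.integers(1, 3))
        exons = []
        p = cursor
        for i in range(n_exons):
            el = int(rng.integers(200, 500))
            exons.append((p, p + el - 1))
            p = exons[-1][1] + 1 + (int(rng.integers(400, 900)) if i < n_exons - 1 else 0)
        tx = Transcript(
            transcript_id=f"NC{idx}",
            gene_id=f"NCGENE{idx}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            biotype="ncRNA",
        )
    return tx, tx.end + 1


def build_genome(config: SimConfig) -> SyntheticGenome:
    """Toy genome plus consistent annotations.

    Deterministic: the same config (seed included) yields byte-identical
    FASTA/GTF/BED on write.
    """
    rng = stage_rng(config.seed, "genome")
    chroms = [f"chr{i+1}" for i in range(config.n_chroms)]
    seqs = {c: _random_seq(rng, config.chrom_length) for c in chroms}
    layout = GenomeLayout()
    transcripts: list[Transcript] = []
    repeats: list[RepeatInterval] = []
    cds_zone = _Occupancy()
    planted = _Occupancy()
    gene_zone = _Occupancy()

    # --- genes, round-robin across chromosomes
    specs = [True] * config.n_coding_genes + [False] * config.n_ncrna_genes
    cursors = {c: 2500 + int(rng.integers(0, 1500)) for c in chroms}
    for idx, coding in enumerate(specs, start=1):
        chrom = chroms[(idx - 1) % len(chroms)]
        strand = "+" if idx % 2 else "-"
        tx, end = _make_gene(rng, chrom, cursors[chrom], idx, coding, strand)
        if end + 2000 > config.chrom_length:
            raise ValueError("requested gene features exceed genome length")
        cursors[chrom] = end + 4000 + int(rng.integers(0, 2000))
        transcripts.append(tx)
        gene_zone.add(chrom, tx.start - 1, tx.end)
        for s, e in tx.cds:
            cds_zone.add(chrom, s - 4, e + 3)
        exs = tx.exons
        for i in range(len(exs) - 1):
            layout.intron_intervals.append((chrom, exs[i][1] + 1, exs[i + 1][0] - 1))

    # --- Alu-like repeats (diverged copies of one consensus; some inverted pairs)
    alu_consensus = _random_seq(rng, 300)
    alu_n = 0

    def plant_repeat(chrom: str, start0: int, seq: np.ndarray, name: str) -> None:
        nonlocal alu_n
        seqs[chrom][start0 : start0 + len(seq)] = seq
        planted.add(chrom, start0, start0 + len(seq))
        repeats.append(RepeatInterval(chrom, start0 + 1, start0 + len(seq), name))

    def try_place(chrom: str, start0: int, length: int) -> bool:
        if start0 < 0 or start0 + length > config.chrom_length:
            return False
        return not (
            cds_zone.overlaps(chrom, start0, start0 + length)
            or planted.overlaps(chrom, start0, start0 + length)
        )

    if config.alu_density > 0:
        # one guaranteed inverted pair inside a long-enough intron per chromosome
        for chrom in chroms:
            for ic, s, e in layout.intron_intervals:
                if ic != chrom or e - s + 1 < 740:
                    continue
                start0 = s - 1 + 10
                gap = 100
                if try_place(chrom, start0, 300) and try_place(chrom, start0 + 300 + gap, 300):
                    fwd = _mutate(rng, alu_consensus, config.alu_divergence)
                    rev = _mutate(rng, alu_consensus, config.alu_divergence)
                    rev = np.frombuffer(
                        revcomp(rev.tobytes().decode()).encode(), dtype="S1"
                    ).copy()
                    alu_n += 1
                    plant_repeat(chrom, start0, fwd, f"AluSyn{alu_n}")
                    alu_n += 1
                    plant_repeat(chrom, start0 + 300 + gap, rev, f"AluSyn{alu_n}")
                    break
        # density-driven placement elsewhere
        for chrom in chroms:
            target = int(config.alu_density * config.chrom_length)
            placed = sum(r.end - r.start + 1 for r in repeats if r.chrom == chrom)
            attempts = 0
            while placed < target and attempts < 40 * config.chrom_length // 300:
                attempts += 1
                start0 = int(rng.integers(0, config.chrom_length - 300))
                if not try_place(chrom, start0, 300):
                    continue
                copy = _mutate(rng, alu_consensus, config.alu_divergence)
                if rng.random() < 0.5:
                    copy = np.frombuffer(
                        revcomp(copy.tobytes().decode()).encode(), dtype="S1"
                    ).copy()
                alu_n += 1
                plant_repeat(chrom, start0, copy, f"AluSyn{alu_n}")
                placed += 300

    # --- non-Alu repeats
    l1_consensus = _random_seq(rng, 400)
    for i in range(config.n_other_repeats):
        chrom = chroms[i % len(chroms)]
        for _ in range(200):
            start0 = int(rng.integers(0, config.chrom_length - 400))
            if try_place(chrom, start0, 400):
                plant_repeat(
                    chrom, start0, _mutate(rng, l1_consensus, 0.1), f"L1Syn{i+1}"
                )
                break

    # --- homopolymer runs
    for i in range(config.n_homopolymer_runs):
        chrom = chroms[i % len(chroms)]
        run_len = int(rng.integers(5, 9))
        for _ in range(200):
            start0 = int(rng.integers(10, config.chrom_length - run_len - 10))
            if cds_zone.overlaps(chrom, start0, start0 + run_len) or planted.overlaps(
                chrom, start0 - 1, start0 + run_len + 1
            ):
                continue
            base = _BASES[rng.integers(0, 4)]
            seqs[chrom][start0 : start0 + run_len] = base
            planted.add(chrom, start0, start0 + run_len)
            layout.homopolymer_runs.append((chrom, start0 + 1, start0 + run_len))
            break

    # --- one exactly duplicated locus pair, intergenic on both ends
    dlen = config.dup_locus_length

    def free_for_dup(chrom: str, start0: int) -> bool:
        return (
            0 <= start0
            and start0 + dlen <= config.chrom_length
            and not gene_zone.overlaps(chrom, start0 - 10, start0 + dlen + 10)
            and not planted.overlaps(chrom, start0 - 10, start0 + dlen + 10)
        )

    src = dst = None
    for _ in range(2000):
        c1 = chroms[int(rng.integers(0, len(chroms)))]
        s1 = int(rng.integers(0, config.chrom_length - dlen))
        if not free_for_dup(c1, s1):
            continue
        c2 = chroms[int(rng.integers(0, len(chroms)))]
        s2 = int(rng.integers(0, config.chrom_length - dlen))
        if not free_for_dup(c2, s2) or (c1 == c2 and abs(s1 - s2) < dlen + 120):
            continue
        src, dst = (c1, s1), (c2, s2)
        break
    if src is None:
        raise ValueError("could not place the duplicated locus pair")
    seqs[dst[0]][dst[1] : dst[1] + dlen] = seqs[src[0]][src[1] : src[1] + dlen]
    for c, s0 in (src, dst):
        planted.add(c, s0, s0 + dlen)
        layout.dup_loci.append((c, s0 + 1, s0 + dlen))

    genome = ReferenceGenome({c: seqs[c].tobytes().decode() for c in chroms})
    from .formats_io import derive_junctions

    annotations = AnnotationBundle(
        transcripts=transcripts,
        splice_junctions=derive_junctions(transcripts),
        repeats=sorted(repeats, key=lambda r: (r.chrom, r.start)),
        known_snps=SnpSet(),
        flank_bp=config.flank_bp,
    )
    return SyntheticGenome(genome=genome, annotations=annotations, layout=layout)


# ---------------------------------------------------------------------------
# truth planting


@dataclass
class PlantedSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    category: str  # 'edit' | 'snp' | artifact category
    ratios: np.ndarray  # per-sample true alt fraction, sample order of config.samples

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


ARTIFACT_CATEGORIES = ("splice", "homopolymer", "multilocus", "hexamer")


@dataclass
class CohortTruth:
    samples: list[str]
    groups: dict[str, str]
    edits: list[PlantedSite]
    snps: list[PlantedSite]
    snp_carriers: dict[tuple[str, int], list[str]]
    artifacts: list[PlantedSite]

    def all_sites(self) -> list[PlantedSite]:
        return [*self.edits, *self.snps, *self.artifacts]

    def edit_keys(self) -> set[tuple[str, int, str, str]]:
        return {s.key for s in self.edits}

    def positions_by_category(self) -> dict[str, set[tuple[str, int]]]:
        out: dict[str, set[tuple[str, int]]] = {"edit": set(), "snp": set()}
        for cat in ARTIFACT_CATEGORIES:
            out[cat] = set()
        for s in self.all_sites():
            out[s.category].add((s.chrom, s.pos))
        return out

    def group_mean(self, site: PlantedSite, group: str) -> float:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        return float(site.ratios[idx].mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.all_sites():
            rows.append(
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "category": s.category,
                    "mean_ratio_control": self.group_mean(s, "control"),
                    "mean_ratio_tumor": self.group_mean(s, "tumor"),
                    "carriers": ",".join(
                        self.snp_carriers.get((s.chrom, s.pos), [])
                    ),
                }
            )
        return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


def _eligible(
    syn: SyntheticGenome,
    chrom: str,
    pos: int,
    used: set[tuple[str, int]],
    junctions: dict[str, list[int]],
    dup_zones: list[tuple[str, int, int]],
    min_junction_dist: int = 6,
) -> bool:
    """Clean-site predicate: far from junctions, outside homopolymers,
    outside the duplicated-locus ±flank zone, unused."""
    if (chrom, pos) in used:
        return False
    if junction_distance(chrom, pos, junctions) < min_junction_dist:
        return False
    if homopolymer_hit(syn.genome, chrom, pos):
        return False
    for c, s, e in dup_zones:
        if c == chrom and s <= pos <= e:
            return False
    return True


def plant_sites(syn: SyntheticGenome, config: SimConfig) -> CohortTruth:
    """Plant editing sites (Alu-biased), SNPs and artifact sites.

    Categories are disjoint by position, and each artifact site satisfies
    exactly the geometric predicate of its own filter.
    """
    rng = stage_rng(config.seed, "plant")
    genome, ann = syn.genome, syn.annotations
    junctions = ann.junction_positions()
    rep_trees = ann.repeat_trees()
    samples = config.samples
    groups = config.manifest
    ctrl_idx = np.array([groups[s] == "control" for s in samples])
    dup_margin = 60  # multilocus flank (50) plus slack
    dup_zones = [
        (c, max(1, s - dup_margin), e + dup_margin) for c, s, e in syn.layout.dup_loci
    ]
    used: set[tuple[str, int]] = set()
    chroms = list(genome.sequences)

    def in_alu(chrom: str, pos: int) -> bool:
        tree = rep_trees.get(chrom)
        return bool(tree and any(iv.data == "Alu" for iv in tree[pos]))

    def draw_ratios(beta_c: tuple[float, float], beta_t: tuple[float, float]) -> np.ndarray:
        r = np.empty(len(samples))
        r[ctrl_idx] = rng.beta(*beta_c, ctrl_idx.sum())
        r[~ctrl_idx] = rng.beta(*beta_t, (~ctrl_idx).sum())
        return r

    def edited_alleles(chrom: str, pos: int) -> tuple[str, str] | None:
        ref = genome.base(chrom, pos)
        if rng.random() < config.ctou_fraction:
            if ref in ("C", "G"):
                return ref, _TRANSITION[ref]
            return None
        if ref in ("A", "T"):
            return ref, _TRANSITION[ref]
        return None

    def sample_clean_position(require_alu: bool | None) -> tuple[str, int, str, str]:
        alu_ivs = [r for r in ann.repeats if r.family == "Alu"]
        for _ in range(200_000):
            if require_alu and alu_ivs:
                r = alu_ivs[int(rng.integers(0, len(alu_ivs)))]
                pos = int(rng.integers(r.start, r.end + 1))
                chrom = r.chrom
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                pos = int(rng.integers(1, genome.length(chrom) + 1))
                if require_alu is False and in_alu(chrom, pos):
                    continue
            alleles = edited_alleles(chrom, pos)
            if alleles is None:
                continue
            if _eligible(syn, chrom, pos, used, junctions, dup_zones):
                return chrom, pos, *alleles
        raise ValueError("insufficient eligible positions for a clean site")

    # --- editing sites: a coding quota, then Alu-biased placement
    edits: list[PlantedSite] = []
    cds_positions = []
    for tx in ann.transcripts:
        for s, e in tx.cds:
            cds_positions.extend((tx.chrom, p) for p in range(s, e + 1))
    rng.shuffle(cds_positions)
    for chrom, pos in cds_positions:
        if len(edits) >= min(config.n_coding_edit_sites, config.n_edit_sites):
            break
        alleles = edited_alleles(chrom, pos)
        if alleles is None or not _eligible(syn, chrom, pos, used, junctions, dup_zones):
            continue
        used.add((chrom, pos))
        edits.append(
            PlantedSite(chrom, pos, *alleles, "edit",
                        draw_ratios(config.control_beta, config.tumor_beta))
        )
    while len(edits) < config.n_edit_sites:
        want_alu = bool(rng.random() < config.alu_bias)
        chrom, pos, ref, alt = sample_clean_position(want_alu)
        used.add((chrom, pos))
        edits.append(
            PlantedSite(chrom, pos, ref, alt, "edit",
                        draw_ratios(config.control_beta, config.tumor_beta))
        )

    # --- germline SNPs: allelic ratio 0.5 in carriers, 0 elsewhere
    snps: list[PlantedSite] = []
    carriers: dict[tuple[str, int], list[str]] = {}
    for _ in range(config.n_snps):
        for _ in range(100_000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, genome.length(chrom) + 1))
            ref = genome.base(chrom, pos)
            if ref == "N" or not _eligible(syn, chrom, pos, used, junctions, dup_zones):
                continue
            others = [b for b in "ACGT" if b != ref]
            alt = others[int(rng.integers(0, 3))]
            break
        else:
            raise ValueError("insufficient eligible positions for SNPs")
        carry = rng.random(len(samples)) < config.snp_carrier_frequency
        if not carry.any():
            carry[int(rng.integers(0, len(samples)))] = True
        used.add((chrom, pos))
        snps.append(PlantedSite(chrom, pos, ref, alt, "snp", np.where(carry, 0.5, 0.0)))
        carriers[(chrom, pos)] = [s for s, c in zip(samples, carry) if c]
        ann.known_snps.add((chrom, pos, ref, alt))

    # --- artifact sites, one class per filter
    artifacts: list[PlantedSite] = []

    def artifact_ratios() -> np.ndarray:
        return rng.beta(*config.artifact_beta, len(samples))

    def add_artifact(chrom: str, pos: int, category: str) -> None:
        ref = genome.base(chrom, pos)
        alt = _TRANSITION.get(ref)
        used.add((chrom, pos))
        artifacts.append(PlantedSite(chrom, pos, ref, alt, category, artifact_ratios()))

    # splice-proximal: within 4 bp of a junction, clean otherwise
    splice_cands = []
    for chrom, positions in junctions.items():
        for j in positions:
            for d in range(1, 5):
                for pos in (j - d, j + d):
                    if not 1 <= pos <= genome.length(chrom):
                        continue
                    if (chrom, pos) in used or genome.base(chrom, pos) == "N":
                        continue
                    if homopolymer_hit(genome, chrom, pos):
                        continue
                    if any(c == chrom and s <= pos <= e for c, s, e in dup_zones):
                        continue
                    splice_cands.append((chrom, pos))
    splice_cands = sorted(set(splice_cands))
    if len(splice_cands) < config.n_artifact_splice:
        raise ValueError("insufficient eligible positions for splice artifacts")
    for i in rng.choice(len(splice_cands), config.n_artifact_splice, replace=False):
        add_artifact(*splice_cands[int(i)], "splice")

    # homopolymer: inside or ±1 of a planted run, away from junctions
    hp_cands = []
    for chrom, s, e in syn.layout.homopolymer_runs:
        for pos in range(s - 1, e + 2):
            if not 1 <= pos <= genome.length(chrom) or (chrom, pos) in used:
                continue
            if junction_distance(chrom, pos, junctions) < 6:
                continue
            if any(c == chrom and ds <= pos <= de for c, ds, de in dup_zones):
                continue
            if genome.base(chrom, pos) != "N":
                hp_cands.append((chrom, pos))
    hp_cands = sorted(set(hp_cands))
    if len(hp_cands) < config.n_artifact_homopolymer:
        raise ValueError("insufficient eligible positions for homopolymer artifacts")
    for i in rng.choice(len(hp_cands), config.n_artifact_homopolymer, replace=False):
        add_artifact(*hp_cands[int(i)], "homopolymer")

    # multilocus: deep inside the duplicated locus so the whole ±50 bp
    # window lies within the duplication
    ml_cands = []
    for chrom, s, e in syn.layout.dup_loci:
        for pos in range(s + 50, e - 50 + 1):
            if (chrom, pos) in used or homopolymer_hit(genome, chrom, pos):
                continue
            if junction_distance(chrom, pos, junctions) < 6:
                continue
            ml_cands.append((chrom, pos))
    ml_cands = sorted(set(ml_cands))
    if len(ml_cands) < config.n_artifact_multilocus:
        raise ValueError("insufficient eligible positions for multilocus artifacts")
    for i in rng.choice(len(ml_cands), config.n_artifact_multilocus, replace=False):
        add_artifact(*ml_cands[int(i)], "multilocus")

    # hexamer-only: geometrically clean; the read simulator confines all
    # alternate observations to read offsets ≤ 6
    for _ in range(config.n_artifact_hexamer):
        chrom, pos, ref, alt = sample_clean_position(None)
        used.add((chrom, pos))
        artifacts.append(PlantedSite(chrom, pos, ref, alt, "hexamer", artifact_ratios()))

    return CohortTruth(
        samples=samples,
        groups=groups,
        edits=edits,
        snps=snps,
        snp_carriers=carriers,
        artifacts=artifacts,
    )


# ---------------------------------------------------------------------------
# pileup simulation


def simulate_pileups(
    syn: SyntheticGenome,
    truth: CohortTruth,
    config: SimConfig,
    out_dir: str | Path | None = None,
    stage: str = "pileups",
) -> dict[str, list[PileupColumn]]:
    """Per-sample pileup columns at all planted sites plus background
    positions.

    Depth ~ NegativeBinomial(mean, dispersion); alternate reads ~
    Binomial(depth, true ratio); each remaining reference read flips to a
    uniform other base with probability ``base_error_rate``.  Read offsets
    are uniform over the read length, except that hexamer-artifact
    alternate reads start within the first six bases.
    """
    rng = stage_rng(config.seed, stage)
    genome = syn.genome
    chroms = list(genome.sequences)
    used = {(s.chrom, s.pos) for s in truth.all_sites()}
    background: list[tuple[str, int]] = []
    while len(background) < config.n_background_sites:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(1, genome.length(chrom) + 1))
        if (chrom, pos) in used or genome.base(chrom, pos) == "N":
            continue
        used.add((chrom, pos))
        background.append((chrom, pos))

    sites: list[tuple[str, int, str, str | None, np.ndarray | None, bool]] = []
    for s in truth.all_sites():
        sites.append((s.chrom, s.pos, s.ref, s.alt, s.ratios, s.category == "hexamer"))
    for chrom, pos in background:
        sites.append((chrom, pos, genome.base(chrom, pos), None, None, False))
    sites.sort(key=lambda t: (t[0], t[1]))

    nb_n = config.depth_dispersion
    nb_p = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    pileups: dict[str, list[PileupColumn]] = {}
    for si, sample in enumerate(truth.samples):
        columns: list[PileupColumn] = []
        for chrom, pos, ref, alt, ratios, hexamer in sites:
            depth = int(rng.negative_binomial(nb_n, nb_p))
            ratio = float(ratios[si]) if ratios is not None else 0.0
            n_alt = int(rng.binomial(depth, ratio)) if ratio > 0 else 0
            n_rest = depth - n_alt
            n_err = (
                int(rng.binomial(n_rest, config.base_error_rate))
                if config.base_error_rate > 0
                else 0
            )
            err_bases = ""
            if n_err:
                # error reads never mimic the planted alternate allele
                others = [b for b in "ACGT" if b != ref and b != alt]
                err_bases = "".join(
                    others[i] for i in rng.integers(0, len(others), n_err)
                )
            bases = (alt or "") * n_alt + err_bases + ref * (n_rest - n_err)
            if hexamer and n_alt:
                alt_off = rng.integers(1, 7, n_alt)
            else:
                alt_off = rng.integers(1, config.read_length + 1, n_alt)
            rest_off = rng.integers(1, config.read_length + 1, depth - n_alt)
            offsets = tuple(int(o) for o in np.concatenate([alt_off, rest_off]))
            columns.append(PileupColumn(chrom, pos, ref, bases, offsets))
        pileups[sample] = columns

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, columns in pileups.items():
            write_pileup(columns, out_dir / f"{sample}.pileup.tsv")
    return pileups


# ---------------------------------------------------------------------------
# evaluation against truth


def evaluate_calls(
    called: set[tuple[str, int, str, str]] | list[CandidateSite],
    truth: CohortTruth,
) -> dict:
    """Sensitivity on planted edits and leakage of SNPs/artifacts."""
    keys = {c.key if isinstance(c, CandidateSite) else tuple(c) for c in called}
    called_pos = {(c, p) for c, p, _r, _a in keys}
    edit_keys = truth.edit_keys()
    tp = len(keys & edit_keys)
    recall = tp / len(edit_keys) if edit_keys else math.nan
    precision = tp / len(keys) if keys else math.nan
    leakage = {}
    for cat, positions in truth.positions_by_category().items():
        if cat == "edit":
            continue
        leakage[cat] = len(called_pos & positions)
    return {
        "n_called": len(keys),
        "n_true_edits": len(edit_keys),
        "recall": recall,
        "precision": precision,
        "leakage": leakage,
    }


# ---------------------------------------------------------------------------
# site-level benchmark generator (no genome, for statistical power studies)


def simulate_differential_benchmark(
    seed: int,
    n_control: int = 20,
    n_tumor: int = 20,
    n_null: int = 200,
    n_shifted: int = 100,
    null_beta: tuple[float, float] = (8.0, 2.0),
    control_beta: tuple[float, float] = (8.0, 2.0),
    tumor_beta: tuple[float, float] = (2.0, 6.0),
    depth_mean: float = 30.0,
    depth_dispersion: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, str], dict[int, str]]:
    """Cohort of null sites (both groups share one Beta) and shifted sites
    (tumor editing drawn from a lower Beta), as site-level calls.

    Returns (calls frame, manifest, {pos: 'null'|'shifted'}).
    """
    rng = stage_rng(seed, "benchmark")
    samples = [f"control_{i+1:02d}" for i in range(n_control)] + [
        f"tumor_{i+1:02d}" for i in range(n_tumor)
    ]
    manifest = {s: ("control" if s.startswith("control") else "tumor") for s in samples}
    is_ctrl = np.array([manifest[s] == "control" for s in samples])
    nb_n = depth_dispersion
    nb_p = depth_dispersion / (depth_dispersion + depth_mean)
    rows = []
    labels: dict[int, str] = {}
    for i in range(n_null + n_shifted):
        pos = i + 1
        shifted = i >= n_null
        labels[pos] = "shifted" if shifted else "null"
        ratios = np.empty(len(samples))
        if shifted:
            ratios[is_ctrl] = rng.beta(*control_beta, is_ctrl.sum())
            ratios[~is_ctrl] = rng.beta(*tumor_beta, (~is_ctrl).sum())
        else:
            ratios[:] = rng.beta(*null_beta, len(samples))
        depths = rng.negative_binomial(nb_n, nb_p, len(samples))
        alts = rng.binomial(depths, ratios)
        for s, d, a in zip(samples, depths, alts):
            rows.append(
                {
                    "sample": s,
                    "chrom": "chrS",
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "total_depth": int(d),
                    "alt_depth": int(a),
                    "editing_ratio": (a / d) if d else math.nan,
                }
            )
    return pd.DataFrame(rows), manifest, labels


# ---------------------------------------------------------------------------
# cohort-on-disk convenience


def toy_gene_sets(
    annotations: AnnotationBundle, truth: CohortTruth, seed: int
) -> dict[str, set[str]]:
    """Small GMT-able gene sets over the synthetic genes: one set holding
    the genes that carry planted coding edits, plus random fillers."""
    rng = stage_rng(seed, "genesets")
    genes = sorted({tx.gene_id for tx in annotations.transcripts})
    edited_coding: set[str] = set()
    for site in truth.edits:
        for tx in annotations.transcripts:
            if tx.chrom == site.chrom and any(s <= site.pos <= e for s, e in tx.cds):
                edited_coding.add(tx.gene_id)
    sets = {"EDITED_CODING": edited_coding or set(genes[:2])}
    for i in range(3):
        k = max(2, len(genes) // 2)
        members = rng.choice(genes, size=min(k, len(genes)), replace=False)
        sets[f"RANDOM_SET_{i+1}"] = set(map(str, members))
    return sets


def simulate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[SyntheticGenome, CohortTruth, dict[str, list[PileupColumn]]]:
    """Build genome, plant truth, simulate pileups; optionally write the
    full file bundle (FASTA/GTF/BED/VCF/pileups/manifest/truth/GMT)."""
    syn = build_genome(config)
    truth = plant_sites(syn, config)
    pileup_dir = Path(out_dir) / "pileups" if out_dir is not None else None
    pileups = simulate_pileups(syn, truth, config, pileup_dir)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(syn.genome, out / "genome.fa")
        write_gtf(syn.annotations.transcripts, out / "genes.gtf")
        write_repeats_bed(syn.annotations.repeats, out / "repeats.bed")
        write_known_sites_vcf(
            syn.annotations.known_snps,
            out / "known_snps.vcf",
            contigs={c: len(s) for c, s in syn.genome.sequences.items()},
        )
        write_manifest(config.manifest, out / "manifest.tsv")
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        from .enrichment import write_gmt

        write_gmt(toy_gene_sets(syn.annotations, truth, config.seed), out / "gene_sets.gmt")
    return syn, truth, pileups
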