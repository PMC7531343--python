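import math

import numpy as np
import pytest
from Bio.Seq import Seq

from editome import quantify as qt
from editome.formats_io import AnnotationBundle, ReferenceGenome, RepeatInterval, SiteCall, Transcript
from editome.screen import CandidateSite

S = CandidateSite


# ---------------------------------------------------------------------------
# editing ratio and the high-confidence gate


@pytest.mark.parametrize("alt,total,expected", [(4, 10, 0.4), (0, 10, 0.0)])
def test_editing_ratio_is_exact_quotient(alt, total, expected):
    assert qt.compute_editing_ratio(alt, total) == pytest.approx(expected)


def test_editing_ratio_undefined_at_zero_depth():
    assert math.isnan(qt.compute_editing_ratio(0, 0))


def test_editing_ratio_rejects_alt_above_total():
    with pytest.raises(ValueError):
        qt.compute_editing_ratio(11, 10)


def _call(depth, ratio):
    alt = round(depth * ratio)
    return SiteCall("s", "chr1", 1, "A", "G", depth, alt, ratio)


@pytest.mark.parametrize(
    "depth,ratio,kept",
    [
        (10, 0.25, True),  # at the depth threshold, above the ratio threshold
        (9, 0.9, False),  # one read short of coverage
        (50, 0.20, False),  # ratio exactly 0.2 is rejected (strict >)
        (10, 0.21, True),
    ],
)
def test_high_confidence_gate_boundaries(depth, ratio, kept):
    got = qt.select_high_confidence([_call(depth, ratio)])
    assert (len(got) == 1) is kept


def test_high_confidence_gate_is_monotone_in_both_thresholds():
    calls = [_call(d, r) for d in (5, 10, 20, 40) for r in (0.1, 0.2, 0.3, 0.9)]
    base = set(id(c) for c in qt.select_high_confidence(calls, 10, 0.2))
    for md, mr in [(11, 0.2), (10, 0.25), (15, 0.5)]:
        tighter = set(id(c) for c in qt.select_high_confidence(calls, md, mr))
        assert tighter <= base


# ---------------------------------------------------------------------------
# substitution family


@pytest.mark.parametrize(
    "ref,alt,family",
    [
        ("A", "G", "A-to-I"),
        ("T", "C", "A-to-I"),
        ("C", "T", "C-to-U"),
        ("G", "A", "C-to-U"),
        ("A", "C", "other"),
        ("G", "T", "other"),
    ],
)
def test_substitution_families_follow_the_unsigned_pair_rule(ref, alt, family):
    cls, fam = qt.classify_substitution(ref, alt)
    assert cls == f"{ref}>{alt}" and fam == family


# ---------------------------------------------------------------------------
# region classification


@pytest.fixture()
def region_setup():
    # plus-strand coding gene: exons [1001..1200],[2001..2400]; CDS from 1101
    # (100 bp 5'UTR) to 2300 (100 bp 3'UTR); an ncRNA at [5001..5400];
    # a second gene at [9001..9600] whose upstream flank overlaps nothing.
    coding = Transcript(
        "T1", "G1", "chr1", "+",
        exons=[(1001, 1200), (2001, 2400)],
        cds=[(1101, 1200), (2001, 2299)],
        biotype="coding",
    )
    nc = Transcript("N1", "NG1", "chr1", "+", exons=[(5001, 5400)], biotype="ncRNA")
    downstream = Transcript(
        "T2", "G2", "chr1", "+", exons=[(9001, 9600)], cds=[(9101, 9500), ],
        biotype="coding",
    )
    # a minus-strand gene whose flank extends to the right of its end
    minus = Transcript(
        "T3", "G3", "chr1", "-", exons=[(12001, 12500)], cds=[(12101, 12400)],
        biotype="coding",
    )
    ann = AnnotationBundle(
        transcripts=[coding, nc, downstream, minus], flank_bp=1000
    )
    return qt.RegionIndex(ann)


@pytest.mark.parametrize(
    "pos,region",
    [
        (1150, "exonic"),  # inside CDS
        (1050, "UTR"),  # 5'UTR
        (2350, "UTR"),  # 3'UTR
        (5100, "ncRNA"),
        (1500, "intronic"),
        (8500, "5'flank"),  # 500 bp upstream of the plus-strand TSS at 9001
        (13000, "5'flank"),  # downstream of a minus-strand gene end = its flank
        (7000, "intergenic"),
        (300, "5'flank"),  # upstream of the first gene
    ],
)
def test_region_precedence_and_flanks(region_setup, pos, region):
    assert region_setup.classify("chr1", pos) == region


def test_intron_beats_flank_of_a_neighboring_gene():
    # intron of G1 that is also within 1 kb upstream of G2's TSS
    g1 = Transcript(
        "T1", "G1", "chr1", "+", exons=[(1001, 1100), (3001, 3100)],
        cds=[(1001, 1100), (3001, 3098)], biotype="coding",
    )
    g2 = Transcript(
        "T2", "G2", "chr1", "+", exons=[(3200, 3400)], cds=[(3200, 3397)],
        biotype="coding",
    )
    index = qt.RegionIndex(AnnotationBundle(transcripts=[g1, g2], flank_bp=1000))
    assert index.classify("chr1", 2800) == "intronic"


# ---------------------------------------------------------------------------
# repeat classification


def test_repeat_precedence_alu_over_other():
    ann = AnnotationBundle(
        repeats=[
            RepeatInterval("chr1", 100, 399, "AluSx"),
            RepeatInterval("chr1", 300, 700, "L1PA2"),
        ]
    )
    assert qt.classify_repeat(S("chr1", 200, "A", "G"), ann) == "Alu"
    assert qt.classify_repeat(S("chr1", 350, "A", "G"), ann) == "Alu"  # overlap
    assert qt.classify_repeat(S("chr1", 600, "A", "G"), ann) == "non-Alu repeat"
    assert qt.classify_repeat(S("chr1", 900, "A", "G"), ann) == "non-repeat"


# ---------------------------------------------------------------------------
# coding effect


def _coding_setup():
    # single-exon plus-strand gene; CDS 21..50 encodes
    # ATG ATA GCA TGG AAA CCC GGG TTT ACG TAA
    cds = "ATGATAGCATGGAAACCCGGGTTTACGTAA"
    seq = "C" * 20 + cds + "C" * 30
    genome = ReferenceGenome({"chr1": seq})
    tx = Transcript(
        "T1", "G1", "chr1", "+", exons=[(11, 70)], cds=[(21, 50)], biotype="coding"
    )
    ann = AnnotationBundle(transcripts=[tx])
    return genome, ann


def test_ile_to_met_recoding_at_codon_wobble():
    genome, ann = _coding_setup()
    # codon 2 is ATA (Ile); editing its third base A>G gives ATG (Met)
    eff = qt.annotate_coding_effect(S("chr1", 26, "A", "G"), ann, genome)
    assert (eff.kind, eff.aa_ref, eff.protein_pos, eff.aa_alt) == ("missense", "I", 2, "M")
    assert eff.hgvs_p() == "pI2M"


def test_synonymous_edit_in_gca_codon():
    genome, ann = _coding_setup()
    # codon 3 is GCA (Ala); A>G at its third base gives GCG, still Ala
    eff = qt.annotate_coding_effect(S("chr1", 29, "A", "G"), ann, genome)
    assert eff.kind == "synonymous" and eff.aa_ref == eff.aa_alt == "A"


def _translate_diff_oracle(tx, genome, site):
    """Whole-CDS translate-and-diff on the mutated genome (oracle)."""

    def protein(g):
        parts = [g[tx.chrom][s - 1 : e] for s, e in tx.cds]
        cds = "".join(parts)
        if tx.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds[tx.frame :]).translate())

    before = protein(genome.sequences)
    seq = genome.sequences[tx.chrom]
    mutated = {
        **genome.sequences,
        tx.chrom: seq[: site.pos - 1] + site.alt + seq[site.pos :],
    }
    after = protein(mutated)
    diffs = [(i + 1, a, b) for i, (a, b) in enumerate(zip(before, after)) if a != b]
    if not diffs:
        return ("synonymous", None)
    (pos, a, b) = diffs[0]
    return ("missense", (a, pos, b))


def test_minus_strand_coding_effect_matches_translate_and_diff_oracle():
    # two-exon minus-strand gene over a fixed random-ish sequence
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 400))
    genome = ReferenceGenome({"chr1": seq})
    tx = Transcript(
        "T1", "G1", "chr1", "-",
        exons=[(51, 130), (201, 300)],
        cds=[(61, 130), (201, 290)],  # 160 bp; 160 % 3 = 1 → trim one base
        biotype="coding",
    )
    tx.cds[0] = (62, 130)  # now 159 bp, divisible by 3
    ann = AnnotationBundle(transcripts=[tx])
    checked = 0
    for pos in range(62, 131):
        ref = genome.base("chr1", pos)
        if ref not in "AT":
            continue
        site = S("chr1", pos, ref, {"A": "G", "T": "C"}[ref])
        eff = qt.annotate_coding_effect(site, ann, genome)
        kind, detail = _translate_diff_oracle(tx, genome, site)
        assert eff.kind == kind
        if kind == "missense":
            assert (eff.aa_ref, eff.protein_pos, eff.aa_alt) == detail
        checked += 1
    assert checked >= 10


def test_genomic_t_to_c_on_minus_strand_is_transcript_a_to_g():
    # the transcript-strand allele is complemented before codon editing
    cds = "ATGATAGCATAA"
    seq = "G" * 10 + str(Seq(cds).reverse_complement()) + "G" * 10
    genome = ReferenceGenome({"chr1": seq})
    tx = Transcript(
        "T1", "G1", "chr1", "-", exons=[(11, 22)], cds=[(11, 22)], biotype="coding"
    )
    ann = AnnotationBundle(transcripts=[tx])
    # codon 2 third base (transcript A at CDS index 5) sits at genomic pos 17
    # on the minus strand: genomic ref T, genomic alt C
    assert genome.base("chr1", 17) == "T"
    eff = qt.annotate_coding_effect(S("chr1", 17, "T", "C"), ann, genome)
    assert (eff.kind, eff.aa_ref, eff.protein_pos, eff.aa_alt) == ("missense", "I", 2, "M")


# ---------------------------------------------------------------------------
# distribution summaries and CDFs


def _event(ref, alt, region, repeat):
    cls, fam = qt.classify_substitution(ref, alt)
    return qt.EditingEvent(
        site=S("chr1", 1, ref, alt), substitution=cls, family=fam,
        region=region, repeat=repeat, coding=None, gene_ids=(),
    )


def test_distribution_fractions_match_counts_and_sum_to_one():
    events = (
        [_event("A", "G", "intronic", "Alu")] * 94
        + [_event("A", "G", "intronic", "non-Alu repeat")] * 2
        + [_event("A", "G", "intronic", "non-repeat")] * 4
    )
    tables = qt.distribution_summary(events)
    rep = tables["repeat"]
    assert rep.loc["Alu", "fraction"] == pytest.approx(0.94)
    assert rep.loc["non-Alu repeat", "fraction"] == pytest.approx(0.02)
    assert rep.loc["non-repeat", "fraction"] == pytest.approx(0.04)
    for name in ("repeat", "region", "substitution", "family"):
        assert tables[name]["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
    assert tables["family"].loc["A-to-I", "fraction"] == pytest.approx(1.0)
    assert tables["region"].loc["intronic", "fraction"] == pytest.approx(1.0)


def test_distribution_summary_rejects_empty():
    with pytest.raises(ValueError):
        qt.distribution_summary([])


def test_ratio_cdf_maximal_separation_and_identical_groups():
    ecdf, p = qt.ratio_cdf({"hi": [1.0, 1.0, 1.0], "lo": [0.0, 0.0, 0.0]})
    assert ecdf.loc[0.0, "lo"] == 1.0 and ecdf.loc[0.0, "hi"] == 0.0
    assert ecdf.loc[1.0, "hi"] == 1.0
    same = [0.1, 0.5, 0.9]
    _, p2 = qt.ratio_cdf({"a": same, "b": same})
    assert p2.loc["a", "b"] == pytest.approx(1.0)


def test_ratio_cdf_control_dominates_tumor_distribution():
    rng = np.random.default_rng(42)
    groups = {
        "control": list(rng.beta(8, 2, 50)),
        "tumor": list(rng.beta(3, 3, 50)),
    }
    ecdf, p = qt.ratio_cdf(groups)
    # higher editing in control: its ECDF sits at or below the tumor ECDF
    assert (ecdf["control"] <= ecdf["tumor"] + 1e-12).all()
    assert (ecdf["control"] < ecdf["tumor"]).any()
    assert p.loc["control", "tumor"] < 1e-6


def test_ratio_cdf_requires_two_groups_of_two():
    with pytest.raises(ValueError):
        qt.ratio_cdf({"a": [0.1, 0.2]})
    with pytest.raises(ValueError):
        qt.ratio_cdf({"a": [0.1, 0.2], "b": [0.3]})
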