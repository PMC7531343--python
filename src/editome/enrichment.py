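"""Gene-set enrichment of differentially edited genes.

Enrichment is a transparent one-sided Fisher exact test of each gene set
against a user-supplied background, with Benjamini–Hochberg correction
across sets.  The background defaults, at the pipeline level, to all genes
bearing at least one testable editing site.  Also implements the
multi-dataset commonality (Venn) logic and the intersection of pathway
genes with missense-edited genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .quantify import EditingEvent


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: tab-separated set name, description, members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3 or not cols[0]:
                continue
            sets[cols[0]] = {g for g in cols[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def genes_from_events(events: list[EditingEvent]) -> list[str]:
    """Unique gene ids touched by events; intergenic events contribute none,
    an event inside overlapping genes contributes all of them."""
    genes: set[str] = set()
    for e in events:
        genes.update(e.gene_ids)
    return sorted(genes)


@dataclass
class EnrichmentResult:
    set_name: str
    n_list_in_set: int
    n_list_out_set: int
    n_bg_in_set: int  # background excluding the list
    n_bg_out_set: int
    odds_ratio: float
    p: float
    q: float = math.nan


def fisher_enrichment(
    genes: list[str] | set[str],
    background: list[str] | set[str],
    gene_sets: dict[str, set[str]],
    min_set: int = 3,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per gene set.

    Sets are intersected with the background first; sets with fewer than
    ``min_set`` background members are skipped.  BH correction across the
    tested sets.
    """
    gene_set = set(genes)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    if not gene_set <= bg:
        raise ValueError("gene list must be contained in the background")
    rest = bg - gene_set
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & bg
        if len(members) < min_set:
            continue
        a = len(gene_set & members)
        b = len(gene_set) - a
        c = len(rest & members)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set_name": name,
                "n_list_in_set": a,
                "n_list_out_set": b,
                "n_bg_in_set": c,
                "n_bg_out_set": d,
                "odds_ratio": float(odds),
                "p": float(p),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name", "n_list_in_set", "n_list_out_set",
            "n_bg_in_set", "n_bg_out_set", "odds_ratio", "p",
        ],
    )
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def multiway_commonality(
    collections: dict[str, set[str]],
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Core items present in every collection, plus counts of every Venn
    region (keyed by the exact subset of collections an item belongs to).

    Region counts sum to the size of the union.
    """
    if len(collections) < 2:
        raise ValueError("need at least two collections")
    names = sorted(collections)
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = 0
    union = set().union(*collections.values())
    for item in union:
        membership = frozenset(n for n in names if item in collections[n])
        regions[membership] += 1
    core = set.intersection(*collections.values())
    return core, regions


def missense_pathway_overlap(
    pathway_genes: set[str] | list[str],
    missense_events: list[EditingEvent],
) -> pd.DataFrame:
    """Pathway genes that also carry a missense editing event, with the
    amino-acid change each one bears."""
    pathway = set(pathway_genes)
    rows = []
    for e in missense_events:
        if e.coding is None or e.coding.kind != "missense":
            continue
        for gene in e.gene_ids:
            if gene in pathway:
                rows.append(
                    {
                        "gene": gene,
                        "site": f"{e.site.chrom}:{e.site.pos}",
                        "substitution": e.substitution,
                        "aa_change": e.coding.hgvs_p(),
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "site", "substitution", "aa_change"])
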