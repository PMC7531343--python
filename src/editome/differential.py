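"""Differential RNA editing between phenotype groups.

A site is called differentially edited between tumor and control when all
three criteria hold simultaneously and strictly:

* Benjamini–Hochberg FDR of the Mann–Whitney U test < 0.05,
* |mean tumor editing ratio − mean control editing ratio| > 0.2,
* |percentage of samples edited in tumor − in control| > 10 points,

where a sample counts as covered at a site when its post-trim depth is at
least ``min_depth`` reads, means are taken over covered samples only, and
"edited in a sample" means passing the high-confidence gate (depth ≥ 10,
ratio > 0.2) in that sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import SiteCall


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided
    method: str  # 'exact' | 'asymptotic'


def mann_whitney_u(
    x: list[float] | np.ndarray,
    y: list[float] | np.ndarray,
    exact_max_n: int = 16,
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    For small samples (n_x + n_y ≤ ``exact_max_n``) the p-value comes from
    the exact permutation null — every assignment of the pooled values to
    the two groups is enumerated, which handles ties exactly.  Larger
    samples use the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    if nx + ny <= exact_max_n:
        # work in doubled-rank integers so midranks compare exactly
        r2 = np.rint(2 * ranks).astype(np.int64)
        u2_obs = int(np.rint(2 * u))
        offset = nx * (nx + 1)
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(nx + ny), nx)),
            dtype=np.intp,
        ).reshape(-1, nx)
        u2_all = r2[combos].sum(axis=1) - offset
        total = len(u2_all)
        p = min(1.0, 2 * min((u2_all <= u2_obs).sum(), (u2_all >= u2_obs).sum()) / total)
        return MannWhitneyResult(u=u, p=p, method="exact")

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-site group summaries and the three-criterion call


@dataclass
class GroupSummary:
    group: str
    n_covered: int
    n_edited: int
    mean_ratio: float  # over covered samples; NaN when none covered

    @property
    def pct_edited(self) -> float:
        if self.n_covered == 0:
            return math.nan
        return 100.0 * self.n_edited / self.n_covered


def calls_to_frame(calls: list[SiteCall]) -> pd.DataFrame:
    df = pd.DataFrame([c.__dict__ for c in calls])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "sample", "chrom", "pos", "ref", "alt",
                "total_depth", "alt_depth", "editing_ratio",
            ]
        )
    return df


def summarize_site_by_group(
    site_calls: pd.DataFrame,
    manifest: dict[str, str],
    min_depth: int = 10,
    min_ratio: float = 0.2,
) -> dict[str, GroupSummary]:
    """Group summaries for one site's calls (rows of one (chrom,pos,ref,alt))."""
    unknown = set(site_calls["sample"]) - set(manifest)
    if unknown:
        raise KeyError(f"samples missing from manifest: {sorted(unknown)}")
    out: dict[str, GroupSummary] = {}
    groups = site_calls["sample"].map(manifest)
    for group in sorted(set(manifest.values())):
        sub = site_calls[groups == group]
        covered = sub[sub["total_depth"] >= min_depth]
        edited = covered[covered["editing_ratio"] > min_ratio]
        out[group] = GroupSummary(
            group=group,
            n_covered=len(covered),
            n_edited=len(edited),
            mean_ratio=float(covered["editing_ratio"].mean()) if len(covered) else math.nan,
        )
    return out


def call_differential(
    calls: list[SiteCall] | pd.DataFrame,
    manifest: dict[str, str],
    case_group: str,
    control_group: str,
    fdr_alpha: float = 0.05,
    delta_mean_min: float = 0.2,
    delta_pct_min: float = 10.0,
    min_depth: int = 10,
    min_ratio: float = 0.2,
    min_covered: int = 5,
) -> pd.DataFrame:
    """Three-criterion differential-editing table, one row per site.

    Sites with fewer than ``min_covered`` covered samples in either group
    are flagged untestable and excluded from the BH family.  ``delta_mean``
    is case − control; direction 'up' means higher editing in the case
    group.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    unknown = set(df["sample"]) - set(manifest)
    if unknown:
        raise KeyError(f"samples missing from manifest: {sorted(unknown)}")
    df = df.assign(group=df["sample"].map(manifest))
    rows = []
    for (chrom, pos, ref, alt), site_df in df.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        summaries = summarize_site_by_group(site_df, manifest, min_depth, min_ratio)
        case, ctrl = summaries[case_group], summaries[control_group]
        testable = case.n_covered >= min_covered and ctrl.n_covered >= min_covered
        u = p = math.nan
        if testable:
            cov = site_df[site_df["total_depth"] >= min_depth]
            res = mann_whitney_u(
                cov.loc[cov["group"] == case_group, "editing_ratio"].to_numpy(),
                cov.loc[cov["group"] == control_group, "editing_ratio"].to_numpy(),
            )
            u, p = res.u, res.p
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                f"n_covered_{case_group}": case.n_covered,
                f"n_covered_{control_group}": ctrl.n_covered,
                f"mean_ratio_{case_group}": case.mean_ratio,
                f"mean_ratio_{control_group}": ctrl.mean_ratio,
                f"pct_edited_{case_group}": case.pct_edited,
                f"pct_edited_{control_group}": ctrl.pct_edited,
                "delta_mean": case.mean_ratio - ctrl.mean_ratio,
                "delta_pct": case.pct_edited - ctrl.pct_edited,
                "testable": testable,
                "u": u,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = out["significant"] = out["direction"] = []
        return out
    out["q"] = math.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = (
        (out["q"] < fdr_alpha)
        & (out["delta_mean"].abs() > delta_mean_min)
        & (out["delta_pct"].abs() > delta_pct_min)
    ).fillna(False)
    out["direction"] = np.where(out["delta_mean"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# cross-cohort concordance


def compare_cohorts(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Overlap of two differential-event sets, keyed by
    (chrom, pos, ref, alt, direction).

    ``pct_b_in_a`` is the concordance of a validation set ``b`` against a
    discovery set ``a``; both normalizations are reported, split by
    direction.
    """

    def keys(df: pd.DataFrame) -> set[tuple]:
        sig = df[df["significant"]] if "significant" in df.columns else df
        return set(
            zip(sig["chrom"], sig["pos"], sig["ref"], sig["alt"], sig["direction"])
        )

    ka, kb = keys(a), keys(b)
    inter = ka & kb

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else math.nan

    by_direction = {}
    for direction in ("up", "down"):
        da = {k for k in ka if k[4] == direction}
        db = {k for k in kb if k[4] == direction}
        by_direction[direction] = {
            "n_a": len(da),
            "n_b": len(db),
            "n_overlap": len(da & db),
            "pct_b_in_a": pct(len(da & db), len(db)),
            "pct_a_in_b": pct(len(da & db), len(da)),
        }
    return {
        "n_a": len(ka),
        "n_b": len(kb),
        "n_overlap": len(inter),
        "pct_b_in_a": pct(len(inter), len(kb)),
        "pct_a_in_b": pct(len(inter), len(ka)),
        "by_direction": by_direction,
    }


# ---------------------------------------------------------------------------
# editing–expression relations


def correlate_editing_expression(
    ratios: list[float] | np.ndarray,
    expression: list[float] | np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between per-sample editing ratios and expression.

    Pairs with an undefined ratio are dropped; a constant vector makes the
    coefficient undefined and returns (NaN, NaN).
    """
    r_arr = np.asarray(ratios, dtype=float)
    e_arr = np.asarray(expression, dtype=float)
    if r_arr.shape != e_arr.shape:
        raise ValueError("paired vectors required")
    keep = ~(np.isnan(r_arr) | np.isnan(e_arr))
    r_arr, e_arr = r_arr[keep], e_arr[keep]
    if len(r_arr) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(r_arr) == 0 or np.ptp(e_arr) == 0:
        return math.nan, math.nan
    if method == "pearson":
        res = stats.pearsonr(r_arr, e_arr)
    elif method == "spearman":
        res = stats.spearmanr(r_arr, e_arr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def compare_expression_groups(
    x: list[float] | np.ndarray, y: list[float] | np.ndarray
) -> MannWhitneyResult:
    """Mann–Whitney comparison of expression between two sample groups
    (e.g. edited vs unedited, or grade-wise)."""
    return mann_whitney_u(x, y)


def editing_matrix(calls: list[SiteCall] | pd.DataFrame) -> pd.DataFrame:
    """Sites × samples matrix of editing ratios (heat-map/cluster-ready)."""
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    df = df.assign(site=[f"{c}:{p}:{r}>{a}" for c, p, r, a in
                         zip(df["chrom"], df["pos"], df["ref"], df["alt"])])
    return df.pivot_table(
        index="site", columns="sample", values="editing_ratio", aggfunc="first"
    )
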