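"""Orchestration: simulate → screen → quantify → differential →
concordance → enrich as one configured, seed-deterministic run.

Artifacts are deterministic under a fixed config+seed (byte-identical
across reruns); the run report additionally records wall times, so the
report file itself is the one output excluded from that guarantee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import call_differential, calls_to_frame, compare_cohorts, editing_matrix
from .enrichment import fisher_enrichment, genes_from_events, read_gmt
from .formats_io import (
    read_fasta,
    read_gtf,
    read_known_sites,
    read_manifest,
    read_pileup,
    read_repeats_bed,
    read_site_table,
    write_site_table,
    AnnotationBundle,
)
from .quantify import classify_events, distribution_summary, quantify_sites, select_high_confidence
from .screen import CandidateSite, ScreenConfig, run_screen
from .synthetic_cohort import (
    CohortTruth,
    PlantedSite,
    SimConfig,
    evaluate_calls,
    simulate_cohort,
    simulate_pileups,
    stage_rng,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or inconsistent stage input (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All pipeline thresholds with their defaults.

    The defaults are the operating point of the method: high-confidence
    gate depth ≥ 10 and ratio > 0.2, read trim 6, splice window 4,
    homopolymer ≥ 5, differential criteria FDR < 0.05, |Δmean| > 0.2,
    |Δpct| > 10.
    """

    seed: int = 0
    # candidate screen
    min_alt_reads: int = 2
    read_trim: int = 6
    splice_window: int = 4
    homopolymer_min: int = 5
    multilocus_flank: int = 50
    multilocus_max_mismatches: int = 2
    snp_match_mode: str = "position"
    # quantification / high-confidence gate
    min_depth: int = 10
    min_ratio: float = 0.2
    flank_bp: int = 1000
    # differential criteria
    fdr: float = 0.05
    delta_mean: float = 0.2
    delta_pct: float = 10.0
    min_covered: int = 5
    # stage toggles
    simulate: bool = True
    screen: bool = True
    quantify: bool = True
    differential: bool = True
    concordance: bool = True
    enrich: bool = True
    # synthetic-cohort overrides (keys of SimConfig)
    sim: dict = field(default_factory=dict)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            min_alt_reads=self.min_alt_reads,
            read_trim=self.read_trim,
            splice_window=self.splice_window,
            homopolymer_min=self.homopolymer_min,
            multilocus_flank=self.multilocus_flank,
            multilocus_max_mismatches=self.multilocus_max_mismatches,
            snp_match_mode=self.snp_match_mode,
        )

    def sim_config(self) -> SimConfig:
        try:
            return SimConfig(seed=self.seed, flank_bp=self.flank_bp, **self.sim)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid sim overrides: {exc}") from exc

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_RANGES: dict[str, tuple[float, float]] = {
    "fdr": (0.0, 1.0),
    "delta_mean": (0.0, 1.0),
    "min_ratio": (0.0, 1.0),
    "delta_pct": (0.0, 100.0),
}


def validate_config(source: str | Path | dict | None) -> tuple[RunConfig | None, list[str]]:
    """Normalize a YAML file or dict into a RunConfig, reporting every
    problem at once.  Unknown keys are rejected by name."""
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            return None, ["config file must hold a mapping"]
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in sorted(set(data) - known):
        errors.append(f"unknown config key: {key!r}")
    sim = data.get("sim", {})
    if sim is not None and not isinstance(sim, dict):
        errors.append("'sim' must be a mapping of SimConfig overrides")
        sim = {}
    sim_known = {f.name for f in dataclasses.fields(SimConfig)}
    for key in sorted(set(sim) - sim_known):
        errors.append(f"unknown sim key: {key!r}")
    for key, (lo, hi) in _RANGES.items():
        if key in data and not (lo <= float(data[key]) <= hi):
            errors.append(f"{key} must lie in [{lo}, {hi}]")
    for key in ("min_alt_reads", "read_trim", "splice_window", "homopolymer_min",
                "multilocus_flank", "min_depth", "min_covered", "seed"):
        if key in data and (not isinstance(data[key], int) or data[key] < 0):
            errors.append(f"{key} must be a non-negative integer")
    if data.get("snp_match_mode") not in (None, "position", "allele"):
        errors.append("snp_match_mode must be 'position' or 'allele'")
    if errors:
        return None, errors
    cfg = RunConfig(**{k: v for k, v in data.items() if k in known})
    try:
        cfg.sim_config()
    except ConfigError as exc:
        return None, [str(exc)]
    return cfg, []


# ---------------------------------------------------------------------------


def _resample_truth(truth: CohortTruth, config: SimConfig, stage: str) -> CohortTruth:
    """Same planted sites, fresh per-sample true ratios: an independent
    validation cohort over the same biology."""
    rng = stage_rng(config.seed, stage)
    is_ctrl = np.array([truth.groups[s] == "control" for s in truth.samples])

    def redraw(site: PlantedSite, beta_c, beta_t) -> PlantedSite:
        r = np.empty(len(truth.samples))
        r[is_ctrl] = rng.beta(*beta_c, is_ctrl.sum())
        r[~is_ctrl] = rng.beta(*beta_t, (~is_ctrl).sum())
        return dataclasses.replace(site, ratios=r)

    edits = [redraw(s, config.control_beta, config.tumor_beta) for s in truth.edits]
    artifacts = [
        redraw(s, config.artifact_beta, config.artifact_beta) for s in truth.artifacts
    ]
    return dataclasses.replace(truth, edits=edits, artifacts=artifacts)


def _read_pileup_dir(path: Path) -> dict[str, list]:
    if not path.is_dir():
        raise DataError(f"missing pileup directory: {path}")
    pileups = {}
    for f in sorted(path.glob("*.pileup.tsv")):
        pileups[f.name.removesuffix(".pileup.tsv")] = list(read_pileup(f))
    if not pileups:
        raise DataError(f"no pileup files under {path}")
    return pileups


def _sites_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt} for s in sites]
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order; returns the run report.

    Every stage reads its inputs from the files the previous stage wrote,
    so each stage can also be run standalone against user-provided files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    sim_dir = out / "sim"
    try:
        t_all = time.perf_counter()
        truth = None
        if config.simulate:
            t0 = time.perf_counter()
            sim_cfg = config.sim_config()
            syn, truth, _pileups = simulate_cohort(sim_cfg, sim_dir)
            for f in sorted(sim_dir.rglob("*")):
                if f.is_file():
                    track(f)
            report["stages"]["simulate"] = {
                "n_edit_sites": len(truth.edits),
                "n_snps": len(truth.snps),
                "n_artifacts": len(truth.artifacts),
                "n_samples": len(truth.samples),
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }

        def require(path: Path, producer: str) -> Path:
            if not path.exists():
                raise DataError(
                    f"missing input {path} (enable the '{producer}' stage or provide it)"
                )
            return path

        if config.screen:
            t0 = time.perf_counter()
            genome = read_fasta(require(sim_dir / "genome.fa", "simulate"))
            transcripts, junctions = read_gtf(require(sim_dir / "genes.gtf", "simulate"))
            repeats = read_repeats_bed(require(sim_dir / "repeats.bed", "simulate"))
            snps = read_known_sites(require(sim_dir / "known_snps.vcf", "simulate"))
            annotations = AnnotationBundle(
                transcripts=transcripts,
                splice_junctions=junctions,
                repeats=repeats,
                known_snps=snps,
                flank_bp=config.flank_bp,
            )
            pileups = _read_pileup_dir(sim_dir / "pileups")
            sites, trace = run_screen(pileups, annotations, genome, config.screen_config())
            _write_tsv(_sites_frame(sites), track(out / "sites.tsv"))
            trace_rows = [
                {"filter": name, "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
                for name, removed in trace.removed.items()
                for s in sorted(removed)
            ]
            _write_tsv(
                pd.DataFrame(trace_rows, columns=["filter", "chrom", "pos", "ref", "alt"]),
                track(out / "trace.tsv"),
            )
            stage = {
                "n_candidates": trace.n_input,
                "removed": trace.removal_counts(),
                "n_survivors": len(trace.survivors),
                "count_conserved": trace.check_conservation(),
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
            if truth is not None:
                stage["truth_evaluation"] = evaluate_calls(sites, truth)
            report["stages"]["screen"] = stage

        if config.quantify:
            t0 = time.perf_counter()
            genome = read_fasta(require(sim_dir / "genome.fa", "simulate"))
            transcripts, junctions = read_gtf(require(sim_dir / "genes.gtf", "simulate"))
            repeats = read_repeats_bed(require(sim_dir / "repeats.bed", "simulate"))
            annotations = AnnotationBundle(
                transcripts=transcripts,
                splice_junctions=junctions,
                repeats=repeats,
                flank_bp=config.flank_bp,
            )
            sites_df = pd.read_csv(require(out / "sites.tsv", "screen"), sep="\t")
            sites = [
                CandidateSite(r.chrom, int(r.pos), r.ref, r.alt)
                for r in sites_df.itertuples(index=False)
            ]
            pileups = _read_pileup_dir(sim_dir / "pileups")
            calls = quantify_sites(pileups, sites, trim=config.read_trim)
            write_site_table(calls, track(out / "calls.tsv"))
            events = classify_events(sites, annotations, genome)
            ev_df = pd.DataFrame(
                [
                    {
                        "chrom": e.site.chrom,
                        "pos": e.site.pos,
                        "ref": e.site.ref,
                        "alt": e.site.alt,
                        "substitution": e.substitution,
                        "family": e.family,
                        "region": e.region,
                        "repeat": e.repeat,
                        "coding_effect": e.coding_effect,
                        "aa_change": e.coding.hgvs_p() if e.coding else "NA",
                        "genes": ";".join(e.gene_ids),
                    }
                    for e in events
                ]
            )
            _write_tsv(ev_df, track(out / "events.tsv"))
            hc = select_high_confidence(calls, config.min_depth, config.min_ratio)
            if events:
                for name, table in distribution_summary(events).items():
                    _write_tsv(
                        table.reset_index(), track(out / f"summary_{name}.tsv")
                    )
            report["stages"]["quantify"] = {
                "n_sites": len(sites),
                "n_calls": len(calls),
                "n_high_confidence_calls": len(hc),
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }

        diff = None
        if config.differential:
            t0 = time.perf_counter()
            calls = read_site_table(require(out / "calls.tsv", "quantify"))
            manifest = read_manifest(require(sim_dir / "manifest.tsv", "simulate"))
            diff = call_differential(
                calls,
                manifest,
                case_group="tumor",
                control_group="control",
                fdr_alpha=config.fdr,
                delta_mean_min=config.delta_mean,
                delta_pct_min=config.delta_pct,
                min_depth=config.min_depth,
                min_ratio=config.min_ratio,
                min_covered=config.min_covered,
            )
            _write_tsv(diff, track(out / "differential.tsv"))
            _write_tsv(
                editing_matrix(calls).reset_index(), track(out / "editing_matrix.tsv")
            )
            sig = diff[diff["significant"]]
            report["stages"]["differential"] = {
                "n_sites": len(diff),
                "n_testable": int(diff["testable"].sum()),
                "n_significant": len(sig),
                "n_up": int((sig["direction"] == "up").sum()),
                "n_down": int((sig["direction"] == "down").sum()),
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }

        if config.concordance:
            t0 = time.perf_counter()
            if truth is None or diff is None:
                raise DataError(
                    "concordance needs the 'simulate' and 'differential' stages enabled"
                )
            sim_cfg = config.sim_config()
            syn2 = None
            from .synthetic_cohort import build_genome

            syn2 = build_genome(sim_cfg)
            truth_val = _resample_truth(truth, sim_cfg, "validation")
            val_dir = out / "validation"
            pileups_val = simulate_pileups(
                syn2, truth_val, sim_cfg, val_dir / "pileups", stage="pileups_validation"
            )
            annotations = syn2.annotations
            sites_val, _trace = run_screen(
                pileups_val, annotations, syn2.genome, config.screen_config()
            )
            calls_val = quantify_sites(pileups_val, sites_val, trim=config.read_trim)
            diff_val = call_differential(
                calls_to_frame(calls_val),
                sim_cfg.manifest,
                case_group="tumor",
                control_group="control",
                fdr_alpha=config.fdr,
                delta_mean_min=config.delta_mean,
                delta_pct_min=config.delta_pct,
                min_depth=config.min_depth,
                min_ratio=config.min_ratio,
                min_covered=config.min_covered,
            )
            _write_tsv(diff_val, track(val_dir / "differential.tsv"))
            for f in sorted((val_dir / "pileups").glob("*")):
                track(f)
            conc = compare_cohorts(diff, diff_val)
            with open(track(out / "concordance.json"), "w") as fh:
                json.dump(conc, fh, indent=2, sort_keys=True)
            report["stages"]["concordance"] = {
                **{k: conc[k] for k in ("n_a", "n_b", "n_overlap", "pct_b_in_a")},
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }

        if config.enrich:
            t0 = time.perf_counter()
            if diff is None:
                raise DataError("enrich needs the 'differential' stage enabled")
            genome = read_fasta(require(sim_dir / "genome.fa", "simulate"))
            transcripts, junctions = read_gtf(require(sim_dir / "genes.gtf", "simulate"))
            repeats = read_repeats_bed(require(sim_dir / "repeats.bed", "simulate"))
            annotations = AnnotationBundle(
                transcripts=transcripts,
                splice_junctions=junctions,
                repeats=repeats,
                flank_bp=config.flank_bp,
            )
            gene_sets = read_gmt(require(sim_dir / "gene_sets.gmt", "simulate"))
            testable = diff[diff["testable"]]
            sig = diff[diff["significant"]]

            def to_sites(frame: pd.DataFrame) -> list[CandidateSite]:
                return [
                    CandidateSite(r.chrom, int(r.pos), r.ref, r.alt)
                    for r in frame.itertuples(index=False)
                ]

            background_events = classify_events(to_sites(testable), annotations, genome)
            sig_events = classify_events(to_sites(sig), annotations, genome)
            background = genes_from_events(background_events)
            gene_list = genes_from_events(sig_events)
            enr = fisher_enrichment(gene_list, background, gene_sets)
            _write_tsv(enr, track(out / "enrichment.tsv"))
            report["stages"]["enrich"] = {
                "n_genes": len(gene_list),
                "n_background": len(background),
                "n_sets_tested": len(enr),
                "n_sets_q05": int((enr["q"] < 0.05).sum()) if len(enr) else 0,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }

        report["wall_time_s"] = round(time.perf_counter() - t_all, 3)
    except Exception:
        for path in written:  # no partial outputs on failure
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out / "run_report.json")
    return report
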