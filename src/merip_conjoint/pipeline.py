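"""End-to-end orchestration: simulate -> consensus -> merge -> annotate ->
motifs -> differential -> conjoint, with a machine-readable run report.

Every stage is a pure function of its inputs plus the config, and all
randomness flows from the single ``seed`` field, so re-running the same
config yields byte-identical outputs (asserted by the smoke tests).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import __version__
from .consensus_peaks import HCPeak, UniPeak, find_hcpeaks, merge_conditions
from .conjoint import classify_conjoint, conjoint_frame
from .differential import (
    log2_intensity_cdf,
    peak_log2_intensity,
    test_diff_genes,
    test_diff_peaks,
    volcano_labels,
)
from .genic_annotation import (
    RegionIndex,
    bin_density,
    partition_transcript,
    summarize_distribution,
)
from .genomic_io import CountTable, GenomicInterval, write_results
from .motif_scan import DegenerateMotif, peak_motif_fraction
from .synthetic_data import SimulationConfig, simulate_study, write_study

logger = logging.getLogger("merip_conjoint")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class RunConfig:
    """Single flat configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    min_support: int = 2
    min_overlap: int = 100
    alpha: float = 0.05
    bin_size: int = 100_000
    motifs: Tuple[Tuple[str, str], ...] = (("RRACH", "RRACH"), ("URUAY", "URUAY"))
    comparisons: Optional[Tuple[Tuple[str, str, str], ...]] = None
    peak_test_method: str = "nb"
    simulation: Optional[SimulationConfig] = None

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.min_support < 2 or self.min_overlap <= 0 or self.bin_size <= 0:
            raise ValueError("thresholds must be positive (min_support >= 2)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.comparisons is None:
            cv = self.simulation.cultivars
            ck, cd = self.simulation.conditions[0], self.simulation.conditions[-1]
            self.comparisons = tuple(
                (f"{c}_{cd}_vs_{c}_{ck}", f"{c}_{ck}", f"{c}_{cd}") for c in cv
            )
        groups = set(self.simulation.groups)
        for name, a, b in self.comparisons:
            if a not in groups or b not in groups:
                raise ValueError(
                    f"comparison {name!r} references unknown group(s): {a}, {b}"
                )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**{**sim, "seed": raw.get("seed", sim.get("seed", 0))})
        comparisons = raw.pop("comparisons", None)
        if comparisons is not None:
            comparisons = tuple(tuple(c) for c in comparisons)
        motifs = raw.pop("motifs", None)
        if motifs is not None:
            motifs = tuple(
                (m["name"], m["pattern"]) if isinstance(m, dict) else tuple(m)
                for m in motifs
            )
            raw["motifs"] = motifs
        return cls(simulation=sim, comparisons=comparisons, **raw)


def match_counts_to_unipeaks(
    table: CountTable, unipeaks: Sequence[UniPeak]
) -> CountTable:
    """Re-key a coordinate-indexed peak count table onto unipeaks.

    Each unipeak receives the column-wise sum of count features overlapping
    it; unipeaks matching no count feature are skipped with a warning.
    """
    if table.feature_info is None:
        raise ValueError("peak count table lacks chrom/start/end feature info")
    trees: Dict[str, IntervalTree] = {}
    for fid, row in table.feature_info.iterrows():
        trees.setdefault(row["chrom"], IntervalTree())[
            int(row["start"]) : int(row["end"])
        ] = fid
    rows, index, info_rows = [], [], []
    skipped = 0
    for up in unipeaks:
        iv = up.interval
        tree = trees.get(iv.chrom)
        fids = sorted(node.data for node in tree.overlap(iv.start, iv.end)) if tree else []
        if not fids:
            skipped += 1
            continue
        rows.append(table.counts.loc[fids].sum(axis=0))
        index.append(up.peak_id)
        info_rows.append((iv.chrom, iv.start, iv.end))
    if skipped:
        logger.warning("%d unipeak(s) had no count features; skipped", skipped)
    counts = pd.DataFrame(rows, index=index).astype("int64")
    info = pd.DataFrame(info_rows, index=index, columns=["chrom", "start", "end"])
    return CountTable(
        counts,
        library_sizes=table.library_sizes,
        metadata=table.metadata,
        feature_info=info,
    )


def _stage(report: Dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            logger.info("stage %-12s %.2fs", name, dt)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "version": __version__,
        "config": _config_echo(config),
        "stages": {},
    }

    with _stage(report, "simulate"):
        study = simulate_study(config.simulation)
        write_study(study, out / "sim")
        report["stages"]["simulate"] = {
            "n_true_peaks": int(len(study.truth.peaks)),
            "n_genes": int(len(study.truth.genes)),
            "peaks_per_replicate": {
                group: [len(r) for r in reps]
                for group, reps in sorted(study.replicate_peaks.items())
            },
        }

    with _stage(report, "consensus"):
        hcpeaks = {
            group: find_hcpeaks(
                reps,
                min_support=config.min_support,
                min_overlap=config.min_overlap,
                condition=group,
            )
            for group, reps in study.replicate_peaks.items()
        }
        for group, peaks in sorted(hcpeaks.items()):
            df = pd.DataFrame(
                {
                    "chrom": [h.interval.chrom for h in peaks],
                    "start": [h.interval.start for h in peaks],
                    "end": [h.interval.end for h in peaks],
                    "name": [f"{group}_hcpeak_{i + 1:05d}" for i in range(len(peaks))],
                    "n_replicates": [len(h.replicates) for h in peaks],
                    "members": [";".join(h.members) for h in peaks],
                }
            )
            write_results(df, out / f"hcpeaks_{group}.tsv")
        report["stages"]["consensus"] = {
            "hcpeaks_per_group": {g: len(p) for g, p in sorted(hcpeaks.items())}
        }

    with _stage(report, "merge"):
        unipeaks = merge_conditions(hcpeaks)
        df = pd.DataFrame(
            {
                "peak_id": [u.peak_id for u in unipeaks],
                "chrom": [u.interval.chrom for u in unipeaks],
                "start": [u.interval.start for u in unipeaks],
                "end": [u.interval.end for u in unipeaks],
                "groups": [";".join(sorted(u.groups)) for u in unipeaks],
            }
        )
        write_results(df, out / "unipeaks.tsv")
        report["stages"]["merge"] = {"n_unipeaks": len(unipeaks)}

    with _stage(report, "annotate"):
        partitions = [partition_transcript(m) for m in study.models]
        index = RegionIndex(partitions, models=study.models)
        annotations = [
            index.assign_region(u, min_overlap=config.min_overlap) for u in unipeaks
        ]
        ann_df = pd.DataFrame(
            {
                "peak_id": [a.peak_id for a in annotations],
                "chrom": [u.interval.chrom for u in unipeaks],
                "start": [u.interval.start for u in unipeaks],
                "end": [u.interval.end for u in unipeaks],
                "region": [a.region for a in annotations],
                "gene_id": [a.gene_id or "" for a in annotations],
                "overlap_bp": [a.overlap_bp for a in annotations],
            }
        )
        write_results(ann_df, out / "annotations.tsv")
        summary = summarize_distribution(annotations)
        (out / "summary.json").write_text(
            json.dumps(summary.as_dict(), sort_keys=True, indent=2) + "\n"
        )
        bins = bin_density(
            [u.interval for u in unipeaks],
            bin_size=config.bin_size,
            chrom_lengths=study.genome.lengths,
        )
        write_results(bins, out / "bins.tsv")
        report["stages"]["annotate"] = summary.as_dict()

    with _stage(report, "motifs"):
        strand_by_peak = {
            a.peak_id: index.strand_by_gene[a.gene_id]
            for a in annotations
            if a.gene_id is not None
        }
        motif_rows = []
        for name, pattern in config.motifs:
            motif = DegenerateMotif(name, pattern)
            ms = peak_motif_fraction(
                unipeaks, study.genome, motif, peak_strands=strand_by_peak
            )
            motif_rows.append(
                {
                    "motif": ms.name,
                    "peaks_with_hit": ms.n_containing,
                    "total_peaks": ms.n_total,
                    "percentage": ms.percentage,
                }
            )
        motif_df = pd.DataFrame(motif_rows)
        write_results(motif_df, out / "motif_summary.tsv")
        report["stages"]["motifs"] = {
            r["motif"]: {"count": r["peaks_with_hit"], "percentage": r["percentage"]}
            for r in motif_rows
        }

    with _stage(report, "differential"):
        unipeak_counts = match_counts_to_unipeaks(study.peak_counts, unipeaks)
        diff_report = {}
        diff_peaks_by_comp: Dict[str, pd.DataFrame] = {}
        diff_genes_by_comp: Dict[str, pd.DataFrame] = {}
        for name, group_a, group_b in config.comparisons:
            dp = test_diff_peaks(
                unipeak_counts,
                group_a,
                group_b,
                alpha=config.alpha,
                method=config.peak_test_method,
            )
            dg = test_diff_genes(
                study.gene_counts, group_a, group_b, alpha=config.alpha
            )
            write_results(
                dp.rename_axis("peak_id").reset_index(), out / f"diff_peaks_{name}.tsv"
            )
            write_results(
                dg.rename_axis("gene_id").reset_index(), out / f"diff_genes_{name}.tsv"
            )
            diff_peaks_by_comp[name] = dp
            diff_genes_by_comp[name] = dg
            dmp_up = int(((dp["direction"] == "UP")).sum())
            dmp_down = int(((dp["direction"] == "DOWN")).sum())
            deg_up = int(((dg["direction"] == "UP")).sum())
            deg_down = int(((dg["direction"] == "DOWN")).sum())
            diff_report[name] = {
                "dmp_up": dmp_up,
                "dmp_down": dmp_down,
                "dmp_total": dmp_up + dmp_down,
                "deg_up": deg_up,
                "deg_down": deg_down,
                "deg_total": deg_up + deg_down,
                "volcano_labels": [str(x) for x in volcano_labels(dp)],
            }
        for group in study.config.groups:
            cdf = log2_intensity_cdf(
                {group: peak_log2_intensity(unipeak_counts, group)}
            )[group]
            write_results(cdf, out / f"cdf_{group}.tsv")
        report["stages"]["differential"] = diff_report

    with _stage(report, "conjoint"):
        peak_genes = {a.peak_id: a.gene_id for a in annotations}
        conj_report = {}
        for name, group_a, group_b in config.comparisons:
            records, counts = classify_conjoint(
                diff_peaks_by_comp[name],
                peak_genes,
                diff_genes_by_comp[name],
                alpha=config.alpha,
            )
            write_results(conjoint_frame(records), out / f"conjoint_{name}.tsv")
            (out / f"quadrants_{name}.json").write_text(
                json.dumps(counts, sort_keys=True, indent=2) + "\n"
            )
            conj_report[name] = counts
        report["stages"]["conjoint"] = conj_report

    report_text = json.dumps(report, sort_keys=True, indent=2) + "\n"
    (out / "report.json").write_text(report_text)
    return report


def _config_echo(config: RunConfig) -> Dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    return clean(config)
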