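"""Synthetic MeRIP-seq study generator with a known ground truth.

Emulates the design of a two-cultivar, control-vs-cadmium m6A study: for
each cultivar x condition group, three biological replicates of peak calls
are emitted around a set of planted "true" peaks, and negative-binomial
IP/input and expression count matrices are drawn with planted differential
methylation (DMP) and differential expression (DEG) effects.

Every stage draws from a purpose-split random stream derived from the one
seed, so changing, say, the count model never perturbs the genome or the
peak layout.  Identical configurations produce byte-identical outputs.

What is emulated: multi-replicate peak concordance (independent presence per
replicate plus Gaussian boundary jitter), transcript structure with
UTRs/CDS/introns, RRACH planting on the host-gene strand, NB counts with
var = mu + phi*mu^2.  What is not: raw reads, fragment-level coverage,
alignment artifacts, isoform complexity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import (
    CountTable,
    GenomeSequence,
    GenomicInterval,
    PeakCall,
    TranscriptModel,
    write_count_table,
    write_fasta,
    write_gff3,
    write_peaks,
    write_results,
)
from .motif_scan import RRACH, expand_iupac, reverse_complement

logger = logging.getLogger("merip_conjoint")


class ConfigurationError(ValueError):
    """A simulation parameter is out of range or infeasible."""


# random stream ids (mixed with the seed so streams stay independent)
_STREAM_GENOME, _STREAM_GENES, _STREAM_TRUTH, _STREAM_PEAKS, _STREAM_COUNTS = range(5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    Peak widths (150-500 bp) and the per-replicate presence probability
    (0.9) are package defaults for quantities the underlying study design
    leaves unstated.  Effect sizes and the planted-effect fractions default
    to the magnitudes of the study being emulated (roughly a third of peaks
    differentially methylated, |log2FC| = 2, NB dispersion 0.1).
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_genes: int = 150
    n_true_peaks: int = 140
    intergenic_fraction: float = 0.05
    replicate_presence_prob: float = 0.9
    boundary_jitter_sd: float = 10.0
    motif_plant_rate: float = 1.0
    nb_dispersion: float = 0.1
    dmp_fraction: float = 0.35
    dmp_log2fc: float = 2.0
    deg_fraction: float = 0.30
    deg_log2fc: float = 2.0
    cultivars: Tuple[str, ...] = ("9311", "NIP")
    conditions: Tuple[str, ...] = ("CK", "Cd")  # first entry is the control
    n_replicates: int = 3
    mean_input_count: float = 300.0
    ip_enrichment: float = 4.0
    library_sizes: Optional[Mapping[str, float]] = None
    peak_width_min: int = 150
    peak_width_max: int = 500
    peak_placement: str = "stop_codon"  # or "regions"

    def __post_init__(self):
        for name in ("n_chrom", "chrom_length", "n_genes", "n_true_peaks",
                     "n_replicates", "peak_width_min", "peak_width_max"):
            if getattr(self, name) < 0 or (
                name in ("n_chrom", "chrom_length", "n_replicates")
                and getattr(self, name) <= 0
            ):
                raise ConfigurationError(f"{name} must be positive")
        for name in ("replicate_presence_prob", "motif_plant_rate",
                     "dmp_fraction", "deg_fraction", "intergenic_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.boundary_jitter_sd < 0:
            raise ConfigurationError("boundary_jitter_sd must be >= 0")
        if self.peak_width_min < 150:
            raise ConfigurationError(
                "peak widths below 150 bp cannot satisfy the 100 bp overlap rule"
            )
        if self.peak_width_max < self.peak_width_min:
            raise ConfigurationError("peak_width_max < peak_width_min")
        if self.peak_placement not in ("stop_codon", "regions"):
            raise ConfigurationError("peak_placement must be stop_codon|regions")
        if self.mean_input_count <= 0 or self.ip_enrichment <= 0:
            raise ConfigurationError("count means must be positive")
        if self.library_sizes is not None and any(
            v <= 0 for v in dict(self.library_sizes).values()
        ):
            raise ConfigurationError("library sizes must be positive")

    @property
    def groups(self) -> List[str]:
        return [f"{cv}_{cond}" for cv in self.cultivars for cond in self.conditions]

    @property
    def samples(self) -> List[str]:
        return [
            f"{g}_rep{r + 1}" for g in self.groups for r in range(self.n_replicates)
        ]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class TruthTable:
    """Ground truth: one row per planted peak and per gene.

    Peak columns: peak_id, chrom, start, end, strand, gene_id (empty string
    for intergenic decoys), input_mean, is_dmp, dmp_direction, motif
    positions, and one ``present_<group>_rep<k>`` flag per emitted replicate
    file.  Gene columns: gene_id, base_mean, is_deg, deg_direction.
    """

    peaks: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self):
        bad = self.peaks.loc[self.peaks["is_dmp"], "dmp_direction"]
        if not bad.isin(["up", "down"]).all():
            raise ConfigurationError("DMP directions must be 'up' or 'down'")
        bad = self.genes.loc[self.genes["is_deg"], "deg_direction"]
        if not bad.isin(["up", "down"]).all():
            raise ConfigurationError("DEG directions must be 'up' or 'down'")


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

# genes are packed into the head of each chromosome; the tail is reserved
# for intergenic decoy peaks
_GENIC_SPACE = 0.80
_MIN_GENE_GAP = 600


def generate_genome(cfg: SimulationConfig) -> GenomeSequence:
    """Uniform-random DNA background (motif planting happens per study)."""
    rng = cfg.rng(_STREAM_GENOME)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for c in range(cfg.n_chrom):
        letters = rng.integers(0, 4, size=cfg.chrom_length)
        seqs[f"chr{c + 1}"] = alphabet[letters].tobytes().decode("ascii")
    return GenomeSequence(seqs)


#: introns are kept clear of the stop-codon neighbourhood (terminal introns
#: this close to the stop are rare in vivo; NMD selects against them)
_STOP_INTRON_CLEARANCE = 150


def _sample_gene_structure(rng: np.random.Generator, strand: str):
    utr5 = int(rng.integers(150, 301))
    cds = 3 * int(rng.integers(100, 301))  # 300-900 bp, multiple of 3
    utr3 = int(rng.integers(150, 301))
    n_introns = int(rng.integers(0, 4))
    spliced = utr5 + cds + utr3
    # genomic-order offset of the stop codon (left-to-right coordinates)
    u_stop = utr5 + cds if strand == "+" else utr3
    allowed = [
        u for u in range(1, spliced - 1)
        if abs(u - u_stop) > _STOP_INTRON_CLEARANCE
    ]
    n_introns = min(n_introns, len(allowed))
    intron_positions = sorted(
        int(p) for p in rng.choice(allowed, size=n_introns, replace=False)
    ) if n_introns else []
    intron_lengths = [int(rng.integers(80, 301)) for _ in range(n_introns)]
    return utr5, cds, utr3, intron_positions, intron_lengths


def generate_gene_models(
    cfg: SimulationConfig, genome: Optional[GenomeSequence] = None
) -> List[TranscriptModel]:
    """Place non-overlapping genes with 5'UTR >= 150, CDS >= 300 (multiple of
    3), 3'UTR >= 150 and 0-3 introns.  Raises on infeasible packing."""
    rng = cfg.rng(_STREAM_GENES)
    chrom_lengths = (
        genome.lengths
        if genome is not None
        else {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chrom)}
    )
    chroms = list(chrom_lengths)
    models: List[TranscriptModel] = []
    chrom_i = 0
    cursor = int(rng.integers(200, 600))
    for g in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        utr5, cds, utr3, ipos, ilen = _sample_gene_structure(rng, strand)
        spliced = utr5 + cds + utr3
        genomic_len = spliced + sum(ilen)
        placed = False
        while chrom_i < len(chroms):
            chrom = chroms[chrom_i]
            limit = int(chrom_lengths[chrom] * _GENIC_SPACE)
            if cursor + genomic_len <= limit:
                placed = True
                break
            chrom_i += 1
            cursor = int(rng.integers(200, 600))
        if not placed:
            raise ConfigurationError(
                f"cannot pack {cfg.n_genes} genes into the genic space "
                f"(failed at gene {g})"
            )
        start = cursor
        # build exons: spliced segments split at intron positions
        bounds = [0] + ipos + [spliced]
        exons, gpos = [], start
        for k in range(len(bounds) - 1):
            seg = bounds[k + 1] - bounds[k]
            exons.append((gpos, gpos + seg))
            gpos += seg
            if k < len(ilen):
                gpos += ilen[k]
        # biological 5'UTR sits leftmost on '+', rightmost on '-'
        u_cds_start = utr5 if strand == "+" else spliced - utr5 - cds
        cds_start = _spliced_to_genomic(exons, u_cds_start)
        cds_end = _spliced_to_genomic(exons, u_cds_start + cds - 1) + 1
        models.append(
            TranscriptModel(
                gene_id=f"gene{g + 1:05d}",
                transcript_id=f"gene{g + 1:05d}.t1",
                chrom=chroms[chrom_i],
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        cursor = gpos + int(rng.integers(_MIN_GENE_GAP, 2 * _MIN_GENE_GAP))
    return models


def _spliced_to_genomic(exons: Sequence[Tuple[int, int]], u: int) -> int:
    """Genomic position of left-to-right spliced offset ``u``."""
    for s, e in exons:
        if u < e - s:
            return s + u
        u -= e - s
    raise ValueError("spliced offset outside exons")


# ---------------------------------------------------------------------------
# Truth peaks and replicate peak calls
# ---------------------------------------------------------------------------

def _truth_and_genes(
    cfg: SimulationConfig, models: Sequence[TranscriptModel],
    chrom_lengths: Mapping[str, int],
) -> TruthTable:
    rng = cfg.rng(_STREAM_TRUTH)
    n_intergenic = int(round(cfg.n_true_peaks * cfg.intergenic_fraction))
    n_genic = cfg.n_true_peaks - n_intergenic
    if n_genic > len(models):
        raise ConfigurationError(
            f"{n_genic} genic peaks exceed the capacity of {len(models)} genes"
        )

    # gene-level truth
    base_means = rng.lognormal(
        mean=np.log(cfg.mean_input_count) - 0.18, sigma=0.6, size=len(models)
    )
    is_deg = rng.random(len(models)) < cfg.deg_fraction
    deg_dir = np.where(rng.random(len(models)) < 0.5, "up", "down")
    genes = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "base_mean": base_means,
            "is_deg": is_deg,
            "deg_direction": np.where(is_deg, deg_dir, ""),
        }
    )
    base_by_gene = dict(zip(genes["gene_id"], genes["base_mean"]))

    host_idx = rng.choice(len(models), size=n_genic, replace=False)
    rows = []
    from .genic_annotation import partition_transcript, REGION_PRIORITY

    region_weights = {  # rough genic placement mix when peak_placement="regions"
        "stop_codon": 0.47, "3'UTR": 0.19, "CDS": 0.12,
        "start_codon": 0.10, "5'UTR": 0.07, "intron": 0.05,
    }
    for i, gi in enumerate(sorted(host_idx)):
        model = models[gi]
        width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
        if cfg.peak_placement == "stop_codon":
            # centre exactly on the base after the last codon (genomic)
            centre = model.cds_end if model.strand == "+" else model.cds_start
        else:
            part = partition_transcript(model)
            labels = [l for l in region_weights if l in part.genomic_segments]
            w = np.array([region_weights[l] for l in labels])
            label = str(rng.choice(labels, p=w / w.sum()))
            segs = part.genomic_segments[label]
            seg = segs[int(rng.integers(0, len(segs)))]
            centre = int(rng.integers(seg.start, seg.end))
        start = max(0, centre - width // 2)
        end = min(chrom_lengths[model.chrom], start + width)
        rows.append(
            {
                "peak_id": f"truth_{i + 1:05d}",
                "chrom": model.chrom,
                "start": start,
                "end": end,
                "strand": model.strand,
                "gene_id": model.gene_id,
            }
        )
    # intergenic decoys live in the reserved tail of each chromosome
    chroms = list(chrom_lengths)
    for j in range(n_intergenic):
        chrom = chroms[j % len(chroms)]
        zone_start = int(chrom_lengths[chrom] * _GENIC_SPACE) + 500
        width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
        start = zone_start + (j // len(chroms)) * (cfg.peak_width_max + _MIN_GENE_GAP)
        end = start + width
        if end > chrom_lengths[chrom]:
            raise ConfigurationError("intergenic zone exhausted; enlarge genome")
        rows.append(
            {
                "peak_id": f"truth_{n_genic + j + 1:05d}",
                "chrom": chrom, "start": start, "end": end,
                "strand": ".", "gene_id": "",
            }
        )
    peaks = pd.DataFrame(rows)
    n = len(peaks)
    peaks["input_mean"] = [
        base_by_gene.get(g, float(rng.lognormal(np.log(cfg.mean_input_count) - 0.18, 0.6)))
        for g in peaks["gene_id"]
    ]
    is_dmp = rng.random(n) < cfg.dmp_fraction
    dmp_dir = np.where(rng.random(n) < 0.5, "up", "down")
    peaks["is_dmp"] = is_dmp
    peaks["dmp_direction"] = np.where(is_dmp, dmp_dir, "")
    peaks["motif_positions"] = ""
    for group in cfg.groups:
        for r in range(cfg.n_replicates):
            peaks[f"present_{group}_rep{r + 1}"] = (
                rng.random(n) < cfg.replicate_presence_prob
            )
    return TruthTable(peaks=peaks, genes=genes)


def generate_replicate_peaks(
    cfg: SimulationConfig,
    models: Sequence[TranscriptModel],
    genome: Optional[GenomeSequence] = None,
) -> Tuple[Dict[str, List[List[PeakCall]]], TruthTable]:
    """Emit jittered per-replicate peak calls for every group, plus the truth.

    Each truth peak appears in each replicate independently with
    ``replicate_presence_prob``; boundaries are jittered by
    Normal(0, boundary_jitter_sd) truncated so width stays >= 150 bp.
    """
    chrom_lengths = (
        genome.lengths
        if genome is not None
        else {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chrom)}
    )
    truth = _truth_and_genes(cfg, models, chrom_lengths)
    rng = cfg.rng(_STREAM_PEAKS)
    out: Dict[str, List[List[PeakCall]]] = {}
    for group in cfg.groups:
        reps: List[List[PeakCall]] = []
        for r in range(cfg.n_replicates):
            calls: List[PeakCall] = []
            flags = truth.peaks[f"present_{group}_rep{r + 1}"].to_numpy()
            # draw jitter for every peak so the stream is presence-independent
            jit = rng.normal(0.0, cfg.boundary_jitter_sd, size=(len(truth.peaks), 2))
            for k, row in enumerate(truth.peaks.itertuples(index=False)):
                if not flags[k]:
                    continue
                start = int(row.start + round(jit[k, 0]))
                end = int(row.end + round(jit[k, 1]))
                start = max(0, start)
                end = min(chrom_lengths[row.chrom], end)
                if end - start < 150:
                    end = min(chrom_lengths[row.chrom], start + 150)
                calls.append(
                    PeakCall(
                        interval=GenomicInterval(row.chrom, start, end, "."),
                        sample=f"{group}_rep{r + 1}",
                        name=f"{group}_rep{r + 1}_{row.peak_id}",
                        score=100.0,
                    )
                )
            reps.append(calls)
        out[group] = reps
    return out, truth


def plant_motifs(
    genome: GenomeSequence, truth: TruthTable, cfg: SimulationConfig
) -> Tuple[GenomeSequence, TruthTable]:
    """Seed an RRACH instance into each selected truth peak (on the host-gene
    strand) and record its genomic position in the truth table."""
    rng = cfg.rng(_STREAM_TRUTH + 1000)  # dedicated planting stream
    kmers = sorted(expand_iupac(RRACH))
    seqs = {name: bytearray(seq, "ascii") for name, seq in genome.sequences.items()}
    positions_col = []
    margin = 40  # keep planted motifs clear of jittered boundaries
    for row in truth.peaks.itertuples(index=False):
        if rng.random() >= cfg.motif_plant_rate:
            positions_col.append("")
            continue
        k = len(RRACH)
        lo, hi = row.start + margin, row.end - margin - k
        if hi <= lo:
            lo, hi = row.start, row.end - k
        pos = int(rng.integers(lo, hi + 1))
        kmer = kmers[int(rng.integers(0, len(kmers)))]
        insert = kmer if row.strand != "-" else reverse_complement(kmer)
        seqs[row.chrom][pos : pos + k] = insert.encode("ascii")
        positions_col.append(str(pos))
    peaks = truth.peaks.copy()
    peaks["motif_positions"] = positions_col
    return (
        GenomeSequence({n: bytes(s).decode("ascii") for n, s in seqs.items()}),
        TruthTable(peaks=peaks, genes=truth.genes),
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with var = mu + phi*mu^2 (Poisson when phi == 0)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(
    cfg: SimulationConfig, truth: TruthTable
) -> Tuple[CountTable, CountTable]:
    """Draw the peak (IP + input) and gene count tables implied by the truth.

    Planted DMPs multiply the IP mean (i.e. the IP/input enrichment ratio)
    by 2**(+-dmp_log2fc) in the stressed condition; planted DEGs multiply
    both the expression mean and, proportionally, IP and input peak counts.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    lib = dict(cfg.library_sizes) if cfg.library_sizes else {}
    lib_factor = {s: float(lib.get(s, 1.0)) for s in cfg.samples}
    control = cfg.conditions[0]

    deg_fc = {
        row.gene_id: 2.0 ** (cfg.deg_log2fc if row.deg_direction == "up"
                             else -cfg.deg_log2fc)
        for row in truth.genes.itertuples(index=False) if row.is_deg
    }
    dmp_fc = {
        row.peak_id: 2.0 ** (cfg.dmp_log2fc if row.dmp_direction == "up"
                             else -cfg.dmp_log2fc)
        for row in truth.peaks.itertuples(index=False) if row.is_dmp
    }

    peak_cols: Dict[str, np.ndarray] = {}
    gene_cols: Dict[str, np.ndarray] = {}
    peak_ids = truth.peaks["peak_id"].to_numpy()
    input_means = truth.peaks["input_mean"].to_numpy(float)
    peak_gene = truth.peaks["gene_id"].to_numpy()
    gene_means = truth.genes["base_mean"].to_numpy(float)
    gene_ids = truth.genes["gene_id"].to_numpy()

    for sample in cfg.samples:
        cond = sample.split("_")[-2]
        stressed = cond != control
        lf = lib_factor[sample]
        expr_fc = np.array(
            [deg_fc.get(g, 1.0) if stressed else 1.0 for g in peak_gene]
        )
        meth_fc = np.array(
            [dmp_fc.get(p, 1.0) if stressed else 1.0 for p in peak_ids]
        )
        mu_in = input_means * expr_fc * lf
        mu_ip = mu_in * cfg.ip_enrichment * meth_fc
        peak_cols[f"{sample}_IP"] = _nb_draw(rng, mu_ip, cfg.nb_dispersion)
        peak_cols[f"{sample}_input"] = _nb_draw(rng, mu_in, cfg.nb_dispersion)

        gexpr_fc = np.array(
            [deg_fc.get(g, 1.0) if stressed else 1.0 for g in gene_ids]
        )
        gene_cols[sample] = _nb_draw(rng, gene_means * gexpr_fc * lf,
                                     cfg.nb_dispersion)

    def _meta(cols: List[str]) -> pd.DataFrame:
        from .genomic_io import parse_sample_label, SAMPLE_META_COLS

        return pd.DataFrame({c: parse_sample_label(c) for c in cols}).T.reindex(
            columns=list(SAMPLE_META_COLS)
        )

    peak_df = pd.DataFrame(peak_cols, index=peak_ids).astype("int64")
    peak_info = truth.peaks.set_index("peak_id")[["chrom", "start", "end"]]
    peak_table = CountTable(
        peak_df, metadata=_meta(list(peak_df.columns)), feature_info=peak_info
    )
    gene_df = pd.DataFrame(gene_cols, index=gene_ids).astype("int64")
    gene_table = CountTable(gene_df, metadata=_meta(list(gene_df.columns)))
    return peak_table, gene_table


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    config: SimulationConfig
    genome: GenomeSequence
    models: List[TranscriptModel]
    replicate_peaks: Dict[str, List[List[PeakCall]]]
    truth: TruthTable
    peak_counts: CountTable
    gene_counts: CountTable


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Run every generation stage in order and return the full study bundle."""
    genome = generate_genome(cfg)
    models = generate_gene_models(cfg, genome)
    replicate_peaks, truth = generate_replicate_peaks(cfg, models, genome=genome)
    genome, truth = plant_motifs(genome, truth, cfg)
    peak_counts, gene_counts = generate_counts(cfg, truth)
    return StudyData(
        config=cfg,
        genome=genome,
        models=models,
        replicate_peaks=replicate_peaks,
        truth=truth,
        peak_counts=peak_counts,
        gene_counts=gene_counts,
    )


def write_study(study: StudyData, out_dir) -> Dict[str, str]:
    """Write FASTA/GFF3/narrowPeak/TSV artifacts; returns path mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_fasta(study.genome, out / "genome.fa")
    paths["genome"] = str(out / "genome.fa")
    write_gff3(study.models, out / "genes.gff3")
    paths["gff3"] = str(out / "genes.gff3")
    for group, reps in study.replicate_peaks.items():
        for r, calls in enumerate(reps):
            p = out / f"{group}.rep{r + 1}.narrowPeak"
            write_peaks(calls, p, narrow=True)
            paths[f"peaks_{group}_rep{r + 1}"] = str(p)
    write_count_table(study.peak_counts, out / "peaks_counts.tsv")
    paths["peaks_counts"] = str(out / "peaks_counts.tsv")
    write_count_table(study.gene_counts, out / "genes_counts.tsv")
    paths["genes_counts"] = str(out / "genes_counts.tsv")
    write_results(study.truth.peaks, out / "truth_peaks.tsv")
    write_results(study.truth.genes, out / "truth_genes.tsv")
    paths["truth_peaks"] = str(out / "truth_peaks.tsv")
    paths["truth_genes"] = str(out / "truth_genes.tsv")
    return paths


def make_abstract_truth(cfg: SimulationConfig) -> TruthTable:
    """A coordinate-free truth table for count-model studies.

    Builds ``n_true_peaks`` peaks hosted one-per-gene on dummy coordinates,
    with DMP/DEG flags drawn at the configured fractions, so the count
    generator and the differential tests can be exercised at scale without
    simulating a genome.
    """
    rng = cfg.rng(_STREAM_TRUTH)
    n = cfg.n_true_peaks
    n_genes = max(cfg.n_genes, n)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    base = rng.lognormal(np.log(cfg.mean_input_count) - 0.18, 0.6, size=n_genes)
    is_deg = rng.random(n_genes) < cfg.deg_fraction
    deg_dir = np.where(rng.random(n_genes) < 0.5, "up", "down")
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base,
            "is_deg": is_deg,
            "deg_direction": np.where(is_deg, deg_dir, ""),
        }
    )
    is_dmp = rng.random(n) < cfg.dmp_fraction
    dmp_dir = np.where(rng.random(n) < 0.5, "up", "down")
    peaks = pd.DataFrame(
        {
            "peak_id": [f"truth_{i + 1:05d}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 300,
            "strand": "+",
            "gene_id": gene_ids[:n],
            "input_mean": base[:n],
            "is_dmp": is_dmp,
            "dmp_direction": np.where(is_dmp, dmp_dir, ""),
            "motif_positions": "",
        }
    )
    for group in cfg.groups:
        for r in range(cfg.n_replicates):
            peaks[f"present_{group}_rep{r + 1}"] = True
    return TruthTable(peaks=peaks, genes=genes)
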