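import numpy as np
import pytest

from merip_conjoint import (
    GenomicInterval,
    TranscriptModel,
    UniPeak,
    annotate_peaks,
    assign_gene,
    assign_region,
    bin_density,
    partition_transcript,
    summarize_distribution,
)
from merip_conjoint.genic_annotation import (
    CDS,
    FIVE_UTR,
    INTERGENIC,
    INTRON,
    PeakAnnotation,
    RegionIndex,
    START_CODON,
    STOP_CODON,
    THREE_UTR,
)


def _model(strand="+", exons=((1000, 2000),), cds=(1200, 1800), gene="g1"):
    return TranscriptModel(gene, f"{gene}.t1", "chr1", strand, exons, *cds)


def _unipeak(start, end, pid="u1", chrom="chr1"):
    return UniPeak(pid, GenomicInterval(chrom, start, end), frozenset({"CK"}))


def _gseg(part, label):
    return [(iv.start, iv.end) for iv in part.genomic_segments.get(label, [])]


class TestPartition:
    def test_plus_strand_single_exon(self):
        part = partition_transcript(_model("+"))
        assert _gseg(part, FIVE_UTR) == [(1000, 1100)]
        assert _gseg(part, START_CODON) == [(1100, 1300)]
        assert _gseg(part, CDS) == [(1300, 1700)]
        assert _gseg(part, STOP_CODON) == [(1700, 1900)]
        assert _gseg(part, THREE_UTR) == [(1900, 2000)]
        assert _gseg(part, INTRON) == []

    def test_minus_strand_mirrors_windows(self):
        part = partition_transcript(_model("-"))
        assert _gseg(part, START_CODON) == [(1700, 1900)]
        assert _gseg(part, STOP_CODON) == [(1100, 1300)]
        assert _gseg(part, FIVE_UTR) == [(1900, 2000)]
        assert _gseg(part, THREE_UTR) == [(1000, 1100)]

    def test_exactly_100bp_utr_trims_to_empty(self):
        part = partition_transcript(_model(exons=((1000, 2000),), cds=(1100, 1800)))
        assert _gseg(part, FIVE_UTR) == []
        assert _gseg(part, START_CODON) == [(1000, 1200)]

    def test_short_cds_consumed_by_windows(self):
        part = partition_transcript(_model(cds=(1400, 1550)))  # 150 bp CDS
        assert _gseg(part, CDS) == []
        # conservation still holds
        total = sum(part.tx_length(l) for l in part.tx_segments)
        assert total == 1000

    def test_windows_split_across_introns(self):
        # stop codon at spliced position inside exon 2, window spans junction
        m = _model(exons=((1000, 1500), (1700, 2200)), cds=(1200, 1950))
        part = partition_transcript(m)
        stop = _gseg(part, STOP_CODON)
        assert len(stop) >= 1
        assert sum(e - s for s, e in stop) == 200
        assert _gseg(part, INTRON) == [(1500, 1700)]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_partition_tiles_spliced_transcript(self, seed):
        """The five spliced-space regions are disjoint and sum to the
        spliced transcript length (introns accounted separately)."""
        from merip_conjoint import SimulationConfig, generate_gene_models

        cfg = SimulationConfig(
            seed=seed, n_genes=250, n_chrom=3, chrom_length=400_000
        )
        for m in generate_gene_models(cfg):
            part = partition_transcript(m)
            segs = sorted(
                seg for segs in part.tx_segments.values() for seg in segs
            )
            assert sum(e - s for s, e in segs) == m.spliced_length
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                assert e1 <= s2  # disjoint


class TestAssignRegion:
    def test_largest_overlap_wins(self):
        parts = [partition_transcript(_model("+"))]
        ann = assign_region(_unipeak(1150, 1350), parts)
        # start window overlap 150 vs trimmed CDS 50
        assert ann.region == START_CODON
        assert ann.overlap_bp == 150
        assert ann.gene_id == "g1"

    def test_tie_broken_by_stop_priority(self):
        # peak [1580,1820): trimmed CDS [1300,1700) overlap 120,
        # stop window [1700,1900) overlap 120 -> stop wins
        parts = [partition_transcript(_model("+"))]
        ann = assign_region(_unipeak(1580, 1820), parts)
        assert ann.region == STOP_CODON

    def test_unassignable_peak_is_intergenic(self):
        parts = [partition_transcript(_model("+"))]
        ann = assign_region(_unipeak(5000, 5400), parts)
        assert ann.region == INTERGENIC and ann.gene_id is None

    def test_every_peak_gets_exactly_one_label(self, demo_study):
        from merip_conjoint import find_hcpeaks, merge_conditions

        hcpeaks = {
            g: find_hcpeaks(reps, condition=g)
            for g, reps in demo_study.replicate_peaks.items()
        }
        unipeaks = merge_conditions(hcpeaks)
        parts = [partition_transcript(m) for m in demo_study.models]
        anns = annotate_peaks(unipeaks, parts)
        assert len(anns) == len(unipeaks)
        summary = summarize_distribution(anns)
        assert sum(summary.region_counts.values()) == len(unipeaks)
        assert abs(sum(summary.region_fractions.values()) - 1.0) < 1e-9

    def test_stop_centred_peaks_recover_stop_label(self):
        """With zero jitter and peaks planted on stop codons, >= 99% of
        peaks are annotated stop_codon."""
        from merip_conjoint import (
            SimulationConfig,
            find_hcpeaks,
            generate_gene_models,
            generate_replicate_peaks,
            merge_conditions,
        )

        cfg = SimulationConfig(
            seed=5, boundary_jitter_sd=0.0, replicate_presence_prob=1.0,
            intergenic_fraction=0.0, n_true_peaks=140,
        )
        models = generate_gene_models(cfg)
        replicate_peaks, _ = generate_replicate_peaks(cfg, models)
        unipeaks = merge_conditions(
            {g: find_hcpeaks(r, condition=g) for g, r in replicate_peaks.items()}
        )
        parts = [partition_transcript(m) for m in models]
        anns = annotate_peaks(unipeaks, parts)
        frac = sum(a.region == STOP_CODON for a in anns) / len(anns)
        assert frac >= 0.99


class TestAssignGene:
    def test_single_containing_gene(self):
        models = [_model("+")]
        assert assign_gene(_unipeak(1200, 1500), models) == "g1"

    def test_max_overlap_rule(self):
        models = [
            _model("+", exons=((1000, 2000),), cds=(1200, 1800), gene="gA"),
            _model("+", exons=((2100, 3200),), cds=(2300, 2900), gene="gB"),
        ]
        # peak overlaps gA by 300, gB by 120
        assert assign_gene(_unipeak(1700, 2220), models) == "gA"

    def test_below_threshold_returns_none(self):
        models = [_model("+")]
        # 400 bp peak overlapping the gene by only 80 bp
        assert assign_gene(_unipeak(1920, 2320), models) is None


class TestSummaries:
    def test_genic_percentage_from_printed_counts(self):
        anns = [
            PeakAnnotation(f"p{i}", STOP_CODON, f"g{i % 9802}", 150)
            for i in range(9904)
        ] + [
            PeakAnnotation(f"x{i}", INTERGENIC, None, 0) for i in range(831)
        ]
        s = summarize_distribution(anns)
        assert s.total == 10735
        assert s.genic_percent == 92.26
        assert s.methylated_genes == 9802
        assert s.mean_peaks_per_gene == 1.01

    def test_all_intergenic_flags_undefined_mean(self):
        anns = [PeakAnnotation(f"x{i}", INTERGENIC, None, 0) for i in range(5)]
        s = summarize_distribution(anns)
        assert s.genic_percent == 0.0
        assert s.mean_peaks_per_gene == 0.0 and not s.mean_defined

    def test_empty_input(self):
        s = summarize_distribution([])
        assert s.total == 0 and s.genic_percent == 0.0


class TestBinDensity:
    def test_midpoints_counted_in_one_bin(self):
        ivs = [GenomicInterval("chr1", s, s + 100) for s in (1000, 2000, 3000)]
        df = bin_density(ivs, bin_size=100_000)
        assert df["count"].tolist() == [3]

    def test_counts_conserve_feature_number(self):
        rng = np.random.default_rng(3)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 900_000, 57)
        ]
        df = bin_density(ivs, bin_size=100_000, chrom_lengths={"chr1": 1_000_000})
        assert df["count"].sum() == 57
        assert len(df) == 10

    def test_boundary_midpoint_goes_to_later_bin(self):
        # midpoint exactly 100000 -> bin 1
        iv = GenomicInterval("chr1", 99_950, 100_050)
        df = bin_density([iv], bin_size=100_000)
        assert df.loc[0, "bin"] == 1
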