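import numpy as np
import pandas as pd
import pytest

from merip_conjoint.differential import (
    test_diff_genes as diff_genes,
    test_diff_peaks as diff_peaks,
)
from merip_conjoint import (
    SimulationConfig,
    find_hcpeaks,
    generate_counts,
    generate_gene_models,
    generate_genome,
    generate_replicate_peaks,
    make_abstract_truth,
    partition_transcript,
    simulate_study,
)
from merip_conjoint.synthetic_data import ConfigurationError


class TestConfig:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(replicate_presence_prob=1.5)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(nb_dispersion=-0.1)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(chrom_length=0)

    def test_sub_150bp_peaks_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(peak_width_min=80)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        s1 = simulate_study(SimulationConfig(seed=4))
        s2 = simulate_study(SimulationConfig(seed=4))
        assert s1.genome.sequences == s2.genome.sequences
        pd.testing.assert_frame_equal(s1.truth.peaks, s2.truth.peaks)
        pd.testing.assert_frame_equal(s1.peak_counts.counts, s2.peak_counts.counts)
        pd.testing.assert_frame_equal(s1.gene_counts.counts, s2.gene_counts.counts)

    def test_count_stream_independent_of_genome_stream(self):
        # changing only the count model must not perturb the gene layout
        m1 = generate_gene_models(SimulationConfig(seed=4, nb_dispersion=0.1))
        m2 = generate_gene_models(SimulationConfig(seed=4, nb_dispersion=0.3))
        assert [m.exons for m in m1] == [m.exons for m in m2]


class TestGenomeAndModels:
    def test_sequences_over_dna_alphabet(self):
        genome = generate_genome(SimulationConfig(seed=2, n_chrom=1,
                                                  chrom_length=10_000))
        assert set(genome.sequences["chr1"]) <= set("ACGT")

    def test_zero_genes_is_valid(self):
        assert generate_gene_models(SimulationConfig(seed=1, n_genes=0)) == []

    def test_infeasible_packing_raises(self):
        with pytest.raises(ConfigurationError, match="pack"):
            generate_gene_models(
                SimulationConfig(seed=1, n_genes=500, n_chrom=1,
                                 chrom_length=20_000, n_true_peaks=0)
            )

    def test_structures_satisfy_minimum_sizes(self, demo_models):
        for m in demo_models:
            part = partition_transcript(m)
            assert m.cds_spliced_length >= 300
            assert m.cds_spliced_length % 3 == 0
            # both UTRs long enough that all five regions are representable
            assert part.tx_length("5'UTR") + part.tx_length("start_codon") > 0
            assert len(m.introns) <= 3

    def test_all_intervals_within_chromosomes(self, demo_study):
        lengths = demo_study.genome.lengths
        for r in demo_study.truth.peaks.itertuples(index=False):
            assert 0 <= r.start < r.end <= lengths[r.chrom]


class TestReplicatePeaks:
    def test_presence_flags_match_emitted_peaks_exactly(self, demo_study):
        truth = demo_study.truth.peaks
        for group, reps in demo_study.replicate_peaks.items():
            for r, calls in enumerate(reps):
                emitted = {c.name.split(f"{group}_rep{r + 1}_")[1] for c in calls}
                flagged = set(
                    truth.loc[truth[f"present_{group}_rep{r + 1}"], "peak_id"]
                )
                assert emitted == flagged

    def test_perfect_concordance_recovers_truth_exactly(self):
        cfg = SimulationConfig(
            seed=9, replicate_presence_prob=1.0, boundary_jitter_sd=0.0
        )
        models = generate_gene_models(cfg)
        replicate_peaks, truth = generate_replicate_peaks(cfg, models)
        for group, reps in replicate_peaks.items():
            hc = find_hcpeaks(reps)
            got = {(h.interval.start, h.interval.end) for h in hc}
            expected = set(zip(truth.peaks["start"], truth.peaks["end"]))
            assert got == expected

    def test_single_replicate_peaks_excluded_from_hcpeaks(self, demo_study):
        truth = demo_study.truth.peaks
        group = "9311_CK"
        pres = truth[[f"present_{group}_rep{r}" for r in (1, 2, 3)]].sum(axis=1)
        singles = truth[pres == 1]
        if len(singles) == 0:
            pytest.skip("no single-replicate peaks at this seed")
        hc = find_hcpeaks(demo_study.replicate_peaks[group])
        for r in singles.itertuples(index=False):
            for h in hc:
                if h.interval.chrom == r.chrom:
                    assert not (r.start < h.interval.end and h.interval.start < r.end)

    def test_recall_matches_binomial_two_of_three(self):
        """hcpeak recall vs truth ~ P(>= 2 of 3 present) = 0.972 at
        presence 0.9, within Monte-Carlo error."""
        cfg = SimulationConfig(
            seed=7, n_true_peaks=1000, n_genes=1000, n_chrom=4,
            chrom_length=800_000, boundary_jitter_sd=0.0,
            intergenic_fraction=0.05, cultivars=("9311",),
        )
        models = generate_gene_models(cfg)
        replicate_peaks, truth = generate_replicate_peaks(cfg, models)
        recalls = []
        for group, reps in replicate_peaks.items():
            hc = find_hcpeaks(reps)
            starts = {
                (h.interval.chrom, h.interval.start, h.interval.end) for h in hc
            }
            hits = sum(
                (r.chrom, r.start, r.end) in starts
                for r in truth.peaks.itertuples(index=False)
            )
            recalls.append(hits / len(truth.peaks))
        expected = 3 * 0.9**2 * 0.1 + 0.9**3  # 0.972
        margin = 3 * np.sqrt(expected * (1 - expected) / len(truth.peaks))
        for rec in recalls:
            assert abs(rec - expected) < margin


class TestCounts:
    def test_poisson_limit_variance_to_mean(self):
        cfg = SimulationConfig(
            seed=3, n_true_peaks=500, n_genes=500, nb_dispersion=0.0,
            dmp_fraction=0.0, deg_fraction=0.0,
        )
        truth = make_abstract_truth(cfg)
        _, gtab = generate_counts(cfg, truth)
        arr = gtab.counts.to_numpy(float)
        ratio = arr.var(axis=1, ddof=1) / arr.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_planted_effects_recovered_inside_design_region(self):
        """Well inside the planted-effect region (|log2FC| = 2.5, phi = 0.1)
        the full differential stage recovers DMPs and DEGs with sensitivity
        >= 0.9 and median log2FC within +-0.3 of truth."""
        cfg = SimulationConfig(
            seed=7, n_true_peaks=1500, n_genes=1500, nb_dispersion=0.1,
            dmp_log2fc=2.5, deg_log2fc=2.5,
        )
        truth = make_abstract_truth(cfg)
        ptab, gtab = generate_counts(cfg, truth)
        dp = diff_peaks(ptab, "9311_CK", "9311_Cd")
        dg = diff_genes(gtab, "9311_CK", "9311_Cd")
        tp = truth.peaks.set_index("peak_id")
        tg = truth.genes.set_index("gene_id")
        pj = dp.join(tp)
        gj = dg.join(tg)
        planted_p = pj[pj.is_dmp]
        planted_g = gj[gj.is_deg]
        assert (planted_p.fdr < 0.05).mean() >= 0.9
        assert (planted_g.fdr < 0.05).mean() >= 0.9
        signed_p = np.where(
            planted_p.dmp_direction == "up", planted_p.log2fc, -planted_p.log2fc
        )
        signed_g = np.where(
            planted_g.deg_direction == "up", planted_g.log2fc, -planted_g.log2fc
        )
        assert abs(np.median(signed_p) - 2.5) < 0.3
        assert abs(np.median(signed_g) - 2.5) < 0.3

    def test_dmp_changes_enrichment_not_expression(self, demo_study):
        truth = demo_study.truth
        dmp = truth.peaks[truth.peaks.is_dmp & (truth.peaks.gene_id != "")]
        deg_genes = set(truth.genes.loc[truth.genes.is_deg, "gene_id"])
        clean = dmp[~dmp.gene_id.isin(deg_genes)]
        counts = demo_study.peak_counts
        ck_in = counts.counts[counts.samples_in("9311_CK", "input")].mean(axis=1)
        cd_in = counts.counts[counts.samples_in("9311_Cd", "input")].mean(axis=1)
        ratios = (cd_in[clean.peak_id] + 1) / (ck_in[clean.peak_id] + 1)
        # input counts of DMP-only peaks do not shift between conditions
        assert abs(np.log2(ratios).median()) < 0.5
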