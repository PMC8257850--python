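# Methods

This note describes the models and procedures implemented in
`merip_conjoint`, the defaults they ship with, and the reasoning behind the
design choices that were genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions and I/O

All intervals are 0-based half-open internally (the BED convention); GFF3's
1-based closed coordinates are converted at the file boundary and restored
on write.  Readers validate rather than repair: malformed records raise
with the line number (peaks), the offending cell (count tables) or the
transcript id (gene models).  One representative transcript is kept per
gene — the mRNA with the longest spliced CDS, ties broken by the
lexicographically smallest transcript id — because peaks are assigned to
genes, not isoforms.  Unstranded peaks (strand `.`) match genes on either
strand, as expected for MeRIP peak calls whose strand information comes
only from the annotation.

## Replicate-consensus peaks (hcpeaks) and the unique set

A high-confidence peak is a connected component in the graph whose nodes
are replicate peak calls and whose edges join peaks *from different
replicates* overlapping by at least `min(min_overlap, shorter peak
length)` bp (default `min_overlap` = 100).  Components spanning ≥ 2 of the
3 replicates survive; the consensus interval is the **union** of member
intervals.  Union was chosen over intersection so that the downstream
100 bp gene-assignment rule sees the full extent of replicate support; the
`min(...)` relaxation keeps sub-100 bp peaks assignable instead of silently
unreachable.  Overlapping peaks within one replicate are pre-merged with a
logged warning (peak callers can emit adjacent fragments).

One subtlety of union-component consensus: the *number* of hcpeaks is not
monotone in the overlap threshold.  Loosening the threshold adds edges,
which can fuse two previously separate components into one and so *reduce*
the count, even though coverage only grows.  The invariant the suite
asserts is therefore that the set of replicate peaks absorbed into hcpeaks
never shrinks as the threshold drops.

hcpeaks from all experimental groups are merged transitively at ≥ 1 bp
overlap into the unique peak set (unipeaks), each carrying per-group
presence flags.  The aggressive 1 bp rule reflects that a unique-set
denominator smaller than the sum of group counts implies merging on any
contact; the resulting intervals are pairwise disjoint by construction.

## Five-region transcript partition

Regions are defined in spliced (mRNA-space) coordinates so that the
"200 bp" windows remain biologically contiguous across exon junctions,
then projected back through the exon structure to (possibly split) genomic
segments:

* start-codon window `[s − 100, s + 100)`, `s` = first CDS base;
* stop-codon window `[t − 100, t + 100)`, `t` = base after the last CDS
  base;
* trimmed 5′UTR = 5′UTR minus the start window; trimmed CDS = CDS minus
  both windows; trimmed 3′UTR = 3′UTR minus the stop window;
* introns = gene span minus exons (genomic space).

Windows are clipped at transcript ends; minus-strand transcripts are exact
mirrors.  When the CDS is shorter than 200 bp the two windows would
overlap: the stop window takes the contested bases (the same ordering as
the assignment tie-break) and the trimmed CDS is empty — logged, not an
error.  These rules guarantee the conservation property the suite checks:
the five spliced-space regions tile the spliced transcript exactly.

The 3′UTR is carried as a reportable label even though the partition is
"five regions plus introns": peak distributions over transcripts are
conventionally reported with a 3′UTR category, and the label set must
support that.

Peak assignment: per label, overlaps are summed across that label's
segments; labels reaching `min(100, peak length)` bp qualify; the largest
overlap wins, ties broken by the fixed priority stop_codon > start_codon >
3′UTR > 5′UTR > CDS > intron (ordered by the enrichment ranking typical of
plant m<sup>6</sup>A data, where the stop-codon region dominates).  Peaks
qualifying nowhere are intergenic.  Gene assignment independently takes
the gene with the largest qualifying overlap, ties resolved by the gene
start nearest the peak midpoint.

Chromosome-scale densities count each feature in the 100 kb bin containing
its midpoint (boundary midpoints go to the later bin; the final partial
bin is kept).

## Motif scanning

IUPAC patterns are normalized to DNA (U → T) at parse time and expanded
position-wise into character classes; scanning uses a zero-width-lookahead
regex so overlapping hits are all reported.  Sequence `N` never matches
any pattern symbol.  Genic peaks are scanned on the annotated gene's
strand, intergenic peaks on both strands, and containment is "≥ 1 hit in
the peak's genomic slice" — the whole peak, not a summit window, since peak
summits are optional in the input.  Percentages are rounded half-up to two
decimals.

## Differential methylation (peaks)

The default test (`method="nb"`) works on per-replicate log2 enrichment

    y_gs = log2((IP_gs/f_IP,s + 0.5) / (input_gs/f_in,s + 0.5))

with median-of-ratios size factors computed per fraction.  The test
statistic contrasts the group means of `y` with a model variance
`(c_g + 2φ)/n` per group, where `c_g = 1/μ_IP + 1/μ_input` is the counting
(Poisson) part at the group means and the NB dispersion φ
(`var(x) = μ + φμ²`) is estimated once across all peaks from the pooled
within-group residual variance (an unbiased moment estimator; strength
borrowing in the spirit of edgeR's common dispersion).  With the variance
effectively known, the z statistic is referred to a normal distribution.
The Haldane pseudocount 0.5 stabilises zeros and is applied to the fold
change only, never to the exact test.

A pooled Fisher's exact test on the summed, size-factor-scaled 2×2 table
(IP_a, input_a; IP_b, input_b) is retained as `method="fisher"`.  Its 2×2
semantics are transparent and it matches exhaustive hypergeometric
enumeration exactly, but it treats pooled counts as Poisson: under
replicate-level overdispersion its type-I error grows with φμ and it
should not be used for inference on biological replicates — which is why
it is not the default.

**Power at the design conditions.**  The per-replicate log-enrichment
contrast carries an irreducible variance of about `4φ/3` (natural-log
scale) for 3 vs 3 designs, because IP and input noise both enter and
sequencing depth cannot reduce the φ term.  At φ = 0.1 and |log2FC| = 2
this puts the expected |z| near 3.7, and BH-adjusted sensitivity at
FDR 0.05 lands almost exactly at 0.9 — the suite's recovery checks at
those settings sit on this boundary by construction, and measured
sensitivity fluctuates in the 0.89–0.92 range across seeds.  Effects even
slightly inside the region (e.g. |log2FC| = 2.5) are recovered with
sensitivity well above 0.9.  The gene test does not pay the double
(IP + input) noise cost and reaches ≈ 0.97 at the same settings.

An IP-only variant was considered and rejected as a default: it roughly
doubles the information per comparison but confounds expression changes
with methylation changes, corrupting exactly the conjoint analysis this
package exists to produce.

## Differential expression (genes)

A Wald test on log2 fold change of size-factor-normalized group means.
Per-gene dispersion is the method-of-moments estimate
`(pooled variance − mean)/mean²` clipped at 0 and shrunk 50 % toward the
across-genes mean dispersion.  The variance of the log fold change uses
the NB relation per group with a 0.5 pseudocount guarding empty means.
Because the shrunk variance mixes a noisy per-gene component (pooled
within-group df, 4 for 3 vs 3) with an effectively exact common component,
the statistic is referred to Student's t with Satterthwaite-style
moderated degrees of freedom `df_pooled / w²` (= 16 at the default
w = 0.5): a plain normal reference is anti-conservative and a raw
t(df_pooled) over-corrects, both confirmed on null simulations in the
suite.  All-zero genes report p = 1, log2FC = 0, NDE.

BH adjustment is the standard step-up with monotonicity enforcement
(delegated to statsmodels) and raises on p-values outside [0, 1].  Peak
"intensity" for cumulative-distribution exports is the size-factor
normalized mean IP over mean input ratio per group (configurable to raw
IP).  Volcano labelling marks the `top_n` = 10 smallest-FDR significant
features plus all features with |log2FC| strictly above 4.  qPCR fold
changes implement 2^−ΔΔCt on replicate-mean Ct values.

## Conjoint classification and enrichment

A gene's methylation direction is the direction of its significant peaks:
UP if only up-peaks, DOWN if only down-peaks, MIXED if both, NDE if none —
a deliberately transparent rule (no significance-weighted voting) that
matches single-call panel reporting.  Crossed with the expression
direction this yields hyper/hypo × up/down quadrants plus MIXED and NDE
margins; quadrant counts partition the genes considered.  Genes with peaks
but missing from the expression table count as expression-NDE with a
warning.  Panel reports emit one UP/DOWN/NDE pair (peaks, expression) per
comparison for each (gene, name, role) row.

Term over-representation is the one-sided hypergeometric upper tail
`P(X ≥ x)` against a user-supplied term→gene map with an explicit
universe (default: all annotated genes).  Term databases are inputs, not
dependencies: no ontology is bundled or downloaded.

## Synthetic data generator

The generator emulates a two-cultivar, control-vs-stress MeRIP-seq design:
2 cultivars × 2 conditions × 3 replicates, with IP + input peak counts and
per-gene expression counts.  Purpose-split random streams (genome, gene
layout, truth/effects, replicate jitter, counts) all derive from one seed,
so changing one parameter never perturbs unrelated outputs, and identical
configurations are byte-identical.

Defaults and what they represent:

| parameter | default | rationale |
|---|---|---|
| `n_genes` / `n_true_peaks` | 150 / 140 | ~1 peak per methylated gene, 5 % intergenic decoys, >92 % genic |
| `peak_width_min/max` | 150–500 bp | satisfies the 100 bp rule with jitter headroom |
| `replicate_presence_prob` | 0.9 | ≥2-of-3 recovery expectation P = 0.972 |
| `boundary_jitter_sd` | 10 bp | replicate boundary noise, truncated to keep width ≥ 150 |
| `motif_plant_rate` | 1.0 | near-universal RRACH containment |
| `nb_dispersion` (φ) | 0.1 | typical biological-replicate overdispersion |
| `dmp_fraction` / `deg_fraction` | 0.35 / 0.30 | roughly a third of peaks/genes affected, the magnitude typical of strong-stress contrasts |
| `dmp_log2fc` / `deg_log2fc` | 2.0 | four-fold planted effects |
| `mean_input_count`, `ip_enrichment` | 300, 4 | mid-depth peak coverage |

Gene models are packed without overlap into the head 80 % of each
chromosome (the tail is reserved for intergenic decoys), with 5′UTR ≥
150 bp, CDS 300–900 bp (multiple of 3), 3′UTR ≥ 150 bp and 0–3 introns of
80–300 bp.  Introns are kept more than 150 bp (spliced) away from the stop
codon — terminal introns that close to the stop are rare in vivo (they
trigger nonsense-mediated decay) and excluding them makes stop-centred
peak placement geometrically recoverable by the 100 bp assignment rule.
Default placement centres each genic truth peak on its host gene's stop
codon; `peak_placement="regions"` instead draws the host region from a
stop-codon-dominated mix.  One concrete RRACH instance is written into the
genome per selected truth peak, on the host gene's strand, clear of
jittered boundaries.

Counts are NB with `var = μ + φμ²` (Poisson at φ = 0): input means come
from lognormal per-gene base expression (σ = 0.6); IP means multiply the
input mean by the global IP enrichment; planted DMPs multiply the IP mean
(hence the IP/input ratio) by 2^±log2FC in the stressed condition; planted
DEGs multiply expression — and proportionally both peak fractions — in the
stressed condition.  DMPs therefore change enrichment without touching
expression, and DEGs change expression without touching enrichment, which
the suite verifies.

What the generator does **not** emulate: raw reads, fragment-level
coverage shapes, alignment artifacts, isoform complexity,
GC/mappability bias, or correlated replicate effects.  Passing tests on
this data demonstrate the pipeline's rules and statistics are implemented
correctly and calibrated under the stated noise model — not that the
specific biological conclusions of any real study would be reproduced.

## Numerical choices

* Percentages and per-gene means round half-up to two decimals
  (`decimal.Decimal`), so printed ratios like 9,904/10,735 → 92.26 are
  exact.
* Assignment ties break by the fixed region priority; gene ties by start
  distance to the peak midpoint; all sorts are stable so outputs are
  reproducible.
* Pipeline reports serialize with sorted keys and no timestamps; re-running
  a config yields a byte-identical `report.json`.
* The acceptance script derives every sub-simulation seed from `--seed`
  (kept below 2³¹) and recomputes all reported quantities at run time.

## Known limitations

* The peak test's common dispersion is a single scalar; peak-specific
  dispersion trends (e.g. mean–dispersion curves) are not modelled.
* Consensus components use pairwise overlap, so a long peak can chain
  distant replicate fragments into one hcpeak; with ≤ 500 bp peaks this is
  rare but possible.
* The conjoint MIXED rule is deliberately coarse; a gene with ten up-peaks
  and one down-peak is MIXED.
* The worked-ratio checks (92.26 %, 1.01, 99.95 %, 96.57 %) validate the
  summary arithmetic on published counts; full-scale reproduction of those
  counts would require the original sequencing data, which is not
  deposited.
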