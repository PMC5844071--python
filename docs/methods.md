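# Methods

## The analysis model

The package treats a ChIP-Seq experiment at *region* granularity: the unit of
inference is an annotated gene body (ORF) or an intergenic gap, not a
base-pair peak call. This matches how occupancy is reported for gene-dense
genomes (the *Tetrahymena* macronucleus averages ~2 kb genes separated by
sub-kilobase gaps), where per-gene enrichment and the identity of the flanked
regulatory space are the quantities of interest.

**Partition.** Gene models are converted to 0-based half-open coordinates
internally (GFF3's 1-based inclusive convention converted on read/write; all
report TSVs emit 1-based inclusive coordinates for genome-browser
cross-checking). Overlapping or bookended gene models are merged into one
genic span, retaining member ids — region lists must be disjoint for the
partition to tile, and how the original annotation handled nested models is
not recoverable, so merging is our convention. Terminal gaps (scaffold ends)
are kept but flagged `edge` and never receive a two-flank class.

**Fold enrichment.** FE of a region is
`((ip_sum + c)/ip_total) / ((input_sum + c)/input_total)` on per-base depth
sums — i.e., IP density over input density after library-size normalization
by total track signal. The pseudocount `c` (default 1 depth-unit per region)
prevents division by zero and biases ratios toward 1 only for regions with
negligible signal; with `c = 0` and zero input the value is +inf and the
region is flagged. Regions whose input density falls below 10% of the genome
mean are flagged `low_input`, not dropped. Whether read counts or base-pair
coverage feeds the sums is the caller's choice: bedGraph values are used as
given, BAM input is reduced to read-spanning base depth (optional 5′→3′
fragment extension).

**Bins.** Threshold bins default to ≥2/≥4/≥6/≥8 interpreted as half-open
intervals [2,4), [4,6), [6,8), [8,∞); a `cumulative_bins` switch labels by
highest cleared threshold instead, since published figure legends often mix
the two readings.

**Strong peaks.** A region "has a strong peak" when a sliding window (width
200 bp, step 50 bp) inside the region reaches window-level FE at or above
the first bin threshold *and* holds at least 5 IP depth-units. The summit is
the center of the best window (ties → leftmost); regions shorter than the
window collapse to one window. This operationalizes the distinction between
"everything above threshold" and "regions with a localized peak" that
region-level lists otherwise conflate; all parameters live in
`EnrichmentConfig` and are echoed in report headers because the resulting
counts depend on them.

**Expression tiers.** Genes with data are ranked descending (ties broken
stably by gene id) and cut at the top ⌈0.09·n⌉ (HIGH) and next ⌈0.29·n⌉
(MODERATE); the remainder is LOW_NO and genes absent from the expression
table are NO_DATA — a first-class tier, since real annotations always exceed
the RNA-Seq ranking. The 9%/29% defaults reproduce the global fractions of
the vegetative *Tetrahymena* ranking this analysis is calibrated to; both
are configurable and a pre-tiered table is accepted. Tiering uses only the
ordering, so FPKM, counts, or ranks are interchangeable.

**Intergenic classification.** Strand alone determines which end of each
flanking gene abuts a gap (a `+` left neighbor abuts via its 3′ end, a `-`
one via its 5′ end; mirrored on the right). A flank is *addressed* when the
summit lies within `d_max` (default 300 bp) of its end, or unconditionally
when the region is at most `both_flank_len` (default 2·d_max) long. Addressed
ends map onto: one 5′ → promoter(single); one 3′ → terminator(single); 5′+5′
→ bidirectional promoter; 3′+3′ → shared terminator; 5′+3′ →
promoter/terminator overlap; none → unclassified. The published five-way
grouping this reproduces was done by visual browser inspection, so the
proximity rule is necessarily our formalization: `d_max` is a free parameter
reported in output headers, and UNCLASSIFIED is allowed rather than forcing
every region into a named class, which would hide the convention's effect.
Regions without a strong peak use their midpoint as summit, flagged.
Composite categories: an occupied ORF is promoter+ORF when an enriched
intergenic region addresses its 5′ end under a promoter-type class, and
ORF+terminator analogously; the overlap class feeds neither, being its own
category in the five-way split.

**Over-representation.** Term enrichment of the occupied gene set is a plain
hypergeometric upper tail with BH FDR across tested terms. Network-aware
term grouping (STRING-style) is deliberately not reproduced: the scientific
claim supported is "which categories are over-represented", not any
network statistic. Unannotated genes stay in the universe (conservative) by
default.

**ChIP-qPCR.** Per target, a standard curve Cq = a + b·log₁₀(% input) is
least-squares fitted on an input dilution series (100/10/1% in the modeled
design); a measured Cq inverts to percent input as 10^((Cq−a)/b), and
amplification efficiency is 10^(−1/b) − 1 (100% at b ≈ −3.3219). Fold
enrichment per replicate is percent input relative to the undiluted input
reference. Tagged vs untagged groups are compared with a two-sided t-test —
Welch by default because the modeled design has unequal group sizes (4 vs 3)
and no variance-homogeneity argument; Student's t is a config switch. SEM is
sd/√n across biological replicates per group. Two identical zero-variance
groups give t = 0, p = 1 by convention.

**Peptide array.** Replicate spot intensities are averaged arithmetically;
raw (out-of-[0,1]) arrays are min–max normalized across the array first
(auto-detected, overridable — the normalization producing published 0–1
scales is rarely stated). Ranking is descending with id tie-break. Each
modified residue (e.g., H4 R3me2s) is checked against supplied histone
sequences; a residue absent from the target species' histone is flagged,
because binding to a non-conserved peptide cannot be read as in-vivo
specificity.

## The synthetic-data generator

The generator emulates the study conditions: 200 genes on 2 chromosomes,
log-normal gene lengths (median 1.5 kb, σ=0.4) and internal gaps (median
400 bp, σ=0.5), expression tiers at 9%/29%, 40 occupied genes with planted
region-level FE in 2–13×, planted intergenic classes
{10 promoter, 5 terminator, 3 bidirectional, 3 shared-terminator, 2 overlap},
and per-base Poisson coverage at λ=30 (a negative-binomial switch models
overdispersion). Each chromosome carries a 500 kb gene-free margin at both
ends, bringing the genome to ~2.4 Mb: library-size normalization needs the
planted enrichment mass to be small relative to the genome for planted
ratios to be recoverable, and the margin supplies that background at the
genome scale the recovery analysis assumes.

Planted FEs are *post-normalization region-level* truths. Because total
signal normalizes the ratio, enrichment planted anywhere deflates apparent
FE everywhere else; the generator compensates analytically, scaling profiles
by s = (G − ΣLᵢ)/(G − ΣtᵢLᵢ) so the measured ratio equals the planted value
in expectation (a validator rejects configurations whose planted mass
exceeds the genome). Genic enrichment is a plateau over the gene body;
intergenic enrichment is a triangular bump (400 bp base) at the planted
summit, height-scaled so the region mean hits the target.

Planted intergenic FEs default to 4–13× — the fourfold cutoff is the
threshold at which intergenic regions are positionally classified in this
kind of analysis — while genic FEs span the full 2–13×. Planted classes
occupy every third internal gap so no gene flanks two planted gaps; flank
strands and gap lengths are set per class (short gaps ≤ 2·d_max for the
two-gene classes, long gaps with an off-center summit for the single-gene
classes) and remaining strands are random, guaranteeing all four orientation
configurations. Tier–occupancy coupling is controlled by ρ ∈ [0,1]: sampling
weights interpolate between uniform and strongly tier-preferring, and
planted FE increases with tier under the same ρ, so ρ ≥ 0.8 produces the
non-decreasing HIGH-fraction trend across FE bins that the trend report
detects.

Expression values are drawn from disjoint per-tier ranges (HIGH 10³–10⁴,
MODERATE 10²–10³, LOW_NO 1–10²), so rank-based tiering recovers the planted
tiers exactly. qPCR Cq values are a + b·log₁₀(true %) + N(0, σ) with
defaults a=26.64, b=−3.32, σ=0.15 and targets mirroring a strongly enriched
set (folds 12.75/9.50/9.38) plus an unenriched control (1.0); array
replicate intensities are affinity + N(0, 0.02) clipped to [0,1], with a
default affinity vector shaped like an acetyl-lysine reader (acetylated
H3/H2A/H4 peptides high, methyl marks low).

What the generator does *not* model: fragment-size distributions, GC or
mappability bias, duplicate reads, replicate structure in coverage, or any
sequence content. Passing tests therefore demonstrate the pipeline's
arithmetic and logic under idealized noise, not robustness to real-data
artifacts; on real tracks the strong-peak parameters and `d_max` should be
tuned against browser inspection.

## Numerical and design choices

- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from one integer; fixed seed ⇒ byte-identical output files
  (checksummed in tests). Report rows order by descending FE with
  lexicographic id tie-break; mergesort keeps sorts stable.
- Degenerate inputs: empty region lists give empty tables; an empty
  expression table makes every gene NO_DATA; a missing expression file skips
  tier reports with a warning rather than aborting; stage errors abort the
  pipeline with the stage name and a nonzero exit.
- Tolerances used in tests reflect the noise model: at λ=30 over ≥500 bp
  regions, planted-FE sampling error is ~1–2%, so the ±10% recovery bound
  holds with wide margin; qPCR power (true fold 4, σ_Cq=0.1, 4v3
  replicates) exceeds 95% at α=0.05 over 200 simulations.
- Problem sizes: tests and the acceptance script run the full default
  simulation (200 genes, ~2.4 Mb, λ=30) — about one second per replicate —
  using 2 replicates for FE recovery (126 planted regions), 10 seeds for
  class recovery and the monotone trend, and smaller 40-gene genomes for
  file-roundtrip and pipeline-orchestration tests.

## Known limitations

- The positional classifier is purely geometric; it uses no TSS, motif, or
  nucleosome evidence, so "promoter" means 5′-proximal intergenic space.
- Library-size normalization is the only background model; there is no
  local background (MACS-style) or replicate-aware (IDR) statistic.
- Transcript structure (introns, UTRs, isoforms) is out of scope; the
  analysis unit is the whole ORF.
- The hypergeometric ORA ignores term ancestry (no GO DAG propagation).
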