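# Methods

## Problem setting

Wheat pre-breeding programmes introgress chromosome segments from wild
relatives (*Aegilops tauschii*, *Secale cereale*, *Thinopyrum
ponticum*) into elite backgrounds. Locating those segments in a
sequenced diversity panel, and connecting them to stress phenotypes,
needs no de-novo assembly: a donor segment betrays itself in
enrichment-capture data through (i) depressed read mapping over
diverged sequence and (ii) SNP alleles private to the donor species.
`introtrace` implements that mapping analysis, the accompanying
stress-phenotype statistics, and synteny-based anchoring of candidate
intervals onto donor assemblies.

## Coverage deviation

Reads per line are counted in 1 Mbp windows (the default; 0-based
half-open internally, printed as Mbp). Counts are normalized by each
line's total filtered mapped reads, giving `c_i`. Because windows
differ in intrinsic mappability, each window is compared with the same
window in the rest of the panel: with `m_i` the across-line median
normalized count, the deviation of a line is

    d_i = c_i / (m_i * eps),   eps = median_i(c_i / m_i)

over non-masked windows, so `median(d) = 1` for every line. The
published description defines `eps` as "the median d value", which is
circular as printed; the pre-ratio median used here is the unique
fixed-point-free reading and makes the median-one property exact.
Windows with `m_i = 0` are masked and invisible to `eps`, outlier
scoring and block calling — they are not zero-filled.

Significance: MAD z-scores `z_i = (d_i − median(d)) / (1.4826 ·
MAD(d))`, pooled genome-wide per line, flagged beyond the two-sided
normal quantile at probability 0.99 (default). Only *low* flags count
as introgression evidence; high flags are kept for QC. A zero MAD is
an error (windows too coarse to carry spread), not a silent pass.

## Donor-specific SNPs

Accession-level calls are filtered (homozygous: 10–60 reads supporting
the alternative allele, allele frequency ≥ 0.8; heterozygous: 10–60
total reads, biallelic with ≥ 5 reads per allele, AF ≥ 0.3). The
allele-frequency denominator for homozygous sites is alt/total reads —
configurable, since conventions differ. A SNP is *species-specific*
when present in ≥ 1 accession of exactly one donor and absent from
every other donor accession and every wheat cultivar; donor sets are
therefore pairwise disjoint by construction.

Panel SNPs match a donor set on identical (chrom, pos, alt);
multi-allelic records are decomposed first. The per-window enrichment
ratio is a line's matched count divided by the plain panel mean for
that window (all lines included, zero counts included — carriers
deflate the ratio when many share a segment, a documented property of
the plain-mean denominator). Ratios below 1.45 are dropped from
evidence; exactly 1.45 is retained. Windows with zero panel mean yield
no evidence.

Panel genotype filtering for association input: heterozygous calls,
quality < 30 or depth < 5 are set missing; homozygous-reference is
asserted at ≥ 5 reads with no alternative call; loci with > 10%
missing data or minor allele frequency < 5% are dropped.

## Segment calling

A window is *evidence* when low-flagged or ratio-retained. Maximal
runs of evidence windows are merged, bridging gaps of ≤ 2 windows when
every bridged window carries ≥ 1 matched donor SNP — donor sequence
nearly identical to the host maps well, so true blocks contain
unflagged windows that still carry donor SNPs. Block boundaries must
themselves be low-flagged: retained-ratio windows are interior
evidence only, because a stray matched SNP in a near-empty window
produces a huge ratio and would otherwise extend blocks outward.
Blocks need ≥ 3 evidence windows and a strict majority of
low-flagged windows. The gap (2), minimum size (3) and majority rules
are calling decisions of this package, not published constants.

Zygosity: heterozygous requires mean segment deviation ≥ 0.65 (midway
between the ~0.5 expected homozygous and 1.0 background) *and* a
heterozygous majority (≥ 0.5) of matched donor SNPs in the segment;
otherwise homozygous. With no matched SNPs the coverage criterion
decides alone, with a warning.

The *core region* of a focal marker is the intersection over carriers
of their segment unions, minus every excluded line's segments, largest
interval kept; an empty result is valid. The marker-level wrapper
drops carriers whose calls do not overlap the marker position
(call/genotype discordance) with a warning, so one under-called line
cannot void the core; the underlying intersection operator keeps
strict semantics.

## Stress phenotypics

One record per line × environment (across-year adjusted means;
mixed-model estimation is upstream of the accepted input). Derived
traits: GM2 = (YLD/TGW)·1000, BM_PM = YLD/HI, SM2 = BM_PM/(shoot dry
weight per shoot), PGF = (DTM − DTA)/DTM.

Stress susceptibility index per line, against panel means:
SSI = (1 − Yht/Yyp) / (1 − Ȳht/Ȳyp). SSI = 1 at the panel-average
proportional loss, 0 for lossless lines; it is scale-invariant and its
Yyp-weighted panel mean is identically 1. Broad-sense heritability
from variance components over e environments and r replicates:
H² = σg² / (σg² + σge²/e + σ²/(re)) ∈ [0, 1].

Group comparisons use Welch's two-tailed t-test (no equal-variance
assumption) with tiers p < 0.01 (*), < 0.001 (**), < 0.0001 (***);
correlations are Pearson with pairwise deletion, displayed when
p ≤ 0.01. Allele-stacking effects class lines by their combination at
the focal markers, report percent change (or °C difference) versus the
all-major reference class, one-way ANOVA and Tukey HSD (family level
0.05). The single-allele helper reports both the additive
(difference of percent changes) and multiplicative (ratio of
fold-changes) no-epistasis conventions, which disagree slightly on
rounded inputs; neither is asserted as canonical.

## Synteny anchoring

Whole-genome alignment blocks (PAF) are filtered by length and MAPQ
(presets: host↔donor 2.5 kb/Q40; donor↔donor 5 kb/Q40). Interval
boundaries are projected linearly through the covering block (no
CIGAR-level mapping — window-scale use case), strand-aware; a boundary
in an alignment gap snaps to the nearest block edge with a warning.
The target chromosome is chosen by aligned-length majority among
overlapping blocks. Genes are extracted from GFF3 (1-based closed,
converted to half-open) by any-overlap, the conservative choice for
candidate capture. Protein anchors, when available, are accepted as a
pre-tabulated table and used as fallback; running aligners is out of
scope.

## Synthetic panel generator

The generator emulates the data structure the analysis assumes, not
read-level reality. Defaults describe a 149-line panel on 7
chromosomes × 60 windows of 1 Mbp.

* **Coverage**: negative binomial (dispersion 200, Poisson in the
  limit) around per-line mean depth (uniform 800–1600 reads/window) ×
  a log-normal per-window mappability (σ = 0.25) drawn once and shared
  across lines — sharing is what makes panel-median normalization the
  correct oracle. Within planted segments the mean is multiplied by
  0.5 (homozygous) or 0.75 (heterozygous; one host haplotype still
  maps). The implied window-to-window CV of ~8% is an
  order-of-magnitude choice for 1 Mbp capture windows after shared-
  mappability correction; realized depth is not published.
* **Donor SNPs**: Poisson per window, 5/window inside segments
  (heterozygous genotype codes in heterozygous segments), 0.2/window
  spurious background elsewhere, positions unique per line.
  Background matches are drawn independently per line, which is
  conservative for the ratio statistic: a single stray SNP in a
  near-empty window looks strongly "enriched", which is why block
  boundaries require coverage evidence.
* **Phenotypes**: line × environment value = class mean + N(0,
  residual_sd); no persistent line effect, so the noise-free limits
  are exact identities. Heat multiplies baseline yield by 1 − 0.481;
  favourable alleles act only under heat, multiplicatively on yield
  (full stack ×1.565, 1B+2B partial stack ×1.243) and additively on
  canopy temperature (full stack −2.0 °C), with heterozygous carriers
  receiving the full effect (dominant expression). Default residual
  SDs: yield 45 (control) / 30 (heat) g·m⁻², CT 0.4 °C.
* **Truth**: ~22% of lines carry a homozygous chr6D-like telomeric
  segment and ~4.7% a heterozygous one, drawn from a fixed cycle of
  (start, end) pairs whose intersection — the true core — is windows
  [5, 7); a few lines carry rye/*Thinopyrum* segments elsewhere, and
  two lines with the unfavourable genotype carry non-core chr6D
  segments to exercise core-region exclusion. Carriers of the core get
  the favourable marker alleles; an additional ~9.4% carry the 1B+2B
  partial stack; exotic labels cover all carriers, topped up to 66/149.

All randomness flows from one integer seed through fixed sub-streams
(coverage, SNPs, phenotypes), so a configuration is bit-reproducible.

What passing tests on this generator do *not* show: robustness to
GC/mappability structure correlated with introgressions, LD or
pedigree structure, segmental duplications mimicking coverage loss,
or imputation artefacts — none of which are modelled.

## Numerical and degenerate-input choices

Zero mapped-read totals, all-masked profiles, zero MAD, zero variance
in correlations, carriers without segments, unparseable marker ids and
unanchorable intervals all raise errors naming the offending record;
lines missing an environment are skipped from SSI with a recorded
list. Ties in interval length resolve to the first (leftmost) largest
interval. Boundary projections round to the nearest base.

## Problem sizes

Tests and the acceptance script run desk-scale: the default 149-line
panel (1043 line-chromosomes, ~15 k SNP records) for mapping metrics,
a 400-line panel for allele-effect recovery, 200 random layouts for
interval-algebra checks, 10⁴ draws for the heritability bound. End to
end this is a few seconds on one CPU.

## Known limitations

Heterozygous-segment boundaries are intrinsically marginal: at 0.75 ×
coverage and ~8% window CV, edge windows sit ~2.5–3 σ below the
panel median, so a truncated heterozygous call occurs on some draws
(the dense-carrier region also biases the panel median slightly
downward, inflating carrier deviation values there). Recovery and
zygosity metrics in the acceptance output quantify this honestly
rather than hiding it. Sub-window breakpoints, phasing and donor
accession-of-origin are out of scope.
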