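# Methods

This note documents the models, numerical choices, and known limits of
the package. Formats, APIs, and usage live in the README.

## Genome tiling and promoter geometry

All coordinates are 0-based half-open internally; GFF3 is converted once
on read. The genome is tiled into consecutive 200-bp bins after trimming
a 200-bp end region from each chromosome. The trim convention is a
config triple (one-end vs both-ends trim, mitochondrial genome in or
out, partial terminal bins dropped); a one-time search over the eight
variants (`calibrate_tiling_convention`) shows that one-end trimming of
the sixteen nuclear chromosomes uniquely reproduces the reference total
of 60,333 bins for R64-1-1, and that convention is frozen as the default.

Promoter geometry is strand-aware. The 1 kb upstream window of a TSS is
divided into five 200-bp subregions ordered −1000→−1; the URS window is
−600..−100. Windows running off a chromosome end are truncated and
flagged, never dropped, and coverage fractions downstream use the
truncated width. Upstream windows are *not* clipped at neighboring
genes: in the compact yeast genome that would silently change the
Intergenic rule's denominator, and the exclusion clause of the
classification already handles feature-containing subregions explicitly.

## Spike-in scaling

Reads exclusively assigned to the spike-in genome measure each sample's
depth-times-IP-efficiency nuisance, because the spike chromatin amount
is constant across samples. The scale factor for a sample is
`reference_spike_reads / sample_spike_reads`; ambiguous reads (aligning
to both genomes) are excluded from both counts. Only relative factors
matter downstream; the reference defaults to the first sample of the
design. H3ac tracks are exempt (factor forced to 1): their analysis is a
ratio to total H3 on the same bin frame, which cancels depth by
construction.

## Robust exponential regression (Pol II-independent bins)

The genome-wide coupling of Hda1 to Pol II is modeled as
`hda1 ≈ exp(α + β·rpb3)` and fitted on the log scale,
`log(hda1 + c) = α + β·rpb3`, by IRLS M-estimation with the Tukey
bisquare ψ (tuning 4.685) and the residual scale re-estimated each
iteration as the normalized MAD. Convergence: max coefficient change
< 1e−8, cap 200 iterations. A single genome-wide fit is made per
condition — the two conditions show visibly different coupling, and a
joint fit would blur exactly the shift the analysis is after.

Numerical choices that matter:

- **Pseudo-count.** `c` defaults to one tenth of the 1st percentile of
  the positive Hda1 signal. The pseudo-count exists only to guard zero
  bins; if it is comparable to the background signal it compresses
  log-residuals in quiet territory and makes the fixed residual
  threshold behave differently in quiet and active regions, inflating
  the flagged fraction among ordinary active bins well above the nominal
  tail. One tenth of the weakest real signal keeps the transform
  essentially distortion-free while remaining scale-equivariant
  (flagging is invariant to globally rescaling the track).
- **Degenerate MAD.** When half or more of the residuals are nearly
  identical — a flat background fitted exactly, or a noise-free limit —
  the MAD collapses to the tie noise and every Tukey weight vanishes.
  The scale estimator therefore falls back to the 90th percentile of
  absolute deviations (normalized by z₀.₉₀) whenever the MAD is less
  than a tenth of that estimate; for well-spread residuals the two
  agree and the MAD is used.
- **Flagging** is one-sided: standardized residual > 2.576 (the 99.5%
  normal quantile), i.e. only Hda1 excess is biologically meaningful
  here. On standard-normal residuals this flags ≈ 0.49% of bins.
- Bins with extreme Rpb3 are not trimmed; the redescending ψ
  down-weights them naturally.

At peak level, Hda1 peaks shorter than 100 bp are discarded and the rest
are split by ≥ 1 bp overlap with any Rpb3 peak into Pol II-associated
and Pol II-independent sets.

## Differential occupancy

A deliberately small NB Wald test in the DESeq2 mold: size factors by
median-of-ratios over genes with no zero count (or, preferably when
spike-in counts exist, spike-derived factors normalized to geometric
mean 1 — these do not assume that most genes are unchanged, an
assumption visibly violated when a third of the genome responds to
starvation); per-gene method-of-moments dispersion pooled across
conditions and shrunk with weight 0.5 toward a fitted a₀ + a₁/mean
trend; Wald statistic log2FC/SE with a delta-method SE on
log2(mean + 0.5); two-sided normal p; BH across testable genes. Genes
with all-zero counts are NA and excluded from the FDR. Classification
uses |log2FC| ≥ 1 and FDR < 0.01. Full DESeq2 machinery (Cox–Reid
dispersion, LFC priors, outlier replacement) is intentionally not
replicated; at the package's scale the simplified estimator is
calibrated (null p-values uniform, FDR controlled in simulation) and
recovers planted four-fold changes.

## Peak classification

Sequential rules, first match wins: (1) tRNA if the peak contains an
entire tRNA gene; (2) CDS if the peak covers ≥ 30% *of the CDS length*
of some Pol II gene (the fraction is of the coding region, not of the
peak); (3) Intergenic if the peak covers ≥ 90% of one of the five
upstream subregions of a Pol II gene and that triggering subregion
overlaps no tRNA and no other gene's CDS; (4) Others. snRNA/ncRNA
features are treated as Pol II genes for rules 2–3. Ties within a rule
resolve by highest coverage fraction, then smallest feature start, so
the outcome is independent of annotation order. Truncated subregions use
the truncated width as denominator.

## URS Poisson enrichment

For each 100-bp TSS-relative window tiling −1000..0, the observed count
is the number of RP genes whose window overlaps at least one Pol II-
independent peak. The null scatters the observed peaks uniformly over
the genome: the chance that one peak of length L touches a w-bp window
is (w + L)/G, so expected = n_genes × Σ_peaks (w + L_i)/G. The upper
Poisson tail gives p, BH across the ten windows, stars at FDR < 0.05 and
0.001. (A per-gene-window hit probability capped at 1 would be binomial;
at realistic densities the Poisson form is indistinguishable and matches
the test named in the figure legends.) Window width is configurable; the
headline −600..−100 region is the union of windows 5–9.

## Motif analysis

Consensus matching only, by IUPAC set membership (`N` in the sequence
never matches), both strands via reverse complement with hits reported
at plus-strand offsets; palindromic double-strand hits at one locus
count once. Positional concentration is a sliding 100-bp binomial test
against the uniform null (p₀ = window/region width), Bonferroni over
window positions — a deliberate simplification of CentriMo's
likelihood-ratio scan.

## Acetylation comparisons

Ratio tracks are log2((ac + ε)/(H3 + ε)) with ε defaulting to the 5th
percentile of positive H3 signal and recorded in the output. Region
values are length-weighted means over bins. WT vs *hda1Δ* over a gene
set is paired per gene: Wilcoxon signed-rank, exact null for ≤ 25
nonzero differences (zero differences dropped and counted), normal
approximation with continuity correction above; the unpaired rank-sum is
reported as a secondary. Pairing per gene is the natural reading of a
per-gene region statistic compared between strains.

## Synthetic data generator

The generator emulates the study design on a toy genome: 3 chromosomes
× 300 kb, 125 mRNA-like genes (80 constitutive, 15 starvation-repressed,
15 starvation-induced, 15 RP-like) plus 15 tRNA genes, placed left to
right with ≥ 1.5 kb spacing and snapped to the 200-bp bin grid (so
planted URS footprints are whole bins and tRNAs sit inside one bin —
real TSSs are not grid-aligned; the snapping trades that realism for
exact ground-truth bookkeeping). About a third of genes change between
conditions, matching the scale of the real starvation response, so the
median-of-ratios assumption is stressed but not absurd.

Signals: Rpb3 bin means are background (5) plus activity over the CDS;
Hda1 means follow exp(0.5 + 0.002·rpb3) with multiplicative log-normal
noise (σ = 0.25); planted Pol II-independent sites — the two whole bins
inside each RP-like URS in −N, and tRNA bins in both conditions — get an
8× excess, far above the 2.576-SD flagging threshold so recovery
properties are sharp. Each sample carries a log-normal depth nuisance
(σ = 0.3) multiplying both the track and its spike-in reads (~10% spike
share, Poisson draws at 10⁶ reads), making the true scale factors
recoverable to ~1%. Per-gene Rpb3 fragment counts are NB (dispersion
0.05, mean count ≈ 200 at mean activity) with planted 4-fold
repressed/induced classes; RP-like genes are strongly repressed in −N.
Acetylation tracks give *hda1Δ* a +0.8 log2 H4ac and +0.3 log2 H3ac
effect at URS bins in −N and +0.5 log2 H4ac at active CDS in +N. One
Rap1 consensus instance (ACACCCATACATTT) is planted per RP-like URS at a
uniform random offset. All draws descend from one seed through
independent substreams.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level artifacts (mappability,
duplicates, fragment-size structure), nucleosome positioning, correlated
noise along the genome, antibody cross-reactivity, composition-biased
spike-in recovery, and genes overlapping or nested within one another.
Problem sizes (4,497 bins, 140 genes, 20-seed repetitions) were chosen
so the full suite and the acceptance script each run in seconds on one
CPU while leaving every statistical margin wide.

## Known limitations

- The built-in Poisson bin-scan peak caller is a stand-in; externally
  called narrowPeak files are the first-class input. On overdispersed
  coverage the caller, like any Poisson model, will call peaks at
  bin-level noise above a smoothed local background.
- The NB test diverges from DESeq2 on real accession data at the few-
  percent level in called-gene counts; exact replication of published
  gene lists is out of scope.
- The exponential coupling is fitted genome-wide per condition; no
  per-chromosome or two-dimensional density modeling.
- Consensus motif matching only; no PWM scores or de novo discovery.
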