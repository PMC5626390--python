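# Methods

This note documents the models and rules `tfsig` implements, the choices
made where the underlying procedure is ambiguous, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Coordinates and formats

All genomic records are 0-based, half-open internally (the BED convention),
whatever the input dialect; the GTF-like gene-model TSV (1-based inclusive)
is converted on read by decrementing the start. The TSS of a minus-strand
gene is `end − 1`, its last covered base, so TSS arithmetic stays half-open
without off-by-one drift. Gene bodies are full transcript spans including
introns; exon-level resolution is deliberately not modelled. Peak amplitude
is the score column of BED6 or the signalValue column of narrowPeak; peaks
are never re-quantified from reads (read mapping, transcript quantification
and peak calling are all upstream of this package's scope).

## Expression pipeline

Order of operations: **collapse → low-abundance filter → offset → fold
changes / DEG calls**. The collapse keeps, per gene, the transcript with the
highest mean RPKM over all samples (ties to the lexicographically smallest
transcript id, for determinism). The filter drops genes whose per-condition
mean RPKM is below 1 in every condition; it runs on raw values because the
"< 1 RPKM" criterion reads most naturally on unshifted data, and
per-condition means (rather than per-sample values) match how replicates
are summarized everywhere else in the pipeline. The offset is the second
quartile — the median — of all RPKM cells pooled over genes and samples of
the post-collapse, post-filter table; whether the original procedure
computed it before or after collapse is not stated, so the order here is a
documented choice (computing it post-collapse keeps the offset a property
of the table actually analysed). Applying the offset twice is an error.

Fold changes are ratios of post-offset replicate means. The offset
deliberately damps ratios of low-abundance genes: a gene at RPKM 0.001
versus 0.1 reports ≈ 1.1×, not 100×. DEG calls use strict inequalities on
both criteria (> t-fold in either direction and p < 0.05) and report
direction by the side of 1 the fold change falls on. No multiple-testing
correction is applied at this stage; FDR control appears only in GSEA.

### Built-in negative-binomial exact test

Precomputed p-values (e.g. from a dedicated DE package) are first-class
input. The built-in test exists so synthetic pipelines run end-to-end; it
is a simple exact conditional NB test, not a clone of any DE tool. With
per-sample counts `NB(μ, φ)`, the group sum over n replicates is
`NB(nμ, φ/n)`; conditioning on the two-group total gives

    P(S_A = a | S = s) ∝ C(a + r_A − 1, a) · C(s − a + r_B − 1, s − a),

with `r_g = n_g/φ`, and the two-sided p-value sums the probabilities of all
splits no more likely than the observed one (the "double tail"
convention). The common dispersion φ is estimated by method of moments
pooled across **all genes** of the table, `φ̂ = Σ(v̂ − m̂)/Σ m̂²` (floor
1e−6): a per-gene estimate at 2–3 replicates is so noisy that plugging it
in makes the test strongly anti-conservative (empirically ~11% rejections
at nominal 5%), whereas the table-level estimate keeps the empirical
type-I error at ~4–5%. The test assumes comparable sequencing depth across
samples; library-size weighting is not implemented.

## Peak analytics

Assignment uses the dual rule: gene-body overlap by ≥ 1 bp, or nearest
covered base strictly within the window (default 50,000 bp) of the TSS on
either side. The stated rule mixes "< 50 kb" and "± 50 kb" phrasings; this
implementation uses strict `< window`, both directions, configurable. When
both criteria hold the single pair is labelled `in_body`. Distances are
signed, downstream-positive relative to the gene's strand, and zero when
the peak covers the TSS; a peak equidistant from two TSSs is assigned to
both and contributes its (tied) distance once to the profile. The
production path indexes gene windows with an interval tree; an all-pairs
brute-force scan exists only in the test suite, as the oracle the index is
checked against on random instances.

Condition overlap counts an A-side peak as shared when it intersects any
B peak by ≥ 1 bp (no reciprocal-fraction requirement — none is stated for
the original analysis), so shared counts are asymmetric under many-to-one
overlaps, and the "fraction shared" is per side. The high-amplitude flag
uses the linear-interpolation quantile (NumPy's default) of all amplitudes
in the set with a ≥ comparison, so an all-equal set is entirely flagged;
"top 25%" fixes no convention, and this one is configurable. Co-occupancy
reports the fraction of A peaks overlapped by B peaks plus, per A peak, the
signed offset to the nearest B-peak midpoint for co-localization
histograms.

## Signatures

Full tier: bound (≥ 1 assigned peak from the treated-condition set) AND
|log2 FC| > log2 2 with p < 0.05 AND mean RPKM > 2 in at least one
condition (raw, pre-offset means). Compact tier: binding must include a
top-quartile-amplitude peak and the fold-change bar rises to threefold.
The "mean RPKM > 2" sentence is attached to both tiers — its placement in
the source procedure is ambiguous, and applying it to both preserves the
compact ⊆ full law (it can be disabled with `min_mean_rpkm=0`).
"Transcriptionally regulated" counts both directions. Per-gene evidence
records the highest-amplitude assigned peak (ties to the smallest peak id).
Gene identity is exact string match; no symbol-aliasing layer exists, which
matters when mixing annotation sources on real data.

The knockout-collapse statistic (n reduced / enhanced / unchanged over a
gene set) ships in two modes because the original "reduced" criterion is
ambiguous: significance-gated (DEG-level call required) and raw fold-change
(< 1 vs > 1). Members absent from the expression table are reported as
absent, not silently dropped.

## GSEA

Weighted KS-style running sum: hits increment by |metric|^p normalized to 1
over hits (p = 1 by default, per the original method's recommendation),
misses decrement 1/(N − N_h); ES is the signed extremum, hence ES ∈ [−1, 1].
The null is **gene-set permutation** (random same-size sets from the ranked
universe): with 2–3 replicates per group, phenotype permutation is
degenerate, so this matches common practice at small n and is a documented
divergence from the original default. NES divides ES by the mean |null ES|
of matching sign; the nominal p is `(b + 1)/(m + 1)` where b counts
same-sign null scores at least as extreme and m the same-sign null scores —
the add-one smoothing keeps p > 0, and conditioning on sign is what makes
null p-values uniform (a denominator of n_perm would bound p near the
same-sign fraction instead). FDR q pools sign-normalized null scores across
sets against the observed scores, per the original method's scheme. The
default ranking metric is the post-offset log2 fold change (the original
choice is unstated); a signed −log10 p metric is available when precomputed
p-values exist.

## Synthetic-data generator

The generator emulates the statistical structure of a two-condition TF
study: (i) non-overlapping genes with random strands placed along
chromosomes; (ii) bound genes receive 1 + Poisson(0.6) treated-condition
peaks at normally distributed distances from the TSS (σ = 15 kb, truncated
to the window), with lognormal amplitudes well above the uniform background
peaks; (iii) a configured fraction of treated peaks is copied into the
untreated set, jittered by less than half a peak width (so overlap is
guaranteed) and shrunk in amplitude (treated peaks are stochastically
larger); the untreated set is padded with its own gene-proximal peaks so
both shared fractions can be controlled independently; (iv) responsive
genes carry planted log2 fold changes (lognormal magnitude with a floor,
60% down-regulated by default, mirroring a repressed majority) on NB counts
with a common dispersion (0.05 by default), and RPKM is computed from
counts, gene length and per-sample depth, so count-based testing and
RPKM-based thresholds are exercised coherently.

Two generator design points matter and were chosen on biological grounds:
expected counts scale with gene length (level × length, the actual
count–RPKM relationship), and responsive genes draw baseline levels from a
higher-abundance lognormal (median 150 vs 30 RPKM-like units) — planted
effects on genes near or below the global median would otherwise be erased
by the median-offset damping that the preprocessing applies *by design*,
and strongly expressed cytokine targets are the realistic regime for this
analysis. The responsive share of the library is kept moderate; planting a
large fraction of the library in responsive genes would compress observed
fold changes through depth normalization (the classic composition bias the
generator intentionally avoids at default settings, and which the pipeline,
like the original RPKM-based procedure, does not correct).

Gene spacing defaults to 100–200 kb, sparse relative to the 50 kb
assignment window, so one peak binds approximately one gene; dense gene
packing makes the bound-gene universe balloon through window overlap, which
is realistic for gene-dense loci but ruins the interpretability of planted
fractions. Presets: `study_like` (2,000 genes, 500 bound, 200 responsive
with P(responsive | bound) = 0.2, shared fractions 0.25/0.5) reproduces the
motivating study's donut and Venn structure; `strong_effect` (1,000 genes,
120 bound, 100 responsive, |log2FC| ≥ 2, sparse background) is the recovery
benchmark. The planted truth defines the true full signature as bound ∩
responsive above the twofold bar, and the true compact signature as its
restriction to genes with a planted top-quartile peak and a threefold
change.

What the generator does **not** emulate: read-level noise, replicate
correlation beyond NB dispersion, chromatin background structure,
isoform complexity, length-dependent quantification bias and
batch effects. Passing recovery tests therefore demonstrates the
correctness of the integration logic under a clean generative model, not
performance on real sequencing data.

## Numerical and determinism choices

All randomness flows from a single integer seed through NumPy PCG64
generators (the study orchestrator derives one sub-seed per stage, all
below 2³¹). Deterministic tie-breaks everywhere: lexicographic ids for
transcript collapse, ranking ties, and best-peak selection; record ordering
is (chrom, start, id). p-values snap to exactly 1 when the whole
conditional mass lies in the tail (floating-point summation would otherwise
report 1 − ε). Degenerate inputs: an all-zero expression table gets offset
0; a gene set spanning the whole ranked universe has no misses and ES 1;
empty bins in the TSS profile report fraction 0 and undefined (NaN)
amplitude; peaks on chromosomes absent from the gene models are counted and
excluded rather than erroring.

Problem sizes in the test suite (120–2,000 genes, hundreds of peaks,
hundreds to thousands of permutations/replicates) were chosen so the whole
validation, including 100-fold simulation sweeps and a 2,000-trial
calibration, completes in well under a minute each while keeping binomial
noise far from the asserted margins.

## Known limitations

- No normalization beyond RPKM + offset (no TMM/quantile; composition bias
  is not corrected).
- The built-in NB test assumes equal library sizes and a single common
  dispersion; it is a stand-in for a dedicated DE tool on real data.
- Exact string gene ids; no cross-annotation or cross-species mapping.
- Gene-set permutation GSEA only; phenotype permutation is not offered.
- Supplementary tables of the motivating study are consumed only as
  user-converted TSVs; no spreadsheet parsing.
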