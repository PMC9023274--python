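# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `cpbind`, and what the synthetic benchmark does and does
not establish.

## Profiles and margins

Nucleobase-density profiles are built on the per-start-position triplet
track: entry *i* covers nucleotides *i* … *i*+2 and holds the fraction
(0, 1/3, 2/3, 1) of its bases in the chosen base set. Smoothing of genomic
tracks uses **stride 3**: the smoothed value at nucleotide *i* is the mean
of *w* in-frame, non-overlapping triplets centred on the triplet starting
at *i*. This reading makes the margin bookkeeping exact: the first and
last 3(*w* − 1)/2 entries of the triplet track are undefined, a smoothed
protein profile of length *l* = *N*aa − (*w* − 1) then leaves the first and
last (3*l* − 1)/2 + 3(*w* − 1)/2 genome positions without a Pearson value
(odd *l*), and the energy profile leaves (3*N*aa − 1)/2 + (*sw* − 1)/2
positions (odd *N*aa) for smoothing window *sw*. For the canonical case of
a 129-residue coat protein with *w* = 21 and *sw* = 63 these are 109
profile values and margins of 193 and 224 — verified exactly in the tests.
Fragment values sit on the central nucleotide; for even spans the two
half-integer centres are averaged onto the integer position between them,
so only integer positions ever carry values.

Density is stored as a fraction rather than a count; Pearson R is
invariant to that choice. Triplet content in the energy model is the
integer count 0–3; using fractions instead rescales raw energies by 1/3
and leaves z-scores unchanged (tested).

## Sliding Pearson

The vectorized implementation centres the smoothed density track once and
evaluates all fragment correlations per reading frame with running sums;
it agrees with naive per-fragment recomputation (`scipy.stats.pearsonr`)
to < 1e−12. Windows whose density (or whose protein profile) is constant
have no defined correlation; they are flagged NaN and excluded from site
calling, BSC denominators and shuffles. Constancy is detected with a
sum-of-squares floor of 1e−20: smoothed tracks are means of quantized
values (1/3-step densities, tabulated scale values), so genuinely
non-constant windows sit many orders of magnitude above the ulp-level
noise that window-mean subtraction leaves behind.

The four-scale combined profile is R_GUA + R_CYT + R_URA − R_ADE, each
term computed against the density of that scale's own base; it is defined
exactly where all four constituents are.

## Energy model

Raw fragment energies are computed as four cross-correlations between the
one-hot genome and a codon-expanded per-residue affinity kernel, which is
algebraically identical to the residue-by-residue double sum (oracle-
tested to 1e−9 on random instances). z-scores use the population standard
deviation (ddof = 0, switchable); an exactly constant smoothed profile has
undefined z (flagged NaN rather than raising).

Region prediction thresholds at the linearly interpolated percentile of
all defined smoothed values, includes ties (≤), and merges regions with
strictly fewer than `merge_gap` = 10 intervening nucleotides; a gap of
exactly 10 stays unmerged.

## Statistics

BSC restricts both numerator and denominator to positions carrying a
defined predicted value. Permutation p-values are the plain fraction of
shuffles with BSC ≥ native — no +1 pseudocount — so p = 0 is reportable at
finite shuffle counts and p-values are discretely conservative under ties.
Shuffles are uniform seeded permutations (numpy Generator); a BSC-vs-cutoff
curve reuses one shuffle set across cutoffs by default so the curve is
internally coherent (independent nulls per cutoff are available). The
normalized BSC (BSC divided by the number of called defined positions)
compares shuffles with unequal call volumes.

## Affinity scales

Woese's polar requirement is the only experimentally determined scale
covering all 20 amino acids and ships built in (name `PYR'`, lower =
stronger pyrimidine-mimetic affinity). Knowledge-based per-base scales are
not bundled; they load from two-column TSVs, with adenine scales defaulting
to the anti-matching (`max`) convention. Every Pearson quantity and every
z-score is invariant under affine rescaling of a scale (tested), so scale
units are immaterial.

For pipelines that need a full per-base scale set but have only a single
scale available, `synthetic.single_scale_energy_set` derives a clearly
synthetic set: the mean-centred scale on the target bases, zero elsewhere.
With it, fragment energy equals (up to a constant) the negative covariance
between residue affinities and local target-base content — sufficient to
exercise and benchmark the energy machinery, but not a substitute for
empirically derived per-base affinities.

## Synthetic benchmark: what it emulates

`generate_pair` plants `n_sites` = 4 regions of 150 nt (3 × 50-residue
protein) in a 4-kb i.i.d. uniform-composition genome. The protein is drawn
by a softmax sampler whose inverse-temperature swings through one sine
cycle along the chain (amplitude 2), producing one strong-affinity and one
weak-affinity patch — the single ~50-residue affinity peak that real coat
proteins exhibit; i.i.d. residues would leave almost no heterogeneity
after 21-window smoothing and make detection trivially impossible. Site
composition follows the rescaled negative affinity profile with Gaussian
noise ε = 0.1 (density scale) and nearest-k/3 rounding; one noisy target
composition is drawn per case and realized at every site with fresh base
identities, emulating a recurrent packaging-signal-like motif (the same CP
binds compositionally similar stem-loops throughout real genomes). Sites
are ≥ 150 nt apart and ≥ 250 nt from the ends.

What passing the benchmark shows: the full pipeline (profiles → matching /
energy → regions → BSC → permutation test) detects planted compositional
complementarity against composition-matched nulls, with calibrated
p-values when nothing is planted (the calibration check uses a shuffle of
a site-free genome as the "native" sequence, which makes native and null
exchangeable by construction). What it does not show: performance on real
genomes, which have codon-usage structure, secondary-structure constraints
and CPs whose affinity patches are not sinusoidal; and nothing here
validates any particular affinity scale.

A structural property of the lowest-1 % criterion is worth recording: on a
4-kb genome the 1 % budget is ~38 positions, while each 63-nt-smoothed
energy funnel has a bottom tens of positions wide whose absolute depth
rides on the local background-composition field. Near-tied funnels
therefore compete for the budget, and the lowest-1 % regions typically hit
3 of 4 planted sites (~0.75–0.85 of sites across seeds, independent of ε —
the same at ε = 0); the lowest-5 % regions hit all of them. This mirrors
the behaviour of lowest-percentile calling generally: it ranks the deepest
minima, it does not enumerate all true sites.

The planted-site permutation check uses cutoff R ≤ −0.8, chosen from the
construction (noise-free planted sites reach R ≈ −0.99, ε = 0.1 sites
≈ −0.9); at permissive cutoffs the smooth protein profile correlates with
background by chance and the test measures call volume rather than site
placement.

## Screening rules

CP candidates are selected by case-insensitive product-name matching:
inclusion terms *coat*, *capsid*, *core* (plus *VP0–VP4* for
*Picornaviridae*), minus an exclusion list (*precursor*, *polyprotein*,
*readthrough*, *read-through*, *leader*, *duplicate*, *homolog*,
*coat-like*, *extension*, *extended*, *RNA replicase*, *proteins*). The
plural *proteins* is matched as a whole token, otherwise every record
containing "protein" would be discarded. Sequences shorter than 50
residues or containing ambiguity codes are dropped. Protein and
mature-peptide records take priority; annotated regions are consulted only
for viruses where the first pass finds nothing.

## Coordinates and I/O

All internal coordinates are 1-based inclusive; BED (0-based half-open) is
converted only at the I/O boundary, and the conversion is a bijection
(property-tested). Only the plus strand is scanned: +ssRNA genomes are
analysed as given. FASTA parsing goes through Biopython; DNA input is
accepted for genomes (T → U), while ambiguity codes anywhere cause
rejection with the offending position named.

## Known limitations

- No secondary/tertiary structure: predictions are purely compositional.
- Energies are relative; cross-virus comparison of raw values is
  meaningless (z-scores are per genome/protein pair).
- The MS2 benchmark requires the user-supplied NC_001417 FASTA (see
  `data/ms2/README.md`); the 15 cryo-EM stem-loop reference intervals and
  the CP/replicase CDS coordinates are bundled.
- Very short proteins (smoothed length l < ~10) give noisy correlations;
  the screening default of ≥ 50 residues avoids that regime.
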