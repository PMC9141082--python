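# Methods

`karyofish` closes a loop around diploid plant karyotype analysis: encode a
species' karyotype and 5S rDNA FISH pattern as a fixture, synthesize
measurement tables and metaphase images from it with known ground truth,
recover measurements from the images, and check that the classical
descriptors come back out. This note records the models, parameters and
numerical choices, and what the synthetic data does and does not show.

## Karyotype fixtures

A fixture holds, per species: the diploid chromosome number 2n, the Levan
class composition (e.g. 20m + 2sm), the longest/shortest chromosome length
ratio L/S, the expected Stebbins cytotype, and a list of 5S signal
assignments (homolog pair, arm, fractional position from the centromere,
intensity, zygosity). Five Fabaceae fixtures are packaged: *Robinia
pseudoacacia*, *R. pseudoacacia* 'idaho', *R. pseudoacacia* f.
*decaisneana*, *Styphnolobium japonicum* and *Amorpha fruticosa*.

Verbal position vocabulary is encoded on the centromere→telomere arm
fraction as: centromere → 0.05, proximal → 0.30, proximal telomere → 0.80,
telomere → 0.95. The reverse mapping used by the analytics bins fractions
at ≤ 0.15 (centromeric), < 0.70 (interstitial), < 0.90
(proximal-telomeric), ≥ 0.90 (telomeric).

The 'idaho' taxon's heteromorphic pair (five strong signals and one weak
across three pairs) is encoded as two one-homolog assignments, one strong
and one weak, on the same pair. The arm positions of the 'idaho' sites are
an assumption (two telomeric pairs plus one centromeric, the centromeric
one heteromorphic); no observation fixes them.

## Table generation (the study conditions)

Haploid total lengths decay geometrically from the longest chromosome
(default 4.0 µm, matching a typical metaphase scale) to the shortest,
fixed by L/S; the two homologs of a pair are identical at zero noise, so
the L/S ratio of a generated table equals the fixture value exactly.

Each Levan class is realized by a representative arm ratio: m → 1.3,
sm → 2.2, st → 4.0, t → 8.0. For species whose cytotype row is 1 (no
chromosome with arm ratio above 2:1) the sm representative drops to 1.9 —
the minimal assignment consistent with a row-1 karyotype that still
contains sm chromosomes. Classes are laid out along the length-sorted
complement in symmetry order (m on the longest pairs, then sm, st, t); a
karyotype formula does not determine which length rank carries which
class, so this is a documented convention, not an inference.

Measurement noise multiplies each arm independently by 1 + ε with
ε ~ Normal(0, cv) truncated at ±3 SD (lengths stay positive). Feasibility
is checked before construction: class counts must be even and sum to 2n,
and the representative ratios must be compatible with the fixture's
cytotype row (row 1 forbids st/t; row 4 forbids classes at or below 2:1).

## Spread rendering

Chromosomes are bent capsules on a 16-bit canvas (default pixel size
0.05 µm, body width 0.45 µm): a circular-arc centerline with a random
total bend of up to ±35°, a Gaussian width constriction at the centromere
(depth 0.55 of the width, σ 0.12 µm), and telomeric tapers (0.15 µm) so
the rendered extent equals the nominal length. With the default
`overlap="forbid"` policy each chromosome is confined to its own jittered
grid cell, which makes footprints disjoint by construction; a canvas
explicitly too small raises a placement error.

FAM (telomeric probe) spots are Gaussian blobs (σ 0.08 µm, amplitude
20 000 counts) at both ends of every chromosome; TAMRA (5S) spots sit at
their assigned arm fractions, weak spots at 0.35 of the strong amplitude.
All channels get a constant background (800) plus Gaussian read noise
(SD 60). Everything rendered is recorded in a ground-truth structure
(per-chromosome lengths, centerline, centromere, spot positions).

Not modelled: chromatid substructure, satellites/secondary constrictions
(none were observed in these species), hybridization chemistry, optical
PSF beyond the Gaussian spots, touching or overlapping chromosomes under
the default policy, and intensity variation within a class. Passing tests
therefore demonstrate the pipeline's correctness on clean, well-spread
metaphases, not robustness to the pathologies of real micrographs.

## Image measurement

Segmentation thresholds the DAPI channel (Otsu by default, with a robust
guard: the threshold must clear the median background by six MADs,
otherwise the image is treated as empty), labels connected components,
drops objects under 50 px, and attempts a distance-transform-seeded
watershed split on components above 6 000 px; unsplittable clusters are
flagged, not force-split.

Per mask, the medial axis (computed on a one-pixel-padded crop so the
distance transform sees the true boundary) is pruned to its weighted
diameter path via a double Dijkstra sweep. Total length = smoothed path
arc length + the tip radius at each end (the skeleton stops about one
half-width short of each telomere). The centromere is located on the
width profile smoothed with a Gaussian of σ = one third of a 10%-of-length
window: candidate positions are interior local minima (`find_peaks` on the
negated profile with 5% prominence) outside a 10% end margin — end-taper
ramps are monotone there and cannot qualify — refined to sub-pixel
precision by a depth-weighted centroid over a window symmetric about the
minimum. Masks without a qualifying dip fall back to the midpoint and are
flagged `metacentric-by-default`.

Spot detection subtracts the median background, smooths (σ 1 px), and
thresholds at 6 robust SDs; spots are assigned to the containing mask or
the nearest mask within 8 px, and anything further is reported as
unassigned rather than dropped. A spot is "weak" when its summed intensity
is below 0.5 × the channel's median spot intensity; the 0.5 is a free
parameter — no measured threshold separates the weak 'idaho' signal from
the strong ones, only the qualitative report.

Accuracy at the default resolution, assessed against ground truth: total
lengths are recovered to a few percent and rank pair means perfectly;
submetacentric arm ratios (2.2) on mid-length (3 µm) chromosomes are
recovered with a batch-mean relative error of about 3–6% (the packaged
validation batch renders 50 such chromosomes over five seeds and requires
a batch mean below 10%). The known failure mode is a centromere lying
within about two body widths of a telomere: for the shortest st
chromosomes (short arm ≈ 6 px) the constriction blends into the telomeric
taper and the measured ratio is biased toward metacentric. This is a
resolution floor of the width-profile approach, not a tuning issue.

## Karyotype descriptors

Levan bands on the arm ratio r = long/short: m ≤ 1.70 < sm ≤ 3.00 <
st ≤ 7.00 < t, boundaries inclusive toward the more symmetric class.
Relative length is the percentage of the whole diploid complement (all 2n
bars are plotted, so the diploid total is the natural denominator).
The karyotype formula lists classes in fixed order m, sm, st, t, omitting
zeros. The longest/shortest ratio uses total chromosome lengths.

Stebbins cytotype: column A/B/C for L/S < 2, in [2, 4], > 4; row 1–4 for
the proportion p of chromosomes with arm ratio > 2 equal to 0, in
(0, 0.5], in (0.5, 1), equal to 1. Boundary cases keep the more symmetric
cell: L/S exactly 2 → B, p exactly 0.5 → row 2 (this keeps the 14/28
borderline *S. japonicum* complement at row 2).

Homolog pairing sorts by length and pairs adjacently; when FISH sites are
available, runs of near-equal lengths (within 2%) are re-paired to
maximize signal-pattern agreement, resolving neighbour ambiguity.

## Signal profiles and clustering

A species' 5S profile is (number of bearing homolog pairs; site counts per
position category, both homologs counted; number of
intensity-heteromorphic pairs). Dissimilarity is a weighted L1 distance
on those counts with default weights 1.0 / 0.5 / 0.25 — pair-count
differences dominate, mirroring an interpretation that ranks species
primarily by how many 5S pairs they carry. As a weighted L1 on count
vectors it is a pseudometric (distinct species can in principle share a
profile). Profiles are clustered by UPGMA (single linkage available) and
exported as an ultrametric Newick tree.

With the packaged profiles and default weights the merge order is: the two
four-pair *Robinia* taxa first (d = 2.0), then 'idaho' (3.25), then
*S. japonicum* with *A. fruticosa* (4.0), then the root (5.42). The three
*Robinia* taxa are monophyletic in the merge order. Note that the two
sparse-signal species pair with each other rather than *A. fruticosa*
joining strictly last: with only one and two 5S pairs respectively and a
dissimilarity dominated by pair counts, |Δn| = 1 between them versus ≥ 2
to any *Robinia* taxon, and no non-negative weighting with the pair-count
term dominant can reverse that. The output is a signal-pattern
similarity dendrogram, not a phylogeny estimate.

## Reproducibility

Every stochastic step takes an explicit integer seed; there is no global
random state. Identical seeds and parameters give bit-identical tables,
images, and report files (SVG output is salted deterministically and
written without timestamps). Problem sizes throughout (five species,
complements of 22–40 chromosomes, ten replicate seeds for robustness
sweeps, 50-chromosome validation batches) keep any single analysis under
a few seconds and the full suite under a minute on one CPU.
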