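# karyofish

Karyotype analytics and oligo-FISH signal mapping for diploid plant
metaphase spreads, with a ground-truthed synthetic spread generator.

Karyotypes — chromosome number, arm-length morphology, and the positions
of FISH-mapped loci such as 5S rDNA — are primary cytogenetic data for
species identification and comparison, but the measurements behind them
(arm lengths read off metaphase photographs, signal positions judged by
eye) are usually manual and hard to audit. `karyofish` is for plant
cytogeneticists and method developers who want that pipeline as tested
code: it encodes a species' karyotype as a fixture, simulates metaphase
FISH images with known ground truth, measures chromosomes back out of
images, computes the classical descriptors, and clusters species by their
5S signal patterns. Five Fabaceae karyotypes (three *Robinia* taxa,
*Styphnolobium japonicum*, *Amorpha fruticosa*) ship as packaged fixtures.

## The model in brief

For a chromosome with long arm `l` and short arm `s`:

- arm ratio `r = l / s ≥ 1`, binned into Levan centromere classes
  `m ≤ 1.70 < sm ≤ 3.00 < st ≤ 7.00 < t`;
- the karyotype formula counts chromosomes per class, e.g.
  `2n = 2x = 20m + 2sm`;
- relative length = 100 · (l + s) / Σ(l + s) over the diploid complement;
- the Stebbins cytotype combines a row (proportion of chromosomes with
  `r > 2`: 0 → 1, (0, 0.5] → 2, (0.5, 1) → 3, 1 → 4) with a column from
  the longest/shortest chromosome ratio (< 2 → A, [2, 4] → B, > 4 → C).

FISH signals are described per homolog pair by channel (FAM telomeric
probe, TAMRA 5S probe), arm, fractional position from the centromere, and
intensity class; species-level 5S profiles are compared by a weighted L1
dissimilarity and clustered by UPGMA into a similarity dendrogram.

Synthetic spreads render each chromosome as a bent capsule on a DAPI
channel with a centromeric constriction, telomeric FAM spots on every
chromosome end, and TAMRA spots at their assigned positions; measurement
recovers arm lengths from the medial axis and its width profile. See
`docs/methods.md` for parameters, numerical choices and limitations.

## Worked example

```python
import karyofish as kf

fixture = kf.load_species_fixture("styphnolobium_japonicum")
table = kf.generate_measurement_table(fixture)       # noise-free complement
result = kf.analyze_karyotype(table)
print(result.formula_string, result.cytotype, round(result.ls_ratio, 4))

run = kf.simulate_species("styphnolobium_japonicum", seed=3)  # rendered spread
masks = kf.segment_chromosomes(run.image)
detected = kf.detect_signals(run.image, masks)
print(len(masks), "chromosomes,",
      len(detected.bearing_chromosomes("TAMRA")), "bearing 5S signals")
```

prints

```
2n = 2x = 14m + 12sm + 2st 2B 2.6847
28 chromosomes, 2 bearing 5S signals
```

i.e. the generated *S. japonicum* complement comes back from the analytics
as 14 metacentric + 12 submetacentric + 2 subtelocentric chromosomes,
cytotype 2B with a longest/shortest ratio of 2.6847, and the rendered
spread is segmented into all 28 chromosomes of which the one 5S-bearing
homolog pair is detected on the TAMRA channel.

The `analysis/` directory holds the same pipeline as numbered narrative
scripts (`01_simulate_karyotypes.py` … `05_signal_clustering.py`) writing
their tables under `results/` and rendered images under `scratch/`; the
`karyofish` command line exposes the stages as subcommands
(`simulate`, `measure`, `analyze`, `cluster`, `report`, `all`).

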