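# sporescope

Quantitative characterization of grass–endophyte symbioses from the lab
bench: automated conidial morphometry from micrographs, flow-cytometry
genome-size and ploidy estimation, distance-based permutation statistics
for nested morphometric designs, and variant screening of multilocus
alignments.

The toolkit targets mycologists and plant–microbe researchers working
with *Epichloë*-type fungal endophytes of cool-season grasses, where the
routine questions are: how big are the asexual spores (conidia) and their
stalks (conidiophores), does their morphology differ by host population or
host ploidy, what is the fungal genome size relative to an internal
standard, and which alignment positions separate the isolates.

## What it computes

**Morphometry.** Conidia are segmented from grayscale micrographs by an
automatic global (Otsu) threshold, hole filling, and 8-connected
labelling; border-touching and out-of-gate objects are discarded. Only
spores lying flat ("sagittal plane") are measured, enforced by a shape
gate on solidity, aspect ratio, and the residual against the fitted
ellipse. With calibration *s* px/µm (default 15.8097):

    length = major axis / s      width = minor axis / s
    area   = pixel count / s²

so `area·s²` equals the pixel count exactly. Conidiophores are measured
along the morphological skeleton: total length is the longest geodesic
path (extended to the region tips) and base width is the local width at
the wider skeleton endpoint.

**Cytometry.** G1 fluorescence peaks are Gaussian fits to a smoothed
channel histogram. Genome size follows the standard-ratio method,
`pg = pg_standard · (mean_sample / mean_standard)`, with QC gates of
≥ 5,000 nuclei and CV < 3 % (plants) or < 10 % (fungi), pg ↔ Mbp via
978 Mbp/pg, and ploidy assigned by nearest monoploid (1Cx) multiple.

**Statistics.** Euclidean-distance PERMANOVA with sequential (Type-I)
sums of squares and seeded permutation p-values `(1 + b)/(1 + B)`;
pairwise centroid-distance permutation tests with Holm–Bonferroni
adjustment; PCA by SVD; Fisher LDA with leave-one-out cross-validation
(accuracy and Cohen's κ); one-way ANOVA with Tukey HSD compact letters;
and radial colony growth rate `GR = (D_final − D_initial)/Δt`.

**Sequence variability.** Variable and parsimony-informative site counts
and SNP calls at a minimum variant-frequency threshold (default 25 %,
inclusive) on FASTA alignments, ignoring gaps and ambiguity codes.

Seeded synthetic generators (spore fields, fluorescence histograms,
nested trait tables) provide ground-truthed fixtures for all of the
above.

## Worked example

```python
from sporescope import simulate, morphometry as M, stats as S

# render a spore field with known truth, then re-measure it
spec = simulate.SporeFieldSpec(n_sagittal=12, n_oblique=3, seed=11)
micrograph, truth = simulate.synth_micrograph(spec)
measures = M.measure_micrograph(micrograph)
print(M.summarize_traits([m.length_um for m in measures], "conidium length (µm)"))
print(M.summarize_traits([m.area_um2 for m in measures], "conidium area (µm²)"))

# nested-design PERMANOVA on a synthetic trait table
table, _ = simulate.synth_morphtable(simulate.MorphSimSpec(seed=7))
traits = ["conidium_length_um", "conidium_width_um",
          "conidium_area_um2", "conidiophore_length_um"]
dist = S.euclidean_distances(table, traits)
print(S.permanova(dist, table, ["site", "host_ploidy", "individual"],
                  n_perm=999, seed=1))
```

prints

```
conidium length (µm): 4.5 ± 0.4 [3.7–5.0] (n=12)
conidium area (µm²): 7.1 ± 0.9 [5.9–8.8] (n=12)
PERMANOVA (999 permutations, seed 1)
              df       SS     R2  pseudo_F  p_perm
site           2  21.9277 0.0345    3.4680  0.0010
host_ploidy    1  20.5286 0.0323    6.4934  0.0010
individual    12 138.2971 0.2174    3.6454  0.0010
Residual     144 455.2466 0.7158       NaN     NaN
Total        159 636.0000 1.0000       NaN     NaN
```

All 15 rendered objects were segmented; the 3 oblique (overlapping) ones
were rejected by the sagittal gate, and the 12 measured spores summarize
to the generator's 4.4 × 2.0 µm regime. In the PERMANOVA, individual
identity absorbs the largest share of variance (R² = 0.217 over 12
degrees of freedom), as expected when individual-level variance
components dominate group effects; p-values sit at the permutation floor
1/(1+999).

The same workflows are available from the shell:

```sh
sporescope simulate micrograph --seed 1 --out sim/
sporescope measure --images sim/micrograph.png --out measures.csv
sporescope stats permanova --table morphtable.csv --terms individual \
    --nperm 10000 --seed 1
sporescope seqvar --aln actG.fasta --min-freq 0.25 --out snps.tsv
```

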