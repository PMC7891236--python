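# gliotopo

Gliomas are not scattered uniformly across the brain: they cluster in the
insula and association cortex and spare the occipital lobe.  `gliotopo` is
an analysis pipeline for asking *why* — it tests whether regional glioma
frequency tracks (i) functional connectome hubness, (ii) the territories
of putative cells of origin (neural stem cells and oligodendrocyte
precursor cells), and (iii) regional transcription of glioma driver genes,
and then asks how much of the spatial distribution those factors jointly
explain.

It is written for researchers in imaging neuro-oncology and imaging
transcriptomics.  Because the original data sources (a multi-site lesion
cohort, a population functional connectome, a post-mortem expression
atlas) are large external downloads, the package ships a first-class
synthetic-data generator that reproduces the *statistical structure* the
analysis relies on — spatially autocorrelated maps, a modular weighted
connectome, co-expressed marker gene panels — with planted, known effect
sizes, so every stage is testable end to end on a laptop.

## The analysis

1. **Lesion frequency mapping** (`lesionmap`): binary tumour masks are
   counted voxel-wise into a frequency map `f(v) = 100 · #{masks overlapping
   v}/N`, smoothed (2 mm FWHM Gaussian), mirrored to the left hemisphere
   (homotopic averaging), and aggregated to a 334-region symmetric
   parcellation (167 per hemisphere) with a 4 mm white-matter extension.
   Internal replicability is measured by correlating maps from disjoint
   half-cohorts with deliberately skewed low-/high-grade composition.
2. **Spatial inference** (`spatialnull`): parcel maps are spatially
   autocorrelated, so map–map correspondence is tested with the spin test —
   random 3-D rotations of the parcels' spherical embedding generate
   contiguity-preserving null maps, and
   `P_spin = (1 + #{ρ_null ≥ ρ_obs}) / (1 + n_spins)`.
   Moran's I (inverse-distance weights) quantifies the autocorrelation that
   motivates this null.
3. **Hub profiling** (`hubgraph`): a weighted functional connectome
   (parcel-mean loading correlations, negatives zeroed) yields nodal
   strength, betweenness centrality, participation coefficient,
   within-module degree z-score, clustering, nodal efficiency and
   eigenvector centrality; metrics with |Spearman ρ| > 0.95 against
   strength are screened out, homotopic pairs averaged, and each surviving
   metric spin-tested against frequency.
4. **Cells of origin** (`cellorigin`): frequency in the hippocampus +
   caudate (NSC-niche stand-ins) versus 10 000 random parcel pairs; an OPC
   marker panel is validated by co-expression against random same-size gene
   sets, discordant members filtered (mean inter-member r ≤ 0), and its
   median regional enrichment correlated with frequency.
5. **Transcriptomics** (`plstx`): expression samples are aligned to the
   map (response = √frequency at each sample), and partial least squares
   extracts gene-weight components maximizing covariance with the response.
   Significance by response permutation; per-gene Z by bootstrap with sign
   alignment; proto-oncogene enrichment by median rank against random sets;
   per-sample loadings mapped to parcels by nearest neighbour.
6. **Integrative model** (`multifactor`): OLS of z-scored √frequency on
   z-scored strength, OPC score, PLS1 and PLS2 loadings over 167 parcels
   (an interaction model gates a main-effects model), with squared partial
   correlations and spin-based, Bonferroni-corrected predictor p-values.

`fixtures` generates all inputs; `workbench.run_pipeline` runs everything
from one seeded config and writes a manifest sufficient to reproduce every
output bit-identically.

## Worked example

Each numbered script under `analysis/` is a thin driver over the library;
all of them accept `--seed` and write tables under `results/`.

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_lesion_frequency_map.py --seed 1
python analysis/03_hub_profile.py --seed 1
```

With seed 1 this prints:

```
cohort: 335 patients, 86 LGG (25.7%)
expression atlas: 600 samples x 2000 genes; marker set 25, driver set 17 (of which 3 planted decoys)
planted effect sizes: {'hub': 0.5, 'opc': 0.5, 'driver': 0.5}
...
parcel frequencies: mean 4.71%, max 8.84%
split-half replicability: r = 0.71 (95% CI 0.44-0.79) with LGG fractions 0.39/0.13
...
screened out (|rho| vs strength > 0.95): ['clustering', 'eigenvector', 'local_efficiency']
          strength: rho = +0.175, P_spin = 0.1460
```

Reading this: the synthetic cohort's frequency map is internally reliable
(half-cohort maps correlate at r = 0.71 even with a three-fold difference
in low-grade fraction between halves), three hub metrics are near-copies of
nodal strength and are dropped, and on this seed the realized
hub–frequency correlation (+0.18) does not clear the spin null — the
planted map-level effect of 0.5 is attenuated twice, once by lesion
sampling noise and once by connectome estimation noise, so single-seed
significance varies (see `docs/methods.md`).  The transcriptomic and
integrative stages (`05`, `06`) print the PLS variance decomposition,
driver-gene enrichment, and the final regression table with partial
variance and spin p-values per predictor.

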