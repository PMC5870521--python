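# phylomorph

3D geometric morphometrics with object symmetry, plus the phylogenetic
comparative analyses used to ask whether skull shapes evolve convergently
when lineages invade the same habitat.

The package is organised as an analysis project: every computation lives in
the importable library under `src/phylomorph/`, and the numbered scripts
under `analysis/` run the full study on synthetic landmark data with known
ground truth (no raw specimen coordinates are distributed, so the
synthetic generator — itself a first-class, tested module — stands in for
the digitized skulls).

## Who this is for

Evolutionary morphologists working with 3D landmark data on bilaterally
symmetric structures (skulls, crania, carapaces) who need, in one coherent
pipeline:

* **Superimposition.** Generalized Procrustes analysis (GPA) removing
  position, orientation and size, with *object symmetry*: each
  configuration is aligned jointly with its reflected, relabeled copy, and
  only the symmetric component `(x + x̄)/2` is carried into the statistics.
  Missing landmarks are estimated beforehand with a 3D thin-plate spline
  (kernel `U(r) = r` + affine part) warped from a consensus.
* **Morphospace and disparity.** PCA of the aligned coordinates;
  Procrustes ANOVA with residual-randomization permutations (RRPP);
  overall disparity `MD = Σᵢ d²(xᵢ, x̄)/(N−1)` partitioned into Foote's
  per-group partial disparities, which sum exactly to MD.
* **Phylogenetic comparative methods.** The multivariate
  phylogenetic-signal statistic
  `K = [r′r / r′C⁻¹r] / [(tr C − n/(1′C⁻¹1))/(n−1)]` with `r = Y − 1a`
  (expected value 1 under Brownian motion); phylogenetic ANOVA by the GLS
  transform `C^{−1/2}` followed by the same RRPP machinery;
  maximum-likelihood ancestral shapes; phylomorphospace coordinates; UPGMA
  phenograms and a tanglegram discordance screen.
* **Convergence.** The distance-based C-metrics in the full shape space:
  `C1 = 1 − Dtip/Dmax`, `C2 = Dmax − Dtip`, `C3 = C2/L_lineage`,
  `C4 = C2/L_clade`, with p-values from Brownian-motion simulation on the
  study tree using the rate matrix estimated from the tip data.

## Worked example

Run the analysis scripts in order (each prints what it found and writes
tables under `results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_superimpose_and_morphospace.py
python analysis/03_disparity.py
python analysis/04_phylogenetic_signal_and_pgls.py
python analysis/05_convergence.py
```

Output of the run at the default seed:

```
bundle: 267 configurations, 28 species -> results/study
  habitats: {'brackish': 17, 'fresh': 3, 'marine': 8}
  missing landmark cells: 22
  forced convergent pair: sp05 + sp20 (weight 0.8)
estimated missing landmarks for 21 configurations
measurement error: among-individual F = 11.78 (p = 0.001); residual variance is replicate (digitizing) error
morphospace: PC1 35.4%, PC2 12.5% (PC1+PC2 = 47.9% of shape variance)
habitat Procrustes ANOVA: F = 16.312, Z = 7.207, p = 0.000999
largest habitat mean-shape distance: brackish-fresh = 0.0636
habitat: overall MD = 0.007330
    brackish: PD = 0.004319 (58.93%), own-mean variance = 0.006650
      marine: PD = 0.002113 (28.83%), own-mean variance = 0.006173
       fresh: PD = 0.000898 (12.25%), own-mean variance = 0.006105
phylogenetic signal: K = 0.9811, p = 0.000999
phylogenetic ANOVA (habitat): F = 1.420, Z = 1.576, p = 0.054
tanglegram screen: 1 discordant phenogram sister pair(s); most distant on the phylogeny: sp05 + sp20 (patristic distance 2.000)
sp05 + sp20: C1 = 0.654 (p = 0.001), C2 = 0.0569 (p = 0.001), C3 = 0.226 (p = 0.001), C4 = 0.0383 (p = 0.001), ProcD = 0.0301
```

Reading these numbers: habitats differ strongly in the ordinary shape
ANOVA, but the habitats were inherited along the tree, and once the
phylogenetic covariance is accounted for the effect collapses to
non-significance — phylogenetic structure, not adaptation, drives most of
the apparent habitat signal (the shape data themselves show
Brownian-motion-level phylogenetic signal, K ≈ 1).  The tanglegram screen
singles out exactly the species pair whose convergence was planted by the
generator, and the C-metrics confirm it: the pair has closed 65% of the
maximum shape distance its lineages ever had (C1 = 0.654), far more than
Brownian motion produces (p = 0.001).

The same pipeline runs from the command line on any data bundle
(`phylomorph simulate | validate | gpa | pca | anova | disparity | signal |
pgls | phenogram | converge | run`); see `phylomorph --help`.

## Layout

```
src/phylomorph/
  geometry.py     landmark data model, GPA, object symmetry, TPS
  stats.py        PCA, Procrustes ANOVA (RRPP), disparity
  phylo.py        trees, covariance, K, PGLS, ancestral states, UPGMA
  convergence.py  C1-C4 and Brownian-motion p-values
  simulate.py     seeded synthetic-data generators (trees, shapes, noise)
  io.py           landmark CSV, metadata CSV, symmetry JSON
  pipeline.py     end-to-end orchestration with per-stage seeding
  cli.py          command-line interface
analysis/         numbered study drivers (simulate -> ... -> convergence)
docs/methods.md   models, parameters, numerical choices, limitations
```
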