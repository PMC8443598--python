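# idioconn

Idiosyncrasy profiling of functional connectomes.

Resting-state fMRI studies that compare a clinical group against controls
usually assume that a given anatomical location belongs to the same
functional network in every person. In practice the layout of the
intrinsic connectivity networks (ICNs) — default mode, somatomotor,
attention systems, and so on — varies from person to person, and in
conditions such as autism this *idiosyncrasy* is pronounced enough to
masquerade as group-level connectivity differences. `idioconn` quantifies
each individual's deviation from a canonical group reference and tests
whether apparent connectivity alterations survive once that deviation is
controlled for.

The pipeline, given parcel-level time series for a two-group multi-site
cohort:

1. **Connectivity.** Pearson correlations per subject, Fisher
   z-transformed, each row thresholded to keep its 10% most similar
   entries. A group-mean matrix defines the canonical connectome.
2. **Embedding.** Diffusion-map embedding of the row-similarity affinity
   (α = 0.5, diffusion time t = 1, first K = 30 eigenvectors). Individual
   embeddings are mapped into the reference space by a closed-form
   change-of-basis operator *O* = argmin‖Φᵢ·O − Ψ‖_F.
3. **Networks.** A full-covariance Gaussian mixture with N = 7 components,
   initialized from a template atlas, assigns each parcel to the ICN of
   highest posterior probability — for the reference and for every
   aligned individual.
4. **Idiosyncrasy descriptors.** Per parcel: surface distance
   SD(p) = geodesic distance to the nearest reference parcel of the same
   network, and diffusion distance DD(p) = ‖φ_p − ψ_q‖² to the nearest
   same-network reference point in embedding space. Per network: Dice and
   Jaccard overlap, symmetric mean surface distance
   MSD(A,B) = (Σ_{a∈A} d(a,B) + Σ_{b∈B} d(b,A)) / (|A|+|B|), network
   size, and the entropy of group-average network probability maps.
5. **Statistics.** GLM group contrasts with site/sex/age covariates;
   TFCE + max-statistic permutation correction for parcel-wise maps
   (labels permuted within site); Benjamini–Hochberg FDR for network
   families; spherical spin tests for spatial map correlations; severity
   and age associations; a bootstrap over reference embeddings.
6. **Centrality.** Degree centrality (connections with r > 0.2) and
   eigenvector centrality, contrasted between groups before and after
   adding each subject's local SD and DD as covariates.

Real cohort data are not required: `idioconn.synthetic` generates complete
study datasets — spherical cortex, contiguous parcels, a 7-network
template, two groups across five sites, and per-subject network layouts
displaced by a controllable geodesic boundary shift — so every stage is
testable against ground truth.

## Worked example

```python
import idioconn

cfg = idioconn.RunConfig()                      # published defaults
ds = idioconn.simulate_dataset(cfg.scenario, seed=2)
model = idioconn.IdiosyncrasyModel.from_dataset(ds, cfg)
res = model.fit(seed=2, n_perm=300)
print(res.summary())
```

prints (abridged):

```
Idiosyncrasy analysis summary
================================================================
subjects: 78 (40 typical / 38 atypical), parcels: 200, networks: 7
...
Network-level group contrasts (atypical - typical):
descriptor network       t       p  cohens_d   p_fdr
       msd    net1  7.9802  0.0000    1.8050  0.0000
       msd    net2  5.4807  0.0000    1.1719  0.0000
       msd    net3  3.5850  0.0006    0.8224  0.0007
       msd    net4  4.5554  0.0000    1.0227  0.0000
       msd    net5 -8.7302  0.0000   -2.0027  0.0000
...
parcel-wise SD: 75 significant parcels (TFCE, FWE 0.05)
parcel-wise DD: 96 significant parcels

degree-centrality contrast: 39 significant parcels before / 25 after
controlling for SD+DD
```

(Two atypical subjects were excluded by the FD > 0.3 mm motion filter.)

Networks 1–4 (shifted 55 length units in the atypical group versus 30 in
the typical group) show strongly positive MSD contrasts; network 5
(shifted 70 units in the typical group, 10 in the atypical) shows the
reverse sign; and most parcels with significant degree-centrality
differences lose significance once the local idiosyncrasy descriptors
enter the model — the package's central demonstration that connectivity
alterations can reflect network idiosyncrasy.

A thin CLI wraps the same pipeline:

```bash
idioconn simulate --config scenario.yaml --seed 1 --out-dir sim/
idioconn run --seed 1 --out-dir run/ --n-perm 300
```

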