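# Methods

This note documents the models and procedures implemented in `idioconn`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Pipeline

### Connectivity

Per subject, functional connectivity is the Pearson correlation matrix of
parcel time series. Correlations are clipped to |r| ≤ 1 − 1e−7 before the
Fisher z-transform so z stays finite while preserving order. Each row then
retains its k = round(0.10·(P−1)) largest z values (the diagonal is
excluded — self-connectivity carries no information — so 10% refers to
off-diagonal entries). Ranking is by signed z: the "most similar" entries
are the most positive ones; ties break toward the lower column index so
runs are reproducible. The matrix may be asymmetric after row-wise
retention; the affinity step re-symmetrizes.

The group-mean connectome averages the *dense* z matrices and applies
retention once to the mean. Averaging already-sparsified matrices would
mix retained and zeroed entries with subject-dependent support and dilute
the meaning of the retained set.

Quality control excludes subjects whose mean framewise displacement
exceeds 0.3 mm (strict inequality; a subject at exactly the cutoff is
kept).

### Diffusion-map embedding

The affinity between two parcels is the normalized angle
1 − arccos(cos(row_i, row_j))/π of their sparsified connectivity rows —
the kernel convention of the gradient-mapping toolboxes this pipeline
follows; plain cosine is available via configuration. With affinity W and
degree D, the density-normalized kernel is W′ = D^−α W D^−α (α = 0.5,
balancing geometry against sampling density) and M = D′^−1 W′ is the
random-walk operator. Writing u_k for the orthonormal eigenvectors of the
symmetric conjugate of M, coordinates are x_k(i) = λ_k^t · u_k(i)/u_0(i)
for the K = 30 largest non-trivial eigenvalues at diffusion time t = 1.
Under this scaling, Euclidean distance in the full (K = P−1) embedding
equals the diffusion distance Σ_u (M^t_iu − M^t_ju)²/π_u exactly; the
acceptance suite verifies the identity against a dense matrix-power
oracle. The eigensolver is a dense symmetric decomposition — deterministic,
and entirely adequate at P ≤ ~1000 — with a fixed per-column sign
convention (first non-negligible entry positive) so repeated runs are
bit-comparable. A disconnected affinity graph raises rather than silently
embedding components separately.

### Alignment

Individual embeddings live in subject-specific eigenspaces; they are
mapped into the reference space by the change-of-basis operator
O = argmin‖Φᵢ O − Ψ‖_F, solved in closed form by least squares over all
parcel rows. Unconstrained least squares (not orthogonal Procrustes) is
the default: the goal is to express individual coordinates *in the
reference basis*, which requires general linear mixing, not a rotation.
Procrustes is available as an option for sensitivity analyses.
Rank-deficient embeddings fall back to the pseudoinverse solution with a
warning. Aligning an already-aligned embedding is a no-op to numerical
precision.

### Network identification

A Gaussian mixture with N = 7 components and full covariances clusters
the reference embedding. EM is initialized from the per-network empirical
moments of a template atlas labeling, which pins component k to network k
without any relabeling step. Each subject's aligned embedding is then
re-clustered by EM warm-started from the reference mixture (the closest
reading of "every embedding is clustered"); assignment under the frozen
reference mixture is available as an option, and is also the automatic
fallback if a subject's EM fails. Because per-subject EM can drift,
components are re-identified with reference networks by nearest-mean
matching (Hungarian assignment) and any remapping is reported.
Convergence: relative log-likelihood change below 1e−6 or 500 iterations;
degenerate covariances are regularized by 1e−6 on the diagonal. EM is
deterministic given the deterministic initialization; there are no random
restarts.

### Idiosyncrasy descriptors

All descriptors are computed at parcel resolution. Geodesics are shortest
paths (Dijkstra) on the parcel graph whose edge weights are mesh geodesic
lengths between the central vertices of adjacent parcels — the natural
parcel-level counterpart of vertex-wise surface distances.

- **SD(p)**: geodesic distance from parcel p to the closest reference
  parcel of the subject's network at p; zero where subject and reference
  labels agree. Agreeing parcels enter group means as zeros (maskable).
- **DD(p)**: *squared* Euclidean distance in the aligned embedding to the
  nearest same-network reference point. The squared form is used
  throughout (it is the form the defining equation prints, and the one
  whose full-rank version matches the diffusion-distance identity).
- **Dice / Jaccard / MSD** per network between the reference parcel set A
  and the subject set B. MSD is the *symmetric* mean surface distance,
  (Σ_{a∈A} d(a,B) + Σ_{b∈B} d(b,A))/(|A|+|B|): the typeset source formula
  omits the operator joining the two sums; the sum is the standard
  symmetric form and is the only reading with MSD = 0 iff A = B. A
  network empty in a subject has Dice = Jaccard = 0 and undefined MSD;
  such subject-network pairs are dropped pairwise in group models.
- **Entropy**: posteriors are averaged across a group first and the
  entropy −Σ p̄ ln p̄ (natural log; maximum ln 7 ≈ 1.9459) is taken per
  parcel — the entropy of the average probability map, not the average of
  subject entropies (two certain but disagreeing subjects must register
  as uncertainty).
- **Cortex-wide summaries** weight per-network scores by reference
  network sizes.
- **Gradient stratification** bins parcels into quantiles of the first
  reference component and reports per-bin means with a Spearman rank
  trend; a constant map is reported as rho = 0 with a defined-trend flag
  set to false.

### Group statistics

Network-level group contrasts use OLS GLMs with intercept, group
(0 = typical, 1 = atypical), one-hot site, sex and age; the group t with
n − rank(X) degrees of freedom, BH-FDR corrected across the seven
networks per descriptor family. Entropy uses two-sample t-tests per
network (parcel-wise within reference territories), reported with
Cohen's d (pooled n−1 SD).

Parcel-wise SD/DD and centrality maps are corrected family-wise by TFCE
(E = 0.5, H = 2, dh = max|t|/100 — the standard surface parameterization;
the source analysis does not print its values) with max-statistic
permutation: group labels are permuted *within site*, since site is the
dominant nuisance in multi-site cohorts and restricted exchangeability is
the conservative choice (free permutation is available). The negative
tail is enhanced symmetrically on −t; p_corr(p) = (1 + #{null max ≥
TFCE(p)})/(n_perm + 1). The TFCE inner loop is an incremental union-find
percolation over descending thresholds (a numba kernel; an equivalent
per-threshold connected-components implementation serves as fallback and
as the oracle in tests). The published analysis used 10,000 permutations;
desk-scale runs here default to hundreds, which the permutation p-value
floor 1/(n_perm+1) makes explicit.

Spin tests rotate parcel centroids by uniform random 3-D rotations and
reassign each parcel the value of the nearest rotated centroid
(duplicates permitted, as is standard for parcel-level spin nulls);
p is two-sided on |r| with the same +1 correction.

Severity associations z-score each descriptor with respect to the typical
group, regress site/sex/age out of the z-scores among atypical subjects,
and correlate the residuals with the severity score, BH-FDR corrected
across networks. Age models add age and group×age terms to the GLM; a
numerically perfect fit is flagged and reported as an infinite t rather
than a spurious finite value.

The reference bootstrap rebuilds the reference (mean FC → embedding →
clustering) from random 50% subsamples and recomputes cortex-wide
Dice/Jaccard/MSD for *all* subjects per replicate, giving the
distribution of descriptors across admissible references.

### Centrality

Degree centrality counts, per parcel, connections whose *raw* correlation
(no Fisher z, no sparsification) strictly exceeds 0.2; negative
correlations never count. Eigenvector centrality is the unit-norm Perron
vector of the non-negative connectivity matrix (negative weights floored
at zero with a warning; disconnected matrices raise because the leading
eigenspace is ambiguous). Group contrasts run twice: with the standard
design, and with each subject's SD and DD *at the parcel under test*
added as local covariates — local, because the claim under test is that a
location's apparent connectivity alteration is explained by the shifting
at that location. Centrality values enter the GLM untransformed.

## Synthetic cohorts

The generator produces the study conditions the statistics are validated
under. Geometry: an icosphere (subdivision 4, radius 100 length units ≈ a
hemisphere-scale sphere) carved into 200 contiguous parcels by
farthest-point sampling + graph Voronoi; a 7-network template laid over
the parcels by the same construction with per-network growth weights
(1.4, 1.2, 1.1, 1.0, 0.95, 0.9, 0.85), giving realistic, heterogeneous
territory sizes (about 47 down to 12 parcels). Unequal sizes matter: they
are what makes a boundary shift change a parcel's degree centrality.

Subjects displace the template by geodesic front propagation: per network,
a random tangential direction; parcels of other networks on the leading
side within the magnitude m of the territory are annexed, own parcels on
the trailing side within m of the boundary are released to their nearest
neighbor network. The realized displacement (mean geodesic distance of
relabeled parcels) is the subject's ground-truth idiosyncrasy. Magnitudes
beyond a territory's geodesic diameter are invalid (the network would be
displaced past its own footprint); the cohort generator caps draws below
that bound, and annexation never consumes a donor's last parcel.

Time series follow a latent-signal block model: parcel p follows its
network's unit-variance latent plus independent noise, x_p = g_k + σε,
with σ chosen so the expected within-network correlation is
r = 1/(1+σ²) = 0.5; latents share 20% of variance with a global signal
(cross-network r ≈ 0.1, comfortably below the 0.2 centrality threshold);
300 timepoints at TR = 2 s. Sites scale amplitude only (±10%), so site is
a genuine nuisance that cannot confound correlation-based measures.

Cohort structure: 40 subjects per group across five sites with weights
matching a typical multi-site autism cohort; age ~ N(18.4, 8²) truncated
to [5, 50]; FD lognormal with ≈2% mass above the 0.3 mm cutoff. Shift
magnitudes: baseline 30 units; networks 1–4 get 55 in the atypical group
(injected increase); network 5 gets 70 typical / 10 atypical (injected
*decrease*, so sign recovery is tested in both directions); magnitudes
rise with age at 0.3 units/year with the same slope in both groups (no
interaction by construction), plus subject noise (SD 8). Severity for
atypical subjects is a + b·(realized mean shift) + noise with a = −2,
b = 0.35, noise SD 0.5, clipped to [1, 10].

No printed effect sizes exist for these quantities in ground-truth units;
the values above were calibrated once so that each injected effect is
recoverable at n = 40/group — the study size the validation targets — and
then frozen. They are documented as a modeling choice, not as estimates
of any empirical effect.

**What the synthetic validation shows and does not show.** Passing tests
establish that the pipeline recovers known topographic shifts, that its
error rates are controlled under its own null, and that every primitive
matches an independent oracle. The generator omits hemodynamics,
vertex-level structure, spatially correlated noise, head-motion artifacts
beyond a scalar FD, and realistic between-network connectivity profiles;
agreement here therefore validates the *machinery*, not any empirical
claim about real cohorts.

## Numerical choices and limitations

- Correlation clipping 1e−7; GMM regularization 1e−6; EM tolerance 1e−6;
  retention ties by column index; embedding sign by first non-negligible
  entry; permutation and spin p-values floored at 1/(n+1).
- Exact-fit GLMs (zero residual variance) report t = ±∞ with a flag
  instead of a 0/0 artifact; inside permutation passes, infinities are
  clipped to a large finite value before TFCE.
- Whether negative z values may rank among the "most similar" retained
  entries is not specified by the source analysis; ranking is by signed z
  (most positive first) and configurable.
- The alignment uses all parcels as correspondences; a network-restricted
  variant was considered and rejected for lacking any stated basis.
- At P well beyond ~2000 the dense eigensolver and the dense all-pairs
  geodesic matrix become the bottlenecks; both are deliberate choices for
  determinism at atlas scale (P ≤ 1000).
- Descriptors are cortical; subcortical nodes are out of scope.
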