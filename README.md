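# retica

Topographic ICA on image patches, and the spatial organization of the
learned oriented units back in retinal coordinates.

## The problem

Neurons in primary visual cortex are oriented edge filters, and in cats
and primates they are arranged in *orientation maps*: locally continuous
iso-orientation domains, embedded in a retinotopic layout, so that a map
measured on the cortex has a structured counterpart in visual space.
Topographic ICA (TICA) is the classic functional model that produces
orientation maps in its learned 2-D topology.  But the model's topology is
not the retina: to compare with biology one must project every learned
unit back to the retinal location of its receptive field and ask whether
same-orientation units cluster there, or are scrambled salt-and-pepper.

`retica` is the toolbox for that analysis, aimed at computational
neuroscientists and anyone doing point-pattern statistics on 2-D filter
populations.  It provides:

* **Synthetic data** for every stage: sparse-Gabor naturalistic images,
  Laplacian-source ICA ground truth, planted unit ensembles with either
  continuous iso-orientation domains or salt-and-pepper orientations, and
  uniform/Cartesian/Neyman–Scott reference point sets.
* **Scale-controlled sampling**: random DC-removed patches with visual
  angle `N/fs` degrees, antialiased undersampling, PCA whitening
  (an sklearn-style transformer, `PCAWhitener`).
* **TICA training** (`TopographicICA`, sklearn-style): orthonormal filters
  `s_i = w_i' z` on whitened patches, energies pooled over an `L x L`
  toroidal window `e_j = sum_i h(i,j) s_i^2`, and monotone gradient ascent
  on the sparsity objective `L(W) = (1/T) sum_t sum_j G(e_j(t))` with
  `G(u) = -(eps + u)^p`.
* **Gabor characterization**: each unit summarized by a nonlinear
  least-squares Gabor fit (center in degrees, frequency in cpd, stripe
  orientation mod 180°), scored by MAE normalized by the unit's range,
  with a 12.5% retention threshold.
* **The uniformity test**: for the centers of units tuned to one
  orientation bin (`S_ori`), the Kullback–Leibler divergence of their
  occupancy histogram from a matched Cartesian grid (`S_cart`), compared
  against a Monte-Carlo null of uniform sets (`S_rand`), with a
  three-outcome decision (more regular than uniform / consistent with
  uniform / inconclusive, possible structure).

## Worked example

Train a small model on synthetic naturalistic images and test whether its
oriented units cluster in retinal space:

```python
from retica import (gen_sparse_gabor_images, extract_patches, whiten,
                    build_topology, fit_tica, receptive_fields, build_atlas,
                    orientation_partition, uniformity_test)

ens = gen_sparse_gabor_images(n_images=100, size=64, density=40,
                              fs=25.0, seed=11)
data = extract_patches(ens, N=16, T=10000, seed=12)
Z, wm = whiten(data, d_r=100)
model = fit_tica(Z, build_topology(10, 10, 5), n_iter=500, seed=13)
atlas = build_atlas(receptive_fields(model, wm), model.topology, ens.fs)
print(f"visual angle: {data.visual_angle:.2f} deg, "
      f"retained units: {len(atlas)}/100")
part = orientation_partition(atlas, K=4)
for b, pts in enumerate(part.members):
    res = uniformity_test(pts, n_real=2000, seed=40 + b)
    print(f"theta ~ {part.centers[b]:5.1f} deg: M={pts.M:3d} "
          f"KLD={res.kld_obs:.3f} null mu={res.null_mean:.3f} "
          f"p_left={res.p_left:.3f} -> {res.outcome}")
```

Output:

```
visual angle: 0.64 deg, retained units: 84/100
theta ~   0.0 deg: M= 19 KLD=0.416 null mu=0.578 p_left=0.123 -> consistent_with_uniform
theta ~  45.0 deg: M= 24 KLD=0.467 null mu=0.582 p_left=0.199 -> consistent_with_uniform
theta ~  90.0 deg: M= 23 KLD=0.588 null mu=0.603 p_left=0.463 -> consistent_with_uniform
theta ~ 135.0 deg: M= 18 KLD=0.413 null mu=0.606 p_left=0.088 -> consistent_with_uniform
```

Reading it: 84 of the 100 learned units pass the Gabor-quality filter; the
centers of the units in every 45°-wide orientation bin have a spatial
histogram whose divergence from a matched Cartesian grid sits inside the
central 90% of the uniform null — i.e. the model's oriented units are
spatially *indistinguishable from random scatter* (salt-and-pepper), not
clustered into iso-orientation domains.  A planted ensemble with genuine
domains (`gen_unit_ensemble(PlantedMapSpec("domains"))`) lands in the
`inconclusive_possible_structure` outcome for a majority of bins instead.

A CLI mirrors the library (`retica synth / sample / train / fit-gabors /
maps / test / run`); `retica run --config run.yaml` executes the full
multi-scale experiment and writes models, atlases, per-bin test reports,
figures and a provenance manifest.

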