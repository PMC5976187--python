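# vesseltrace

Cooperative minimum-cost-path centerline extraction at vessel bifurcations.

## The problem

Centerlines of the carotid artery are commonly extracted from MRI as two
minimum-cost paths that share a trunk: common carotid (CCA) to internal
carotid (ICA), and CCA to external carotid (ECA).  The tracking cost is
only as good as the image: when one branch has poor lumen contrast, both
independently extracted paths run up the clearly visible branch and the
faint branch is missed entirely.  `vesseltrace` implements a cooperative
correction for this failure: each branch path is re-extracted with a
blocking constraint around its neighbour's post-bifurcation course, which
guarantees the two centerlines cannot follow the same path beyond the
bifurcation.

The package is aimed at researchers working on vascular image analysis
who need a complete, testable reference pipeline: cost construction,
anisotropic fast marching, cooperative correction, evaluation metrics,
and a synthetic phantom generator so that everything runs and is verified
without any MRI data.

## Method

**Cost image.** For voxel intensity I(x), the tracking cost is

    p(x) = 1 / (eps + m(x)^alpha * s(x)^beta),        p~(x) = p(x) + omega

where `m` is a multi-scale circular medialness in [0, 1] (high at centres
of tubular cross-sections), `s` is a Gaussian similarity to the lumen
intensity statistics inside spherical ROIs around the seed points
(radius 3.5 mm at the CCA seed, 2.5 mm at the branch seeds), and the
constant `omega` penalises path length, enforcing smoothness.  With
several co-registered sequences, each term is maximised voxelwise over
the sequences before combining.

**Minimum-cost paths.** The minimal action map U, with ||grad U|| = p~ and
U(p0) = 0, is solved by fast marching with the first-order upwind scheme
on the anisotropic voxel grid (per-axis spacings h_i, 6-connected
neighbourhood):

    sum_i ( max{U(x) - U(x - d_i), U(x) - U(x + d_i), 0} / h_i )^2 = p~(x)^2

The centerline is then recovered by fourth-order Runge-Kutta integration
of -grad(U)/||grad U|| from the endpoint back to the source at step
delta = 0.1 mm.

**Cooperative correction.** Both branch paths are first extracted
independently.  The one with the lower average cost (U at its endpoint
divided by path length) is kept as the best path; the voxels within
rho = 1.75 mm of its course beyond the bifurcation gap point are set to a
high blocking cost K, and the neighbour path is recomputed on that cost.
A second constraint around the corrected neighbour then re-extracts the
best path.  Four variants are provided: SCIE and SCBIE extract the
branches independently (the *BIE forms route both centerlines through a
bifurcation seed obtained by shifting the annotated gap point t = 5.1 mm
back along the CCA path), CCIE and CCBIE are their cooperative
counterparts.

**Evaluation.** Curves are compared by the Hausdorff distance H; the
per-artery error CAD = max(H_ica, H_eca) counts as a failure when it
exceeds 3.5 mm (about one artery radius).  Leave-one-case-out selection
of `omega` and an exact binomial McNemar test on discordant failures
complete the evaluation tools.

## Worked example

The `demo` subcommand renders the faint-branch phantom (one branch at 45%
lumen contrast), builds the cost from its two pseudo-sequences, runs all
four method variants, and scores them against the analytic ground truth:

```sh
vesseltrace demo --out demo_out --seed 7
```

```
INFO vesseltrace: SCIE: CAD=7.921 mm failed=True
INFO vesseltrace: SCBIE: CAD=7.921 mm failed=True
INFO vesseltrace: CCIE: CAD=2.003 mm failed=False
INFO vesseltrace: CCBIE: CAD=1.889 mm failed=False
```

The independent extractions (SCIE/SCBIE) miss the faint branch by ~8 mm —
both centerlines ran up the bright branch — while the cooperative
variants recover it to about 2 mm, i.e. inside the lumen.  `demo_out/`
contains the volumes (`seq1.nii.gz`, `seq2.nii.gz`), seeds, ground-truth
and extracted centerlines (JSON point lists), and `evaluation.csv` with
per-branch Hausdorff distances:

```
case,method,H_ica,H_eca,CAD,failed
faint_branch,SCIE,0.1560,7.9211,7.9211,True
faint_branch,SCBIE,0.1581,7.9213,7.9213,True
faint_branch,CCIE,0.3431,2.0032,2.0032,False
faint_branch,CCBIE,0.6491,1.8893,1.8893,False
```

The individual pipeline stages are also exposed (`vesseltrace phantom`,
`cost`, `extract`, `evaluate`), and the same functionality is available
as a library:

```python
import vesseltrace as vt
from vesseltrace import phantom, cost, cooperative, evaluation

spec = phantom.faint_branch_preset()
seq1, seq2, truth = phantom.make_phantom(spec)
image = cost.multispectral_cost([seq1, seq2], truth.seeds,
                                phantom.study_cost_params(spec))
image = cost.crop_roi(image, truth.seeds)
result = cooperative.run_method("CCBIE", image, truth.seeds)
```

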