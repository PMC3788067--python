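# tracerval

**Validation of DTI-tractography connectivity measures against anatomical
tracer histology, on a synthetic phantom with known ground truth.**

Diffusion-tensor tractography is routinely used to estimate cortico-cortical
connectivity, on the hypothesis that the number of streamlines N<sub>D</sub>
connecting two cortical regions is proportional to the number of axons
N<sub>B</sub> connecting them. Testing that hypothesis against anatomical
tracer data requires a long chain of image processing: segmenting labelled
fibers in micrographs, counting the fibers that cross the white/gray-matter
(WGM) boundary, gridding their centroids into *density distribution maps*
(DDMs), carrying those maps through a histology-to-MRI registration chain
with Jacobian-determinant density compensation, projecting them onto the 3D
WGM interface, and comparing them — regionally and voxel by voxel — with the
interface densities of deterministic (FACT) and probabilistic streamlines.

`tracerval` implements that entire chain as a tested, reusable library, and
exercises it on a digital phantom in which the "anatomy" is known exactly: a
cortical slab with an injection region, eight projection regions whose axon
counts span three orders of magnitude, curved white-matter bundles with
prolate diffusion tensors, Rician-noise DWI (31 directions, b = 1200 s/mm²,
0.3 mm voxels, SNR ≈ 25), synthetic boundary micrographs with planted
fibers, and smooth invertible deformation fields with analytic Jacobians.
Because every input is generated, every stage of the pipeline can be checked
against construction-level ground truth.

Who this is for: researchers validating tractography pipelines, developing
histology-MRI co-registration chains, or needing a fully controlled test bed
for connectivity statistics.

## The quantities at the core

* **Regional agreement.** Per region, N<sub>D</sub> is regressed on
  N<sub>B</sub> with a free intercept *a*; if 0 lies in the 95% CI of *a*
  the model is refit through the origin (N<sub>D</sub> = b·N<sub>B</sub>).
  Pearson *r*, Spearman *r*<sub>s</sub>, and the Spearman restricted to the
  strongest connections (N<sub>B</sub> > 100), (*r*<sub>s</sub>)<sub>top</sub>,
  are reported, along with false negatives (N<sub>B</sub> > 0, N<sub>D</sub> = 0)
  and false positives (N<sub>B</sub> = 0, N<sub>D</sub> > 0).
* **Voxelwise agreement.** Within one region,
  r<sub>p</sub> = Σ(B<sub>i</sub>−B̄)(D<sub>i</sub>−D̄) /
  √(Σ(B<sub>i</sub>−B̄)² Σ(D<sub>i</sub>−D̄)²) over the n interface voxels
  beneath that region.
* **Seed depth sweep.** All comparisons are repeated with the tracking seed
  (and selection) region extended d<sub>w</sub> = 0, 0.3 and 0.6 mm into the
  white matter beneath the interface — the lever that rescues pathways
  occluded by superficial crossing fibers.

## Worked example

```python
from tracerval import RunConfig, run_experiment

result = run_experiment(RunConfig(output_dir="demo_run", rng_seed=5))
print(result.report_path.read_text())
```

The run builds the 64³ phantom, simulates and refits the DWI, tracks with
both schemes, builds the histology and tractography interface DDMs, and
writes `demo_run/report.md`. With seed 5 the regional-agreement table reads
(abridged):

```
| comparison            | d_w = 0 mm        | d_w = 0.3 mm      | d_w = 0.6 mm      |
| ds: N_B vs N_D, r     | 0.992 (p<1.2e-07) | 0.992 (p<1.4e-07) | 0.992 (p<1.5e-07) |
| ds: N_B vs N_D, r_s   | 0.8   (p<0.0096)  | 0.778 (p<0.014)   | 0.778 (p<0.014)   |
| prob: N_B vs N_D, r   | 0.988 (p<6.3e-07) | 0.992 (p<1.6e-07) | 0.993 (p<8.6e-08) |
```

and the connectivity table for the deterministic scheme at
d<sub>w</sub> = 0.6 mm begins

```
roi  N_B        N_D  N_S    N_T
1    14958.2    581  14976  555
2    1991.5     36   1996   31
3    50.0       21   50     21
```

Reading this: region 1 was planted with 15000 axons; 14958.2 tracer-fiber
counts survive the full DDM chain (gridding, two deformation transfers with
Jacobian compensation, interface assignment — mass is conserved to < 0.1%),
and 581 selected streamlines cross that region's interface. The Pearson
r ≈ 0.99 between N_D and N_B (dominated by the strongest connections) with a
lower Spearman rank agreement reproduces the qualitative behaviour seen with
real tracer data: streamline counts identify strong connections reliably and
rank weak ones poorly. On a phantom with an occluding crossing bundle, the
occluded region's N_D drops to 0 (a false negative) at d_w = 0 and is
recovered at d_w = 0.6 mm.

A command-line interface wraps the same pipeline:

```bash
tracerval run -c config.yaml --seed 5 -o demo_run
tracerval detect micrograph.tif --markers markers.tsv   # fiber counting
tracerval grid crossing.tsv --image-size 6660           # DDM gridding
```

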