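# protocol_lab

Protocol optimization for diffusion-MRI structural connectomics of the
mouse brain, reproduced as a simulation study on synthetic phantoms.

High-end ex-vivo mouse diffusion acquisitions (120 diffusion
directions, 43-µm voxels, single shell at b = 4,000 s/mm²) take
hundreds of hours; population studies need cheaper protocols that
still recover the same connectome.  This package implements the whole
evaluation chain needed to answer *how much* angular and spatial
resolution can be traded away:

* **gradients** — electrostatic-repulsion direction sets, angular
  subset extraction by antipodal dot-product snapping, FSL-style
  bvec/bval IO;
* **conditioning** — the N×6 second-order design matrix
  `(gx², gy², gz², 2gxgy, 2gxgz, 2gygz)`, its SVD condition number
  σ_max/σ_min, and a Monte Carlo over Haar-uniform rotations that
  ranks schemes by rotational stability;
* **phantom** — a brain-like multi-fiber phantom (thick fimbria-like
  bundle, thin curved fornix-like bundle, a 90° crossing, gray-matter
  blobs) with ball-and-stick signal
  `S(g) = S0[(1−Σf_i)e^{−bd} + Σf_i e^{−bd(g·v_i)²}]` and Rician
  noise;
* **downsample** — spatial downsampling by cropping the center of
  k-space (the 43 → 86 → 172 µm simulation);
* **fibers** — per-voxel tensor fit plus a batched ball-and-stick fit
  with up to four sticks, BIC model order selection, and
  residual-bootstrap dyad dispersion `1 − ‖mean aligned dyad‖`;
* **tracking** — probabilistic streamlines with fraction-weighted dyad
  draws and dispersion-scaled angular kicks;
* **connectome** — region×region streamline counts, Spearman rank
  correlation of connectomes, and Blondel vertex similarity
  `S_{k+1} = B S_k Aᵀ + Bᵀ S_k A` (normalized even iterates);
* **pipeline** — the orchestrated (angular subset × spatial factor)
  experiment grid with deterministic seeding and CSV outputs.

For whom: anyone designing rodent diffusion protocols or studying how
acquisition choices propagate into tractography and graph-level
statistics, and anyone who wants a self-contained, ground-truthed
sandbox for the estimators themselves.

## Worked example

```python
from protocol_lab import (
    generate_uniform_directions, subset_by_dot_product,
    design_matrix, condition_number, rotation_stability,
)

full = generate_uniform_directions(120)          # electrostatic table
target = generate_uniform_directions(60)
sub = full.subset(subset_by_dot_product(full, target), name="snapped-60")

print(round(condition_number(design_matrix(full)), 4))
print(round(rotation_stability(full, 50_000, seed=0).cn_mean, 4))
print(round(rotation_stability(sub, 50_000, seed=1).cn_mean, 4))
```

prints

```
1.5815
1.5818
1.6033
```

i.e. the 120-direction table is essentially at the uniform-sampling
floor √(5/2) ≈ 1.5811 of the quadratic design (its condition number
moves by less than 1e-3 under arbitrary rotations of the object),
while the 60-direction subset snapped out of it pays about 0.02 in
conditioning — still the best of the nine reduced schemes.

The full experiment (about ten minutes) runs through the numbered
scripts:

```sh
python analysis/01_condition_numbers.py    # stability audit of 9 schemes
python analysis/02_run_pipeline.py         # phantom -> fit -> track -> connectomes
python analysis/03_compare_connectomes.py  # similarity summaries
```

The final script prints, among other things, the global Spearman
similarity of every reduced protocol to the reference (`A` = angular
directions, `S` = spatial downsampling factor):

```
Similarity to the reference protocol (A120, full resolution):
  other      rho
 A60_S1 0.992513
 A45_S1 0.974601
A120_S2 0.940336
 A12_S1 0.920090
 ...
A120_S4 0.749207
```

Sixty directions at full resolution are nearly indistinguishable from
the reference; dropping to 12 directions costs more than halving the
spatial resolution; factor-4 downsampling is the most damaging move.
The Blondel per-node scores in the same report show the thick
white-matter bundle surviving downsampling far better than any
gray-matter blob — the robust-tract / vulnerable-cortex asymmetry the
protocol design has to respect.

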