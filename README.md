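# dynoc — dynamic overlapping communities in brain functional networks

`dynoc` is a Python toolkit for detecting **overlapping communities shared
across time** in dynamic (time-resolved) brain functional networks, built for
resting-state fMRI analyses in which a region of interest may belong to
several functional communities at once and community intensities vary from
one time point to the next.

The pipeline it implements:

1. **Jackknife-correlation (JC) connectivity.** For two regional BOLD signals
   x and y, the connectivity assigned to time point t is
   `JC_t = −corr(x, y | all time points except t)` — the negated
   leave-one-out Pearson correlation — and each edge's T values are then
   z-scored across time (population SD). After standardization, a large value
   means time point t contributed strongly to that edge's correlation,
   independent of the edge's static correlation level. This yields an
   N×N×T tensor per subject.
2. **Group-level dynamic network.** For every edge (i, j), each subject
   contributes a length-T feature vector; the subject whose vector minimizes
   the summed Euclidean distance to all subjects' vectors is selected and its
   whole time course is copied into the group tensor F (no averaging — a
   provenance table records whose trajectory each edge carries).
3. **Overlapping community detection.** With F clipped non-negative, solve

   ```
   min_{C, Z_t ≥ 0}  Σ_t ‖F_t − C Z_t Cᵀ‖_F² + β‖C‖₁    s.t. max_j C[·, j] = 1
   ```

   where C (N×k) holds non-negative membership strengths shared by all time
   points and Z_t is a diagonal non-negative intensity matrix per time point.
   Optimization alternates a multiplicative update for the Z_t with a
   projected-gradient step for C (negatives clipped, columns renormalized to
   max 1 with the intensities rescaled to preserve C Z_t Cᵀ), over multiple
   random restarts. k and β are chosen by grid search with 2-fold
   cross-validation over time points.
4. **Evaluation metrics.**
   - *Structural stability*: repeated randomly initialized detections are
     hardened to partitions, averaged into a consensus matrix, and scored by
     the cophenetic correlation coefficient (ccc) of its average-linkage
     hierarchy — 1 means perfectly stable communities across runs.
   - *Node functional diversity*: Shannon entropy of a region's normalized
     community weights `D_t = C diag(√z_t)` at each time point (0 for a
     single-community region, ln k at uniform membership).
   - *Community activity level*: `a_p(t) = z_p(t) · mean(C[N_p, p])` where
     N_p are the regions strictly above the column's mean + 1 SD threshold;
     overlapping nodes are the regions that pass that threshold in two or
     more communities.
   - A label-permutation test compares any per-unit metric between cohorts.

A seeded synthetic-data generator plants ground-truth overlapping community
structure (block membership with anchored column maxima, sinusoidal temporal
intensities, symmetric Gaussian noise) so the entire pipeline is testable
without any imaging data.

## Worked example

```python
import numpy as np
import dynoc

truth = dynoc.make_truth(n_regions=30, n_communities=3, overlap_fraction=0.1,
                         T=20, seed=1)
print("planted overlap nodes:", truth.overlap_nodes)

tensors = dynoc.simulate_group_tensors(truth, n_subjects=6, noise_sd=0.1, seed=2)
network = dynoc.build_group_network(dynoc.GroupTensorSet(tensors=tensors))
network = dynoc.preprocess_nonnegative(network)

model = dynoc.fit(network, k=3, beta=0.1, n_init=20, seed=3)
print(f"objective: {model.objective_trace[-1]:.2f} after "
      f"{len(model.objective_trace) - 1} sweeps (converged={model.converged})")

found = dynoc.overlapping_nodes(model.C)
print("detected overlapping nodes:", sorted(found))

curve = dynoc.stability_curve(network, k_grid=[2, 3, 4], n_runs=20, beta=0.1, seed=4)
print(curve.to_string(index=False))

act = dynoc.activity_level(model)
print("mean community activity:", np.round(act.summary, 3))
```

Output:

```
planted overlap nodes: (0, 10, 20)
objective: 265.06 after 21 sweeps (converged=True)
detected overlapping nodes: [0, 10, 20]
 k      ccc  n_runs
 2 0.981588      20
 3 1.000000      20
 4 0.999494      20
mean community activity: [0.495 0.437 0.517]
```

The detector recovers exactly the three planted overlap regions; the
stability curve peaks at the planted k = 3 (ccc = 1.0 means the twenty
independently initialized runs agree perfectly on the hardened community
assignment); and the activity summaries reflect the time-averaged intensity
of each community weighted by its thresholded members' strengths.

## Command line

Every stage is also a `dynoc` subcommand: `simulate`, `jc`, `group`,
`detect`, `select`, `stability`, `diversity`, `activity`, `overlaps`,
`compare` and `run` (full pipeline from a flat `key = value` config file —
see `examples/config_example.txt`). All artifacts are delimited text with a
JSON manifest; reruns with the same config and seed are bitwise identical.
Exit codes distinguish parameter (2), structural (3) and numerical (4)
errors.

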