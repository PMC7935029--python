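# Methods

## Model

Each fMRI frame is treated as a signal on a fixed directed graph whose
nodes are atlas ROIs. The graph is built from functional connectivity:
per-record FC matrices (Pearson correlation of ROI time courses over all
frames) are averaged into a group FC matrix using **training records
only**, and each node keeps directed edges to the k nodes with the largest
*signed* correlation (the coefficient itself, not its magnitude; the
diagonal is excluded; ties break toward the lower node index so graphs are
identical across platforms). One graph is shared by all subjects, frames
and layers.

Convolution is the asymmetric EdgeConv edge function

    x_i' = max_{j:(i,j) in E} h_Theta( x_i || x_j - x_i )

with h_Theta a ReLU MLP (one linear map per convolution block by default;
depth is configurable) and a feature-wise maximum over the k neighbors.
The concatenated input gives each feature access to the node's own
activity and to its co-activation difference with a neighbor, which is
where correlation structure expresses itself frame by frame.

The network stacks five such layers. Outputs of layers 1..4 are
concatenated and fed to layer 5 (skip connections by concatenation, which
tolerates unequal widths). Per frame, node features are reduced to a frame
embedding; the temporal head combines frame embeddings (arithmetic mean by
default, or a single tanh recurrent layer whose final hidden state is
used); a linear softmax layer yields class probabilities.

Two choices here were genuinely open and are worth flagging:

* **Node-to-frame reduction.** Global max/average pooling over nodes is
  the point-cloud convention, but it discards node identity. Connectome
  fingerprints live in *which* ROI pairs co-fluctuate, i.e. in
  node-indexed second moments; after global pooling the embedding of a
  held-out session is statistically indistinguishable across subjects (we
  measured chance-level cross-session generalization with both max and
  mean pooling, against perfect generalization with a node-preserving
  reduction). The default is therefore `flatten` — the N x F feature map
  is concatenated into one frame vector — with `max` and `mean` available
  in the config.
* **Normalization.** Each linear map inside an edge MLP is followed by
  batch normalization before the ReLU, as in the dynamic-graph CNN
  lineage EdgeConv comes from. Without it the stacked ReLU/max network
  collapses onto a large shared offset and optimization stalls at chance.
  Batch statistics are used while training; evaluation uses tracked
  running moments (momentum 0.9), so a trained model is a deterministic
  function. Linear biases are omitted under BN (its mean subtraction
  cancels them exactly).

The implementation is plain numpy with hand-derived gradients (EdgeConv,
BN, the recurrent head's backpropagation through time, Adam), verified
against central finite differences to ~1e-9 in float64. Exact ReLU/max
ties are sent down one branch (the first maximizer), the standard
subgradient choice. Parameters default to float32 for speed; float64 is
available via `CgcnModel.initialize(..., dtype=...)`.

## Training protocol

Records are z-scored per ROI column within each record (correlation is
scale-free, and the network needs comparable input magnitudes; the
statistics come from the record itself, so normalization cannot leak
across records or folds). Time courses are cut into non-overlapping
100-frame clips; a clip inherits its record's label; the trailing
remainder is dropped. The loss is categorical cross-entropy plus an L2
penalty on weight matrices. Optimization is Adam; when validation accuracy
has not improved for `lr_patience_epochs` (default 5) epochs the learning
rate is halved, never below 1e-6. Parameters (and BN running moments) are
snapshotted only when a new best validation accuracy is reached, and the
best snapshot is returned. The L2 coefficient is chosen by refitting once
per value of {0.1, 0.01, 0.001, 0.0001} and keeping the best-validation
run (ties toward the smaller penalty).

Evaluation scores each test record on the *first* n frames as a single
clip, for any n from the full scan down to one frame, so accuracy-vs-frame
curves are deterministic. Cross-validation harnesses rebuild the group FC
and graph from each fold's training records only; stratified k-fold
partitions *subjects* (site x class proportions preserved; all sessions of
a subject stay together) to rule out twin-clip leakage.

Saliency is single-ROI occlusion: with the trained model fixed, one input
column at a time is set to zero — after z-scoring, so "zero" is that ROI's
mean level — and the accuracy drop relative to baseline is the ROI's
contribution. A full scan costs exactly N+1 evaluation passes and never
touches the graph or weights.

## Synthetic cohorts

The generator emulates the statistical structure the classifier exploits,
not the physiology. Signals are zero-mean multivariate Gaussian draws,
i.i.d. across frames (an optional AR(1) coefficient adds smoothness; the
conv stack consumes frames independently, so temporal correlation is
secondary). The correlation matrix of each subject is built as:

1. a block structure: N ROIs in `n_networks` equal blocks,
   `within_network_corr` (default 0.6) inside a block, 0 between;
2. plus a subject *fingerprint*: a symmetric Gaussian perturbation of
   magnitude `fingerprint_strength` (default 0.5) supported on the
   informative ROIs (the first half of the networks), drawn once per
   subject and reused for all sessions;
3. plus, optionally, a class effect: a fixed symmetric perturbation of
   magnitude `group_effect` on *between*-network entries among the
   informative ROIs, shared by all subjects of a class — giving occlusion
   a ground-truth set of informative ROIs;
4. projected to the nearest valid correlation matrix (eigenvalues clipped
   at 1e-3, diagonal renormalized), so sampling never fails.

`noise_sd` is the marginal standard deviation of every ROI (a pure scale;
correlations are unchanged). Site effects are per-site affine distortions
(gain ~ 1 + 0.1 x `site_effect` x N(0,1) per ROI, offset ~ `site_effect` x
N(0,1)), mimicking scanner variation without destroying correlation
structure. All randomness derives from one seed through spawned
sub-streams, so cohorts are bit-reproducible.

What this does **not** model: hemodynamics and BOLD spectra, motion and
physiological artifacts, non-Gaussian tails, heavy site-specific
covariance differences, atlas misregistration. Passing the simulation
studies therefore shows the pipeline recovers planted covariance
structure under its own assumptions — not that the published real-data
accuracies would be reproduced.

## Desk-scale study conditions

The bundled experiments run on one CPU core in a few minutes each:

* **Identification** — 20 subjects x 2 sessions, 60 ROIs in 4 networks,
  300 frames per session, strong fingerprints (0.5). Graph (k=5) and
  training clips come from session 1 (two 100-frame clips per record for
  training, one for validation); session 2 is the test set, scored at 1,
  5, 10, 30 and 100 frames. Chance is 1/20.
* **Graph control** — same cohort, k=3, matched models trained on
  connectivity vs seeded-random graphs; accuracy compared at 10 test
  frames, the few-frame regime where the neighborhood definition matters
  most.
* **Occlusion** — 24 subjects, 2 classes, 40 ROIs, class effect 0.5 on
  between-network coupling among the 20 informative ROIs, mild
  fingerprints (0.2). Saliency is scored over every 30-frame window of
  the test sessions (240 evaluation units) so per-ROI accuracy drops are
  graded rather than quantized by a handful of records.

Model widths in these experiments are (8, 8, 8, 8, 16); training is Adam
at 0.01 with batches of two clips for ~15 epochs. With ~40 training clips,
small batches give enough optimizer steps per epoch for the softmax head
to converge; the batch-norm statistics are computed over frames x nodes x
neighbors and remain stable at this batch size.

## Numerical notes and limitations

* k-NN ranking uses signed correlation; strong negative edges are
  deliberately not selected (an absolute-value variant would be a
  one-line change but is not what the graph-construction rule specifies).
* Group FC averages raw coefficients; Fisher-z averaging is available via
  a flag and changes little at these correlation levels.
* The float32 default makes forward outputs reproducible bit-for-bit on a
  given platform but not across BLAS implementations; checkpoints store
  exact arrays, so save/load round trips are bit-identical.
* The recurrent head is a plain tanh recurrence trained by full BPTT; it
  is the non-deterministic-free alternative and is not used by the
  bundled experiments, which rely on the fully deterministic
  average-pooling head.
* `l2_sweep` refits from scratch per grid value with a seed offset; it
  does not share initialization across grid points.
* Occlusion saliency is contrastive only at ROIs the model actually uses;
  ROIs that are informative in principle but redundant given their
  neighbors can legitimately show near-zero drops.
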