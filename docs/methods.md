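# Methods

## Model

The regressor maps a mutation-centered window of the mutant protein chain
to ΔΔG = ΔG_mutant − ΔG_wild-type (kcal/mol). Two per-residue embedding
streams of the same window enter separate branches:

- **Encoder branch** (ESM-2-class stream, L×1280). Two fully connected
  ReLU layers reduce 1280 → 768 → 512 per position; a fixed sinusoidal
  positional-encoding table (entry(pos, 2i) = sin(pos/10000^(2i/d)),
  entry(pos, 2i+1) = cos(·)) is added; `num_layers` post-norm Transformer
  encoder layers (multi-head scaled dot-product attention, position-wise
  feed-forward of width 2·d_model, residual connections, layer norm,
  dropout on sub-layer outputs) operate at d_model = 512 with 4 heads; a
  linear projection yields an L×256 map, and the mutation-site row is the
  branch feature (256 values).
- **Multiscale convolution branch** (ProtT5-class stream, L×1024). Two
  fully connected ReLU layers reduce 1024 → 512 → 256 per position; the
  L×256 map is treated as a single-channel 2-D image and passed through
  three blocks, each running three parallel sub-layers with 3×3, 5×5 and
  7×7 kernels in the order convolution → ReLU → batch normalisation → 2×2
  max-pooling, channel-concatenated between blocks (8/16/32 channels per
  scale); global average pooling and one fully connected layer produce a
  512-vector.
- **Fusion head.** Active branch features are concatenated (256+512=768)
  and passed through fully connected layers of widths 256 → 128 → 1 with
  ReLU and dropout between layers; the last layer is the linear ΔΔG
  readout.

Branch modes (`passthrough`, `encoder`, `multiscale_conv`, `off`) swap
either stream's processing for the ablation grids; `passthrough` is the
two-layer reduction with site-row extraction and no attention or
convolution.

Where the architecture description leaves choices open we fixed them as
follows: reduction stems interpolate input and output width at their
midpoint; all "nonlinear fully connected" layers use ReLU; positional
encoding is fixed sinusoidal rather than learned; the encoder runs at
d_model 512 and projects to the 256-wide output map; the convolution image
is single-channel (positions × features); "same" spatial padding precedes
each pool; the conv branch's fixed-length vector comes from global average
pooling followed by one fully connected layer; dropout inside the encoder
reuses the global rate. The L2 penalty is an explicit `l2_reg · Σ‖W‖²`
term over weight matrices (biases and normalisation parameters excluded)
added to the loss, keeping it optimizer-agnostic rather than coupled to a
particular decay implementation.

### Numerical backend

The network, its gradients and Adam run on a package-local reverse-mode
autodiff engine over numpy arrays (`priddg.nn`). Convolution uses a
strided-view einsum contraction; max-pooling routes gradients to the first
maximal element of each 2×2 window; softmax subtracts the detached row
maximum (exact, by shift invariance). Every operation and layer is
validated against central finite differences to ~1e-6 absolute error in
the test suite. Parameters are float64 at initialisation and cast to
float32 for training; initialisation is fan-in-scaled normal,
N(0, √(2/fan_in)), fully determined by the seed.

## Training and evaluation

Loss: MSE + l2_reg·Σ‖W‖². Optimiser: Adam (β₁ = 0.9, β₂ = 0.999) with the
configured learning rate; minibatches reshuffled each epoch; early
stopping on validation RMSE with best-epoch restoration. Defaults at the
published operating point: lr 1e-4, dropout 0.3, l2 1e-3, batch 32, max
200 epochs, patience 20. Loss, optimiser, batch size and epoch budget are
this package's choices (exposed in `TrainSpec`); only lr, dropout and L2
come from the published operating point.

Protocols: CV1 = repeated random 90/10 train/test, CV2 = 80/20, each
repeated (default 20×, seeds seed+0…seed+r−1); CV3 = 10-fold. In every
protocol, 10% of the training portion is held out for validation. All
split cardinalities use floor rounding with the remainder going to test
then validation (394 → 315/79 at fraction 0.8). "10% for validation" is
read as 10% of the training portion, so the CV1 test fold is exactly 10%
of the data. Splits are mutation-level by default; pair-grouped splitting
(forward/reverse partners move as a unit) is available because a reverse
record in test with its twin in train shares the label magnitude — reports
state which mode was used. Metrics: PCC (undefined on constant vectors and
reported as missing, never zero), RMSE and MAE in kcal/mol; aggregates are
mean ± sample standard deviation over folds.

Dataset construction: duplicate mutation keys agreeing within 1e-6
kcal/mol collapse to one record; keys with conflicting labels are dropped
entirely and logged (a deliberate conservative policy — silently picking
one of several inconsistent measurements would be worse). ΔΔG = 0 bins as
≥ 0 and < 1 in summary counts. Reversibility augmentation registers the
forward record's mutant chain as the reverse record's context, keyed per
record, so both partners validate against their own sequence.

Windowing: windows come from the mutant sequence. Terminus handling is a
package choice: chains ≥ target length slide the window to keep 181 real
residues (off-centre site index recorded); shorter chains are taken whole
and their embedding rows zero-padded at the tail, after embedding, so
tokenizers never see padding symbols. Only mutant windows are embedded.

## Synthetic study design

The generator emulates the statistical shape of curated protein–RNA
mutation benchmarks while staying fully seed-deterministic:

- 68 complexes, 315 forward mutations, chain lengths 120–500, matching
  the curated training set's scale; reversibility augmentation doubles it
  to 630.
- **Labels**: ΔΔG = w·φ + c·direction + ε, where φ is the difference
  between mutant-chain and context-chain synthetic embeddings averaged
  over the ±2-residue neighbourhood of the site, w is scaled to unit
  signal standard deviation (kcal/mol), ε ~ N(0, 0.3 kcal/mol) is drawn
  once per pair and negated for the reverse twin, and the intercept c
  (sign-flipped for reverse records) is set so ~90% of forward labels are
  ≥ 0, mirroring the sign skew of curated forward sets. φ is odd under
  swapping the two chains, so label antisymmetry is exact, not just
  approximate — without paired noise the augmentation invariant would be
  untestable.
- **Synthetic embeddings**: each residue's vector is 0.9 × a per-residue
  identity pattern + 0.1 × a pattern keyed by the ±2 context 5-mer, both
  hashed from the provider seed, bounded in [−1, 1]. Editing one site
  changes rows i−2…i+2 only.
- **Decodability by design.** A model that sees only the mutant window
  cannot observe the other chain of the pair, so label components tied to
  it would be irreducible noise. Two design choices keep the planted
  signal recoverable: (i) mutations are alanine-scanning (forward = X→A),
  as in most curated ΔΔG sets, which makes the record's direction — and
  hence the sign-skew intercept — decodable from the window's centre
  residue; (ii) the wild-type residue at a mutated site is a seed-derived
  function of its right neighbour, a stylised stand-in for the real-world
  predictability of wild-type residues from context (the regularity
  protein language models exploit), which makes the forward records'
  identity signal recoverable from the window too. With both, the best
  linear predictor on (φ, direction) attains held-out PCC ≥ 0.98 and a
  window-only model has an information ceiling near 0.9 — so the package's
  learnability bar (PCC ≥ 0.8) is demanding but attainable.
- What the fixtures do **not** emulate: real biophysics (no energetics, no
  RNA partner, no structure), inter-mutation correlation within a complex,
  heavy-tailed label noise, and label error heterogeneity across source
  labs. Passing the synthetic studies therefore demonstrates that the
  pipeline, architecture and optimisation work as specified — not that the
  model would reach any particular accuracy on experimental data.

## Desk-scale studies

The quantitative studies (learnability, ablation gap, overfit and
antisymmetry diagnostics) run a width-reduced configuration of the same
architecture, `ModelConfig.desk_scale()`: d_model 32, 16-dim encoder
output, 24-wide convolution image with 2/4/8 channels per scale, 32/16/1
head, 31-residue windows, 32/24-dim synthetic embeddings, dropout 0.1,
l2 1e-5, lr 2e-3, batch 32, ≤70 epochs with patience 15. These sizes keep
a full CV2×3 study under five minutes on one CPU core with the numpy
backend. Dropout and L2 are reduced deliberately: rates tuned for
512-wide layers suppress learning entirely in 16–32-wide layers (dropout
0.3 removes a third of a 16-dim feature vector), and the summed-weight L2
penalty at 1e-3 dominates the loss at small widths. The published-width
configuration remains the package default and is exercised by the
shape-contract and gradient-flow tests; the single-sample overfit
diagnostic also disables dropout, since it checks the optimiser and
dropout exists precisely to prevent memorisation.

## Known limitations

- The real ESM-2/ProtT5 providers are thin adapters; without their
  backends (torch + fair-esm / transformers and checkpoint downloads) they
  raise immediately with guidance, and no quantitative study in this
  repository uses them. The exact checkpoints are pinned only by their
  hidden sizes (1280/1024) and can be overridden.
- Published-width training on the 630-record benchmark is possible with
  this backend but takes hours per cross-validation repeat on one CPU
  core; the desk-scale studies are the supported way to exercise the full
  pipeline quantitatively.
- The conflict-resolution rule (drop all disagreeing duplicates) and the
  terminus-handling policy are this package's choices among behaviours the
  task leaves open; both are isolated behind flags/config and logged.
- Batch normalisation with very small batches (e.g. the single-sample
  overfit diagnostic) relies on running statistics converging over
  repeated identical batches; training-mode and evaluation-mode outputs
  can differ noticeably at batch size 1.
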