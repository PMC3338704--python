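# Methods

## Problem and model

Catalytic residues are rare (typically 2–5 per enzyme chain of hundreds of
residues) and are distinguished by evolutionary conservation, chemistry
(polar/charged side chains), and local environment (coil regions, solvent
exposure). `catres` frames their detection as binary classification of
per-residue feature vectors with L1-regularized logistic regression,

min over (w, v) of (1/m)·Σᵢ log(1 + exp(−yᵢ(wᵀxᵢ + v))) + λ‖w‖₁,

labels yᵢ ∈ {+1, −1}, intercept unpenalized. The L1 penalty performs feature
selection inside the fit, which matters because the windowed encoding is
wide (up to 187 slots at window 10) relative to the number of positive
examples, and because the surviving slots are directly interpretable (each
has a name such as `VJSD+0`, `SS-4-E`, `ACH-Win17`, `RT-Cys`).

### Feature channels

Eight channels, in a fixed canonical amino-acid order
(A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V):

- **RT** (20 bits): one-hot residue type; non-canonical letters (B, Z, X, U,
  O) encode as all zeros.
- **OP** (10 bits): membership in Taylor's ten *overlapping* property
  classes, in the order Polar, Positive, Negative, Charged, Hydrophobic,
  Aliphatic, Aromatic, Small, Tiny, Proline. Membership sets are the
  authority for the bit patterns; note that A ∈ Small, so A encodes as
  0000100110 (Hydrophobic, Small, Tiny).
- **ACH** (10 reals): mean Sweet–Eisenberg (OMH, 1983) hydrophobicity over
  centered windows of sizes 3, 5, …, 21. At the termini, out-of-range
  positions contribute 0 to the sum while the divisor stays the full window
  size — the same zero-fill convention used for window assembly. The scale
  is embedded as a constant table (A −0.40 … V 0.91).
- **JSD** (1 real): Jensen–Shannon divergence, log base 2 and mixture weight
  ½, between the profile column's amino-acid distribution p and the BLOSUM62
  background q (the Robinson–Robinson frequencies distributed with the
  BLOSUM62 data, embedded to five decimals; they sum to exactly 1.00000).
  With these conventions the score is symmetric, bounded in [0, 1], and 0
  iff p = q.
- **VJSD** (1 real): the class-level conservation score RVD,
  Σ_c P_c·log₂(P_c/Q_c) over the ten overlapping classes (a sum of
  per-class relative-entropy terms, *not* a KL over a partition, because the
  classes overlap), combined with JSD as the arithmetic mean of the two
  per-chain min–max-normalized tracks.
- **SS** (3 reals): predicted secondary-structure scores stored in (H, E, C)
  order; PSIPRED `.ss2` files carry them as (C, H, E) and are remapped at
  read time.
- **ASA** (1 bit): solvent exposure, binarized at a relative-accessibility
  threshold of 5.0 (the producing tool's units) unless the input is already
  binary. The cut is configurable; 5.0 separates "buried" from "at least
  marginally exposed" in RSA-style outputs.
- **Consurf** (1 real): an external per-residue conservation estimate,
  accepted losslessly at read time and min–max normalized per chain before
  windowing so that its heterogeneous database scales are comparable across
  chains (normalization can be disabled).

Window assembly: RT, OP and ACH describe the central residue only; SS, ASA,
JSD, VJSD and Consurf contribute one block per offset −w…+w, zero-filled
where the window overhangs a terminus. Dimension d = 40 + 7·(2w+1). No
mean/variance standardization is applied: every channel is bounded by
construction, and L1 solution paths are scale-sensitive, so rescaling would
silently change which slots survive.

Profile columns whose percentage row is all zero carry no evidence and fall
back to the background distribution (conservation scores exactly 0), which
avoids log-of-zero pathologies.

## Training and evaluation protocol

- **Class imbalance** is handled by construction of the training set: per
  chain, all catalytic residues plus six background residues per catalytic
  one, drawn uniformly without replacement (seeded). No instance weighting
  is applied on top.
- **Cross-validation** splits *chains*, never residues: windowed features of
  neighboring residues overlap, so residue-level splits would leak
  information between train and test. Chains are shuffled with the seed and
  dealt round-robin into k = 10 folds (sizes differ by at most one chain).
- **Pooling**: held-out scores from all folds are pooled and a single
  PR/ROC sweep is computed on the pool, giving one AUPR/AUC per grid cell.
- **Curves** follow the one-site-at-a-time construction: sites sorted by
  score (ties broken by the stable original row order), the predicted set
  grown one site per step, (P, R, FPR) recorded at every prefix. AUPR uses
  the step-wise average-precision rule this sweep induces (mean precision at
  the prefixes where a positive enters); trapezoidal PR area is available as
  an option. AUC is computed as the rank-sum (Mann–Whitney) statistic with
  the half-tie correction, which equals the trapezoidal ROC area when scores
  are distinct.
- **Operating point**: the sweep point with maximal F = 2PR/(P+R), earliest
  prefix on ties; its threshold is stored in the model and used for calls at
  prediction time. Metrics are computed on the subsampled 6:1 universe
  during tuning; prediction scores every residue of every chain.
- **Grid search**: λ ∈ {0.001, 0.002, …, 0.020} × window ∈ {0, …, 10}
  (220 cells) by default, selecting maximal pooled AUPR with ties preferring
  the smaller window then the smaller λ. The fold assignment is held fixed
  across the grid.
- **Ablation** removes one channel's slots from the layout and reruns the
  identical protocol, giving the leave-one-attribute-out comparison table.

## Solver

FISTA (accelerated proximal gradient) over (w, v) with soft-thresholding on
w only, fixed step 1/L with L = ‖[X, 1]‖₂²/(4m) (the logistic-loss Hessian
bound), adaptive restart on objective increase, and the intercept
initialized at its w = 0 optimum log(m₊/m₋). Stopping: maximal violation of
the subgradient optimality conditions (KKT residual) ≤ 1e−8, checked every
10 iterations. The problem is convex, so this certifies global optimality to
tolerance; the solve involves no randomness and is bit-reproducible. λ_max —
the smallest penalty with all-zero optimal weights — is computed in closed
form from the gradient at (0, log(m₊/m₋)) and is used as a solver sanity
check. The objective uses `logaddexp`, so margins of magnitude 10⁴ and
beyond neither overflow nor lose the loss value.

## Synthetic data

The generator stands in for curated catalytic-site datasets, which require
structure databases and several external prediction tools to assemble. Per
chain (defaults: 50 chains, lengths 60–120, 2 catalytic sites, signal
strength σ = 0.8, all channels carrying signal):

- background residues drawn from the BLOSUM62 background; catalytic residues
  from the polar/charged pool (background-renormalized) with probability
  ½ + σ/2;
- background profile columns are Dirichlet draws around the background with
  concentration 50 (mild noise, so per-chain normalization never sees a
  constant track); catalytic columns are Dirichlet draws around
  (1−σ)·q + σ·one-hot(residue), and exactly one-hot at σ = 1;
- secondary structure: Dirichlet(3.5, 2.0, 4.5) baseline over (H, E, C),
  with catalytic sites mixed toward pure coil with weight σ;
- exposure: Bernoulli(0.45) baseline; catalytic sites exposed with
  probability ½ + σ/2; raw accessibility values are written on either side
  of the 5.0 binarization cut;
- conservation track: standard normal baseline, +2σ shift at catalytic
  sites.

Channel toggles restrict the signal to chosen channels, and
`signal_offsets` moves the track-channel signal to flanking positions —
used to build identifiability fixtures where only windows of sufficient
width can see the signal. σ = 0 gives exact label–feature independence (the
null used to check that the protocol does not manufacture signal).

What the generator does **not** emulate: realistic alignment depth or
phylogenetic correlation between chains, correlated errors of the external
predictors, annotation noise, or realistic chain lengths and site counts per
chain. Passing tests on this generator therefore demonstrate correctness of
the machinery (encodings, solver, protocol) and its ability to recover a
planted signal — not the accuracy attainable on real enzymes, which depends
on the quality of real profiles and tracks.

## Problem sizes

The test suite and the acceptance script run the protocol at deliberately
modest scale — the method's behavior, not throughput, is what they certify:
12–20 chains for unit-level checks, and a 50-chain dataset (700 training
rows after 6:1 subsampling) with a restricted tuning grid (windows {1, 3, 6}
× λ {0.002, 0.01}, ten folds) in the acceptance script. The full 220-cell
grid is available through `catres tune` and scales linearly in cells × folds.

## Known limitations

- The JSD/VJSD arithmetic follows the Capra–Singh formulation (λ_mix = ½,
  log₂) and the mean-combination for VJSD; both are configurable, as
  published variants differ in the mixture weight, the log base, and the
  normalization universe (per chain vs whole dataset; per chain here).
- The ASA binarization cut and the per-chain Consurf normalization are
  heuristics for heterogeneous upstream tools; with differently scaled
  inputs they should be revisited.
- The solver is dense and single-threaded; it is sized for datasets of
  thousands of rows and up to a few hundred features, not genome-scale
  matrices.
- Chains with zero annotated catalytic residues contribute no training rows
  (they are still scored at prediction time).
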