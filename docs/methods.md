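# Methods

This note records the models, conventions and design choices behind
`motifscaffold`, at the level a maintainer or reviewer needs to judge what
the package computes and what its tests do and do not demonstrate.

## Template geometry and binning

Inter-residue geometry follows the trRosetta output space: per ordered pair
(i, j) a Cβ–Cβ distance d and three orientation angles — the symmetric
dihedral ω(Cαᵢ, Cβᵢ, Cβⱼ, Cαⱼ), the asymmetric dihedral
θ(Nᵢ, Cαᵢ, Cβᵢ, Cβⱼ) and the asymmetric planar angle φ(Cαᵢ, Cβᵢ, Cβⱼ).
Glycine receives a virtual Cβ built from N/Cα/C with bond length 1.522 Å,
angle N–Cα–Cβ = 110.4° and dihedral C–N–Cα–Cβ = −122.55° (IUPAC sign).
Real Cβ atoms are used when present; on the bundled fixture the virtual
construction perturbs d by well under 0.3 Å.

The default binning is the trRosetta convention: 36 distance bins of 0.5 Å
over 2–20 Å plus a trailing no-contact bin, 24 ω/θ bins and 12 φ bins of
15°.  Bins are right-open: a value exactly on an interior edge starts the
bin it lower-bounds (d = 3.0 Å → bin 2 = [3.0, 3.5)).  Pairs beyond 20 Å
(and the diagonal) land in the no-contact bin and carry no angle targets.
The bin layout is a convention choice, not a measured quantity; the scheme
descriptor travels with every serialized geometry container so alternative
layouts are first-class.

PDB input goes through gemmi.  Alternate locations resolve to the
highest-occupancy conformer (first listed on ties).  Insertion codes are a
hard error rather than being renumbered, because motif spans are expressed
in author numbering and silent renumbering would corrupt them.  mmCIF and
multi-model template files are out of scope (multi-model files are read
only as RMSF ensembles).

## Restraint maps

Each restrained template position carries one of three weight categories —
low (1), medium (5), heavy (10) — and the pair weight is their product,
giving the spread {1, 5, 10, 25, 50, 100}.  Restraints live only on
motif × motif pairs; motif–linker and linker–linker pairs are unrestrained
(weight 0).  Whether such pairs should instead be down-weighted is an open
modelling question; zero was chosen as the conservative reading and is
trivially changed by editing the compiled weight matrix.

Motifs are inclusive author-numbered template spans.  Internal fixed-length
gap segments occupy sequence offsets inside the motif but contribute no
geometry targets (short loops carried along for spacing).  Sequence
constraints pin design positions to fixed residue identities.

The shipped `engsp` preset encodes the GH101 active-site scaffold: three
discontinuous motifs (603–705, 722–800, 807–893 in template numbering)
compiled onto a 290-residue design, with 23 sequence-constrained positions
of which six are fixed to the substrate-contacting identities
(Asp-658, His-661, His-694, Asn-696, Asn-764, Glu-796).  The remaining 17
constrained positions are placeholders (`null`): their identities are not
published, so the preset marks the positions and the user supplies the
residues.  Linker-length bounds and the gap segments are likewise editable
modelling choices; the only hard global constraint is the 290-residue
design length.

Placement sampling is exactly uniform over all feasible placements (native
order, non-overlap, linker bounds) via dynamic-programming counts over
linker-length compositions, not rejection sampling, so the distribution is
correct even for tightly constrained layouts.

## Hallucination objective and MCMC

The loss has two terms over predicted categorical distributions p(i,j,·):

* restrained: Σ_{ij∈mask} W(i,j)·CE(i,j) / Σ W, where CE is the
  cross-entropy against the one-hot template bin, averaged over the
  channels that carry a target (no-contact pairs: distance only).  The
  normalisation makes a uniform prediction score ln K independently of W,
  so weights trade pairs against each other instead of scaling the loss.
* free: −⟨KL(p ∥ background)⟩ over unrestrained pairs, channel-averaged.
  Minimising the total therefore maximises divergence from the
  random-sequence background — the "free hallucination" pressure toward
  confidently predicted structure in unrestrained regions.

Total = restrained + λ·free with λ = 1 by default; λ is configurable
because the mixing weight of the two terms is not a published quantity.
Whether the restrained cross-entropy should be summed or averaged over
channels is likewise unpublished; the per-pair channel mean used here keeps
the two terms on comparable scales.  An ε-floor of 1e−8 is applied to all
probabilities before logarithms.

MCMC: each step proposes a point mutation at a uniformly random
non-constrained position (uniform over the other 19 residues, or over the
consensus alphabet when one is active) with probability 0.9, else a shift
of one motif by δ ∈ {−3…−1, 1…3}.  A shift carries the motif's sequence
segment — including its sequence constraints — to the new offset;
infeasible shifts are auto-rejected.  Acceptance is standard Metropolis
(accept if ΔL ≤ 0, else with probability exp(−ΔL/T)) under a geometric
annealing schedule T_k = T₀·γᵏ with T₀ = 0.1, γ = 0.999.  The acceptance
rule and schedule are implementation choices (the published description
says only "MCMC optimization"); both are configurable.  Trajectories
default to 5000 steps — the short-trajectory / many-trajectories regime —
and are bit-reproducible per seed.  Because motif moves relocate restrained
design indices, the restraint spec is recompiled (and cached) per
placement; this is why the trajectory runner takes a compiler rather than
one fixed restraint spec.

### Surrogate oracle

Real structure-prediction networks are out of scope; the surrogate oracle
makes every stage executable and testable.  Given the fraction m of motif
design positions matching a reference sequence, it predicts for restrained
pairs the mixture m·onehot(target) + (1−m)·uniform, and for unrestrained
pairs the same mixture around a fixed pair-dependent bin.  Both loss terms
are therefore monotone in m, giving the MCMC a well-defined gradient toward
the reference — a deliberately idealised landscape.  Passing trajectories
under the surrogate demonstrates the correctness of the search machinery
(constraint handling, acceptance, bookkeeping), not that any real network
would be optimised equally well: the surrogate's landscape is unimodal and
noise-free, which real predictors are not.

## Sequence-space iteration

Clustering is greedy centroid clustering in input order at identity
threshold 0.6: deterministic, order-stable, and a true partition.  The best
cluster has the lowest mean loss (ties: larger cluster, then lower id).
Consensus constraints keep, per position, the residues at frequency ≥ 0.5,
falling back to all observed residues when nothing reaches the threshold,
so allowed sets are never empty.  Threshold and minimum frequency are
configuration values; the published pipeline states neither.

The 2D sequence-space embedding is PCA of one-hot encodings (L×20, no
per-column standardisation — the encoding is already on a uniform scale)
via mean-centred SVD.  Signs are fixed so each component's
largest-magnitude loading is positive, with near-ties (within 1e−6)
breaking to the lowest column index, which makes the embedding invariant to
input order.

## Redesign loop

Candidates are kept iff mean confidence > 75 and backbone Cα RMSD to the
reference model < 2 Å, both strict, matching the stated criteria; ranking
is by descending confidence with ties broken by ascending RMSD then input
order (a deterministic replacement for the published manual inspection).
Round 1 designs 232 sequences at sampling temperature 0.2; later rounds 100
per carried-forward parent; the top 2 kept candidates seed each next round.
RMSD is measured against the original seed model over all pairable Cα
atoms (a motif-only option exists; which atom set the published filter used
is not stated).  A round that keeps nothing halts the loop with a flagged
report.  Provenance (round, parent) forms a forest rooted at the seed.

The mock predictor scores a sequence by its identity to a hidden target
(confidence = 100·identity) and emits an idealized helical Cα trace
perturbed proportionally to (100 − confidence), so confidence and RMSD
co-vary and both filter branches are exercised.  The mock designer mutates
parents toward the target at rate 0.1 per position with a small
temperature-scaled noise rate, honouring fixed identities.  Seeded property
tests start the loop at 75% identity to the target — the regime where
round-1 candidates straddle the confidence filter, mirroring a hallucinated
seed design sitting just below the quality bar — and verify that the mean
kept-set confidence is non-decreasing over three rounds in ≥ 19/20 seeds.
This demonstrates the selection dynamics of the loop, not the behaviour of
real inverse-folding networks.

## Structural metrics

Superposition is least-squares Kabsch via SVD with the determinant
correction that excludes reflections.  Subset RMSD fits the transform on
one atom selection (e.g. backbone) and reports the RMSD over another
(e.g. catalytic side chains) without re-fitting.  The minimum side-chain
distance between two residues is over heavy atoms only and errors on
glycine.  RMSF superposes frames iteratively on the running mean structure
until the mean moves < 1e−6 Å, then reports per-atom root-mean-square
deviations from the mean.  This is plain iterative least squares rather
than a Bayesian (Theseus-style) maximum-likelihood superposition:
deterministic, dependency-free, and equivalent for the rigid/mobile
contrasts the package tests; it does not down-weight high-variance atoms,
so absolute RMSF values for very mobile loops can differ from a Bayesian
estimate.

## Thermal unfolding

Interfaces take °C (melt curves are recorded that way); thermodynamics are
computed in K with R = 8.314 J mol⁻¹ K⁻¹ and enthalpies in kJ/mol.

* MRE = θ·MW / (10·n·c·d) with θ in mdeg, c in g/L, d in cm.  The mean
  residue weight uses MW/n by default (MW/(n−1) is switchable).
* Two-state melt: K(T) = exp[−(ΔH/R)(1/T − 1/T_m)], signal
  (y_N + m_N T)(1−f_D) + (y_D + m_D T)f_D with f_D = K/(1+K), evaluated
  through the logistic function for overflow-free behaviour at extreme K.
  Fits are six-parameter nonlinear least squares; the heuristic
  initialisation puts T_m at the maximum |dy/dT| (finite differences),
  ΔH = 300 kJ/mol, and baselines from linear fits to the terminal 15% of
  the curve.  Standard errors come from the fit covariance.  A fit is
  demoted to non-converged when the optimizer fails, T_m leaves the data
  range, ΔH ≤ 0, or the fitted transition amplitude is under 5% of the
  signal range (no credible transition).
* Heat-capacity-corrected melt:
  ΔG(T) = ΔH(1 − T/T_m) − ΔC_p[(T_m − T) + T ln(T/T_m)], folded fraction
  f = expit(ΔG/RT), signal = y_N(T)·f + y_D·(1−f).  The published baseline
  parameterisation is not recoverable from the source material, so the
  package adopts a quadratic native baseline y_N = a₀ + a₁·ΔT² and a
  constant denatured baseline y_D = b₁, with ΔT = T − T_ref
  (T_ref = 298.15 K by default); this reconstruction is switchable by
  fixing parameters.  ΔC_p is weakly determined by a single curve and can
  be held fixed, which tightens the T_m standard error on noisy data.
* DSC excess heat capacity: C_p(T) = ΔH²/(RT²)·K/(1+K)², peaking at T_m
  (exactly, up to the slowly varying 1/T² factor) with integrated area ΔH.
* Zero-denaturant extrapolation: ordinary least squares of fitted T_m
  against [GuHCl]; intercept and its standard error are reported.

The shipped `DSC_PARAMS` table carries the published unfolding parameters
of the four characterised designs and the wild-type enzyme (residue count,
T_m, ΔH); the synthetic melt generator evaluates the chosen model on a °C
grid and adds i.i.d. Gaussian noise.  Round-trip tests (generate noiseless
→ refit from heuristic initialisation) recover every row's T_m and ΔH to
better than 0.1%.  What synthetic curves do not emulate: instrument drift,
correlated noise, aggregation-distorted (irreversible) transitions, and
non-two-state unfolding — so a passing round trip validates the fitting
machinery, not two-state behaviour of any real protein.

## Problem sizes

Tests run the pipeline at desk scale: a 36-residue toy template with three
motifs on a 42-residue design, coarse bin counts (12/8/8/4) for MCMC
property tests, 2000-step trajectories, mock redesign campaigns of 60/40
candidates over three rounds, and melt grids of 100–200 points.  These
sizes were chosen so the full suite exercises every code path, including
20-seed stochastic properties, in about a minute; all defaults in the
library itself remain at campaign scale (5000 steps, 232/100 sequences,
290-residue preset).

## Known limitations

* The surrogate oracle's landscape is unimodal; multi-modal search
  behaviour (cluster diversity across trajectories) is exercised only
  weakly at desk scale.
* Variable motif lengths during search, automatic active-site detection,
  and profile-HMM alignment of variable-length sequences are out of scope.
* The RMSF estimator is non-Bayesian (see above).
* Real-network adapters (structure predictors, inverse-folding designers)
  are interface stubs by design; nothing in the package downloads or runs
  network weights.
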