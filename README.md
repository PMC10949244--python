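# motifscaffold

Desk-scale tooling for *motif-scaffolding* protein design: carving a
functional site out of a large natural enzyme and hallucinating a small de
novo scaffold that presents it.  The motivating system is the active site
of a GH101 endo-α-*N*-acetylgalactosaminidase — a >1300-residue,
multi-domain glycoside hydrolase whose catalytic (β/α)₈ TIM-barrel-like
core can be recapitulated in a ~290-residue designed protein.

The package implements the complete computational loop of such a design
campaign, with every neural network behind a pluggable interface so the
whole pipeline runs deterministically on one CPU:

1. **Template geometry** (`template_geometry`) — parse a template PDB and
   derive binned inter-residue 6D geometry: Cβ–Cβ distance *d* and the
   orientation angles ω (Cαᵢ–Cβᵢ–Cβⱼ–Cαⱼ), θ (Nᵢ–Cαᵢ–Cβᵢ–Cβⱼ) and
   φ (Cαᵢ–Cβᵢ–Cβⱼ), on the trRosetta bin layout (36 × 0.5 Å distance bins
   over 2–20 Å + no-contact; 15° angle bins).
2. **Restraint maps** (`restraint_map`) — three-tier per-residue weights
   (low 1 / medium 5 / heavy 10) lifted multiplicatively to pair weights
   W(i,j) = wᵢ·wⱼ (heavy·heavy = 100, low·low = 1); discontinuous motifs
   with fixed internal gaps placed randomly but in native order on the
   design scaffold; sequence constraints on active-site positions.
3. **MCMC hallucination** (`hallucination`) — minimise
   L = Σ W·CE(target, predicted) / Σ W − λ·⟨KL(predicted ∥ background)⟩
   over sequences by Metropolis MCMC (point mutations and motif moves,
   geometric annealing, 5000-step default trajectories).  The predictor is
   an interface; a deterministic surrogate oracle ships for desk-scale runs.
4. **Sequence space** (`sequence_space`) — greedy identity clustering of
   hallucinated batches, best-cluster selection by mean loss, consensus
   alphabets constraining the next iteration, one-hot PCA campaign maps.
5. **Redesign loop** (`redesign`) — the iterative predict → inverse-fold →
   filter (pLDDT > 75, backbone RMSD < 2 Å, both strict) → top-2 selection
   loop (232 sequences at designer temperature 0.2 in round 1, 100 per
   parent after), with deterministic mock predictor/designer.
6. **Structural metrics** (`struct_metrics`) — Kabsch superposition
   (proper rotations only), subset RMSD after fitting on another atom set,
   minimum side-chain heavy-atom distances, per-residue RMSF of ensembles
   after iterative superposition on the mean structure.
7. **Thermal unfolding** (`thermofit`) — mean residue ellipticity
   MRE = θ·MW/(10·n·c·d); two-state van't Hoff melts
   y(T) = [(y_N+m_N T) + (y_D+m_D T)K]/(1+K), K = exp[−(ΔH/R)(1/T−1/T_m)];
   heat-capacity-corrected fits with
   ΔG(T) = ΔH(1−T/T_m) − ΔC_p[(T_m−T) + T ln(T/T_m)] and quadratic
   baseline correction; DSC excess-heat-capacity simulation; linear
   extrapolation of T_m to zero denaturant; a synthetic melt generator.

Out of scope by design: the networks themselves (trRosetta, OmegaFold,
ESMFold, ProteinMPNN weights and inference), MD simulation, and everything
wet-lab.  Interfaces are the seam where real adapters would plug in.

## Worked example

Generate the built-in toy template (an idealized mixed α/β chain with
author-numbering jumps mimicking motif spans carved from a parent protein),
hallucinate against the surrogate oracle, and fit a simulated melt curve:

```sh
$ motifscaffold fixtures --kind toy-template --seed 1 --out-dir fx
$ motifscaffold --verbose hallucinate --pdb fx/toy_template.pdb \
      --preset fx/toy_preset.json --steps 2000 --seed 1 --out-prefix out/run
best loss -1.8580, acceptance 0.62

$ head -2 out/run_best.fasta
>best seed=1 total=-1.858015
SKNNDGNQLWYTCLQQLVCQPFQYVFAYVITHCSTLEDSSYAQW
```

The loss combines the weighted restraint cross-entropy (0 when every
restrained pair's predicted geometry is one-hot on its template bin) with
the negated KL foldedness term (more negative as unrestrained regions
sharpen), so a total of −1.86 means the trajectory has both matched the
motif geometry and "folded" its linkers under the surrogate.  The run also
writes a per-step loss table (`out/run_loss.csv`) and a manifest with the
seed and config hash that make the trajectory bit-reproducible.

```sh
$ motifscaffold simulate-melt --tm 81.1 --dh 193 --out melt.csv
$ motifscaffold fit-melt --csv melt.csv --out fit.json
Tm = 81.1 C, dH = 193 kJ/mol (converged=True)
```

The six-parameter two-state fit recovers the generating melting temperature
(81.1 °C) and van't Hoff enthalpy (193 kJ/mol) of the round-trip exactly —
the same check the test suite runs for every shipped parameter set,
including the wild-type enzyme's much sharper transition (ΔH = 1120 kJ/mol).

A full campaign — batch hallucination → clustering → consensus-constrained
hallucination → mock redesign → metrics — runs end to end in seconds:

```sh
motifscaffold campaign --config config.json --seed 2 --out-dir camp
```

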