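"""MCMC sequence hallucination against a pluggable geometry predictor.

The objective combines two terms.  The *restrained* term is the
pair-weighted cross-entropy between the predictor's categorical geometry
distributions and the one-hot template targets, normalised by the total
pair weight — it drives recapitulation of the active-site geometry.  The
*free* term is the negated mean Kullback-Leibler divergence of unrestrained
pair distributions from a random-sequence background — minimising it
maximises divergence from background, i.e. pushes unrestrained regions
toward confidently predicted (folded) structure.

Each MCMC step proposes either a point mutation at a non-constrained
position or a shift of one motif (carrying its sequence segment, including
any sequence constraints, with it), and accepts by the Metropolis criterion
under a geometric annealing schedule.

Real structure-prediction networks are abstracted behind the
:class:`PredictorOracle` protocol; the shipping :class:`SurrogateOracle` is
a deterministic stand-in whose predictions sharpen as the designed motif
sequence approaches a reference, which makes full trajectories runnable and
testable on a laptop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .restraint_map import (
    MotifSpec,
    Placement,
    RestraintSpec,
    ScaffoldLayout,
    compile_restraints,
    place_motifs_random,
    shift_motif,
)
from .template_geometry import BinnedGeometry, BinningScheme

__all__ = [
    "AMINO_ACIDS",
    "DesignState",
    "PredictedDistributions",
    "LossBreakdown",
    "MCMCConfig",
    "PredictorOracle",
    "SurrogateOracle",
    "RestraintCompiler",
    "MCMCResult",
    "restrained_loss",
    "free_loss",
    "total_loss",
    "uniform_background",
    "propose",
    "metropolis",
    "run_mcmc",
    "surrogate_predict",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EPS = 1e-8  # floor on categorical probabilities before any logarithm

_CHANNELS = ("dist", "omega", "theta", "phi")


@dataclass
class PredictedDistributions:
    """Per-pair categorical distributions over the binning scheme.

    One (L, L, K_channel) array per channel; each pair's distribution is
    non-negative and sums to 1.
    """

    scheme: BinningScheme
    dist: np.ndarray
    omega: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def validate(self, atol: float = 1e-6) -> None:
        for name in _CHANNELS:
            p = self.channel(name)
            if np.any(p < 0):
                raise ValueError(f"negative probability in channel {name}")
            sums = p.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"channel {name} distributions do not sum to 1")


@dataclass
class LossBreakdown:
    restrained: float
    free: float
    lam: float

    @property
    def total(self) -> float:
        return self.restrained + self.lam * self.free


@dataclass
class DesignState:
    """An MCMC state: sequence, motif placement, and (optionally) its loss."""

    sequence: str
    placement: Placement
    loss: LossBreakdown | None = None


@dataclass
class MCMCConfig:
    """Trajectory controls.

    5000 steps is the campaign default (short trajectories, many of them);
    tests and examples use far fewer.  ``t0``/``t_decay`` define a geometric
    annealing schedule; ``p_mutation`` is the probability of a point
    mutation vs a motif shift; ``lam`` mixes the free term into the total.
    ``alphabet`` optionally restricts per-position mutation alphabets
    (e.g. from consensus constraints of an earlier design round).
    """

    steps: int = 5000
    t0: float = 0.1
    t_decay: float = 0.999
    p_mutation: float = 0.9
    lam: float = 1.0
    seed: int = 0
    max_shift: int = 3
    alphabet: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if not 0.0 <= self.p_mutation <= 1.0:
            raise ValueError("p_mutation must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    def temperature(self, step: int) -> float:
        return self.t0 * self.t_decay**step


class PredictorOracle(Protocol):
    """Contract for geometry predictors: deterministic given configuration."""

    def predict(self, sequence: str, spec: RestraintSpec) -> PredictedDistributions: ...


def _pair_ce(pred: PredictedDistributions, spec: RestraintSpec) -> np.ndarray:
    """Per-pair cross-entropy vs one-hot targets, averaged over the channels
    that carry a target (no-contact pairs: distance only)."""
    L = spec.length
    ce_sum = np.zeros((L, L))
    n_channels = np.zeros((L, L))
    for name in _CHANNELS:
        target = getattr(spec, name)
        has = target >= 0
        p = pred.channel(name)
        idx = np.clip(target, 0, p.shape[-1] - 1)
        picked = np.take_along_axis(p, idx[..., None], axis=-1)[..., 0]
        ce = -np.log(np.maximum(picked, EPS))
        ce_sum += np.where(has, ce, 0.0)
        n_channels += has
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_channels > 0, ce_sum / np.maximum(n_channels, 1), 0.0)
    return out


def restrained_loss(pred: PredictedDistributions, spec: RestraintSpec) -> float:
    """Weighted mean cross-entropy over restrained pairs.

    sum over restrained pairs of W(i,j) * CE(pair) / sum of W — the
    normalisation makes a uniform prediction score ln K regardless of the
    weight map, so weights trade pairs off against each other rather than
    scaling the loss.
    """
    if pred.scheme != spec.scheme:
        raise ValueError("prediction and restraint binning schemes differ")
    wsum = spec.W[spec.mask].sum()
    if wsum == 0:
        return 0.0
    ce = _pair_ce(pred, spec)
    return float((spec.W[spec.mask] * ce[spec.mask]).sum() / wsum)


def _pair_kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pf = np.maximum(p, EPS)
    qf = np.maximum(q, EPS)
    return np.sum(p * (np.log(pf) - np.log(qf)), axis=-1)


def free_loss(
    pred: PredictedDistributions,
    background: PredictedDistributions,
    spec: RestraintSpec,
) -> float:
    """Negated mean KL divergence of unrestrained pairs from background.

    Returned negated so that *minimising* the total loss *maximises* the
    divergence of unrestrained regions from the random-sequence background.
    Zero-probability background bins are handled by an epsilon floor.
    """
    if pred.scheme != background.scheme:
        raise ValueError("prediction and background binning schemes differ")
    L = spec.length
    off = ~spec.mask & ~np.eye(L, dtype=bool)
    if not off.any():
        return 0.0
    kl = np.zeros((L, L))
    for name in _CHANNELS:
        kl += _pair_kl(pred.channel(name), background.channel(name))
    kl /= len(_CHANNELS)
    return float(-kl[off].mean())


def total_loss(
    pred: PredictedDistributions,
    spec: RestraintSpec,
    background: PredictedDistributions,
    lam: float = 1.0,
) -> LossBreakdown:
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return LossBreakdown(
        restrained=restrained_loss(pred, spec),
        free=free_loss(pred, background, spec),
        lam=lam,
    )


def uniform_background(scheme: BinningScheme, length: int) -> PredictedDistributions:
    """Uniform categorical background over every channel (surrogate mode).

    Real-network adapters may supply a network-derived random-sequence
    background instead.
    """
    arrays = {}
    for name in _CHANNELS:
        k = scheme.n_bins(name)
        arrays[name] = np.full((length, length, k), 1.0 / k)
    return PredictedDistributions(scheme=scheme, **arrays)


def _mutable_positions(state: DesignState, spec: RestraintSpec) -> list[int]:
    return [i for i in range(len(state.sequence)) if i not in spec.fixed]


def propose(
    state: DesignState,
    spec: RestraintSpec,
    layout: ScaffoldLayout,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[DesignState | None, str]:
    """One MCMC proposal: point mutation or motif shift.

    Mutations pick a uniformly random non-constrained position and a
    uniformly random *different* residue (restricted by ``config.alphabet``
    if set).  Shifts move one motif by delta in {-3..-1, 1..3} together with
    its sequence segment; infeasible shifts return ``(None, "shift")`` for
    auto-rejection.  Identity constraints are never violated.
    """
    if rng.random() < config.p_mutation:
        mutable = _mutable_positions(state, spec)
        if not mutable:
            raise ValueError("all positions are sequence-constrained; cannot mutate")
        pos = int(rng.choice(mutable))
        allowed = config.alphabet.get(pos, AMINO_ACIDS) if config.alphabet else AMINO_ACIDS
        options = [a for a in allowed if a != state.sequence[pos]]
        if not options:
            return None, "mutation"
        aa = options[int(rng.integers(len(options)))]
        seq = state.sequence[:pos] + aa + state.sequence[pos + 1 :]
        return DesignState(sequence=seq, placement=dict(state.placement)), "mutation"

    motif = layout.motifs[int(rng.integers(len(layout.motifs)))]
    deltas = [d for d in range(-config.max_shift, config.max_shift + 1) if d != 0]
    delta = int(deltas[int(rng.integers(len(deltas)))])
    new_placement = shift_motif(state.placement, layout, motif.name, delta)
    if new_placement is None:
        return None, "shift"
    start = state.placement[motif.name]
    seq = list(state.sequence)
    segment = seq[start : start + motif.length]
    rest = seq[:start] + seq[start + motif.length :]
    new_start = new_placement[motif.name]
    seq = rest[:new_start] + segment + rest[new_start:]
    return DesignState(sequence="".join(seq), placement=new_placement), "shift"


def metropolis(delta_loss: float, temperature: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis acceptance: always accept downhill moves, accept
    uphill moves with probability exp(-dL/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_loss <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_loss / temperature))


@dataclass
class RestraintCompiler:
    """Recompiles the restraint spec whenever the placement changes.

    Motif-shift moves relocate the design indices of restrained pairs, so
    the compiled spec is placement-dependent; specs are cached per placement.
    """

    template: BinnedGeometry
    template_numbering: list[int]
    layout: ScaffoldLayout
    _cache: dict = field(default_factory=dict, repr=False)

    def compile(self, placement: Placement) -> RestraintSpec:
        key = tuple(sorted(placement.items()))
        if key not in self._cache:
            self._cache[key] = compile_restraints(
                placement,
                self.template,
                self.template_numbering,
                self.layout.motifs,
                self.layout.length,
            )
        return self._cache[key]


@dataclass
class MCMCResult:
    best: DesignState
    final: DesignState
    history: pd.DataFrame
    acceptance_rate: float


def _random_sequence(length: int, fixed: dict[int, str], rng: np.random.Generator,
                     alphabet: dict[int, str] | None = None) -> str:
    seq = []
    for i in range(length):
        if i in fixed:
            seq.append(fixed[i])
        else:
            pool = alphabet.get(i, AMINO_ACIDS) if alphabet else AMINO_ACIDS
            seq.append(pool[int(rng.integers(len(pool)))])
    return "".join(seq)


def run_mcmc(
    oracle: PredictorOracle,
    compiler: RestraintCompiler,
    config: MCMCConfig,
    background: PredictedDistributions | None = None,
) -> MCMCResult:
    """Run one hallucination trajectory; bit-reproducible per seed.

    Initialises with a uniformly random placement and a random sequence
    satisfying the identity constraints, then iterates
    propose / evaluate / Metropolis for ``config.steps`` steps, tracking the
    best state seen.  Oracle failures propagate annotated with the step.
    """
    rng = np.random.default_rng(config.seed)
    layout = compiler.layout
    placement = place_motifs_random(layout, rng)
    spec = compiler.compile(placement)
    if background is None:
        background = uniform_background(spec.scheme, layout.length)
    sequence = _random_sequence(layout.length, spec.fixed, rng, config.alphabet)
    state = DesignState(sequence=sequence, placement=placement)
    state.loss = total_loss(oracle.predict(state.sequence, spec), spec, background, config.lam)
    best = state

    records = []
    n_accept = 0
    for step in range(config.steps):
        candidate, kind = propose(state, spec, layout, config, rng)
        accepted = False
        if candidate is not None:
            cand_spec = compiler.compile(candidate.placement)
            try:
                pred = oracle.predict(candidate.sequence, cand_spec)
            except Exception as exc:  # annotate with the failing step
                raise RuntimeError(f"oracle failed at step {step}") from exc
            candidate.loss = total_loss(pred, cand_spec, background, config.lam)
            if metropolis(
                candidate.loss.total - state.loss.total, config.temperature(step), rng
            ):
                state = candidate
                spec = cand_spec
                accepted = True
                n_accept += 1
                if state.loss.total < best.loss.total:
                    best = state
        records.append(
            {
                "step": step,
                "move": kind,
                "accepted": accepted,
                "restrained": state.loss.restrained,
                "free": state.loss.free,
                "total": state.loss.total,
                "best_total": best.loss.total,
            }
        )
    history = pd.DataFrame(
        records,
        columns=["step", "move", "accepted", "restrained", "free", "total", "best_total"],
    )
    rate = n_accept / config.steps if config.steps else 0.0
    return MCMCResult(best=best, final=state, history=history, acceptance_rate=rate)


def surrogate_predict(
    sequence: str,
    spec: RestraintSpec,
    reference: dict[int, str],
) -> PredictedDistributions:
    """Deterministic surrogate predictor.

    ``reference`` maps template positions to reference residues.  Let m be
    the fraction of motif design positions whose residue matches the
    reference.  Restrained pairs get the mixture
    ``m * onehot(target) + (1 - m) * uniform``; unrestrained pairs get a
    one-hot on a fixed pair-dependent bin softened the same way, so both
    loss terms sharpen as the motif sequence approaches the reference.
    """
    scored = [
        (dpos, tpos) for dpos, tpos in spec.design_to_template.items() if tpos in reference
    ]
    if not scored:
        raise ValueError("reference defines no motif positions")
    matches = sum(1 for dpos, tpos in scored if sequence[dpos] == reference[tpos])
    m = matches / len(scored)

    L = spec.length
    arrays = {}
    for name in _CHANNELS:
        k = spec.scheme.n_bins(name)
        target = getattr(spec, name)
        p = np.full((L, L, k), (1.0 - m) / k)
        i, j = np.indices((L, L))
        free_bin = (i + j) % k
        bins = np.where(target >= 0, target, free_bin)
        np.put_along_axis(
            p, bins[..., None], p[..., 0:1] + m, axis=-1
        )
        arrays[name] = p
    return PredictedDistributions(scheme=spec.scheme, **arrays)


@dataclass
class SurrogateOracle:
    """PredictorOracle wrapper around :func:`surrogate_predict`."""

    reference: dict[int, str]

    def predict(self, sequence: str, spec: RestraintSpec) -> PredictedDistributions:
        return surrogate_predict(sequence, spec, self.reference)
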