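"""Weighted restraint maps over discontinuous motifs on a design scaffold.

Each template residue carried into the design belongs to one of three weight
categories — low (1), medium (5), heavy (10) — expressing how strongly its
pairwise geometry must be recapitulated.  The per-residue linear map is
lifted to a 2D pair-weight matrix multiplicatively: two heavy residues
interact with weight 10 x 10 = 100, two low ones with 1 x 1 = 1.

Motifs are contiguous author-numbered template spans, optionally containing
internal fixed-length gap segments (short loops that keep their sequence
offsets but carry no geometric restraints), and optionally carrying
sequence-constrained positions (active-site identities fixed to the wild
type).  Motifs are placed in their native order at random feasible offsets
within a design scaffold of length L; placements may move during MCMC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

from .template_geometry import BinnedGeometry, BinningScheme

__all__ = [
    "WeightCategory",
    "MotifSpec",
    "ScaffoldLayout",
    "Placement",
    "RestraintSpec",
    "pair_weight_map",
    "place_motifs_random",
    "count_placements",
    "compile_restraints",
    "shift_motif",
    "load_preset",
]


class WeightCategory(int, Enum):
    """Three-tier per-residue restraint weight: low 1, medium 5, heavy 10."""

    LOW = 1
    MEDIUM = 5
    HEAVY = 10

    @classmethod
    def from_label(cls, label: str) -> "WeightCategory":
        return {"low": cls.LOW, "medium": cls.MEDIUM, "heavy": cls.HEAVY}[label.lower()]


_VALID_WEIGHTS = {1, 5, 10}


@dataclass
class MotifSpec:
    """A discontinuous template motif mapped onto the design.

    ``span`` is an inclusive author-numbered range on the template.  ``gaps``
    are sub-ranges inside the span that stay as fixed-length unrestrained
    loops (they occupy sequence offsets but contribute no geometry targets).
    ``weights`` gives a category per restrained template position (default
    low).  ``fixed`` maps template positions to required residue identities;
    a value of None marks a constrained position whose identity the user
    must supply before a constrained run.
    """

    name: str
    span: tuple[int, int]
    gaps: list[tuple[int, int]] = field(default_factory=list)
    weights: dict[int, WeightCategory] = field(default_factory=dict)
    fixed: dict[int, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.span
        if hi < lo:
            raise ValueError(f"motif {self.name}: empty span {self.span}")
        for glo, ghi in self.gaps:
            if not (lo <= glo <= ghi <= hi):
                raise ValueError(f"motif {self.name}: gap ({glo},{ghi}) outside span")
        spans = sorted(self.gaps)
        for (_, a_hi), (b_lo, _) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise ValueError(f"motif {self.name}: overlapping gap segments")
        for pos in self.fixed:
            if not lo <= pos <= hi:
                raise ValueError(f"motif {self.name}: fixed position {pos} outside span")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1

    @property
    def template_positions(self) -> list[int]:
        """All template positions of the span, in order (gaps included)."""
        return list(range(self.span[0], self.span[1] + 1))

    @property
    def gap_positions(self) -> set[int]:
        out: set[int] = set()
        for glo, ghi in self.gaps:
            out.update(range(glo, ghi + 1))
        return out

    @property
    def restrained_positions(self) -> list[int]:
        gaps = self.gap_positions
        return [p for p in self.template_positions if p not in gaps]

    def weight_of(self, pos: int) -> WeightCategory:
        return self.weights.get(pos, WeightCategory.LOW)


@dataclass
class ScaffoldLayout:
    """Design length, ordered motifs, and linker-length bounds.

    ``linker_bounds`` has ``len(motifs)+1`` (min, max) entries: the
    N-terminal extension, the gaps between consecutive motifs, and the
    C-terminal extension.
    """

    length: int
    motifs: list[MotifSpec]
    linker_bounds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.linker_bounds) != len(self.motifs) + 1:
            raise ValueError("need len(motifs)+1 linker bounds")
        for lo, hi in self.linker_bounds:
            if lo < 0 or hi < lo:
                raise ValueError(f"bad linker bounds ({lo},{hi})")
        min_total = sum(m.length for m in self.motifs) + sum(lo for lo, _ in self.linker_bounds)
        if min_total > self.length:
            raise ValueError(
                f"minimal motif+linker length {min_total} exceeds design length {self.length}"
            )

    @property
    def motif_lengths(self) -> list[int]:
        return [m.length for m in self.motifs]

    @property
    def slack(self) -> int:
        return self.length - sum(self.motif_lengths)


Placement = dict[str, int]  # motif name -> 0-based start offset in the design


def pair_weight_map(per_residue_weights) -> np.ndarray:
    """Lift a linear weight map to the 2D pair-weight matrix W(i,j) = wi * wj."""
    w = np.array([int(x) for x in per_residue_weights], dtype=float)
    if not set(np.unique(w).astype(int)) <= _VALID_WEIGHTS:
        raise ValueError(f"per-residue weights must be in {_VALID_WEIGHTS}")
    return np.outer(w, w)


def _gap_counts(layout: ScaffoldLayout) -> np.ndarray:
    """DP table N[i, s] = number of ways to fill linker slots i..end with total s."""
    bounds = layout.linker_bounds
    slack = layout.slack
    k = len(bounds)
    N = np.zeros((k + 1, slack + 1), dtype=object)
    N[k, 0] = 1
    for i in range(k - 1, -1, -1):
        lo, hi = bounds[i]
        for s in range(slack + 1):
            total = 0
            for g in range(lo, min(hi, s) + 1):
                total += N[i + 1, s - g]
            N[i, s] = total
    return N


def count_placements(layout: ScaffoldLayout) -> int:
    """Number of feasible placements (order-preserving, within linker bounds)."""
    return int(_gap_counts(layout)[0, layout.slack])


def place_motifs_random(layout: ScaffoldLayout, rng: np.random.Generator | int) -> Placement:
    """Sample a placement uniformly over all feasible placements.

    Feasibility: motifs keep their native order, do not overlap, respect the
    linker-length bounds, and lie inside [0, L).  Sampling is exact via
    dynamic-programming counts over linker-length compositions.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    N = _gap_counts(layout)
    slack = layout.slack
    if N[0, slack] == 0:
        raise ValueError("infeasible layout: motifs cannot fit in the design length")
    placement: Placement = {}
    pos = 0
    remaining = slack
    for i, motif in enumerate(layout.motifs):
        lo, hi = layout.linker_bounds[i]
        choices = list(range(lo, min(hi, remaining) + 1))
        weights = np.array([float(N[i + 1, remaining - g]) for g in choices])
        total = weights.sum()
        g = choices[int(rng.choice(len(choices), p=weights / total))]
        pos += g
        placement[motif.name] = pos
        pos += motif.length
        remaining -= g
    return placement


def _check_placement(layout: ScaffoldLayout, placement: Placement) -> bool:
    pos = 0
    for i, motif in enumerate(layout.motifs):
        lo, hi = layout.linker_bounds[i]
        start = placement.get(motif.name)
        if start is None:
            return False
        gap = start - pos
        if not lo <= gap <= hi:
            return False
        pos = start + motif.length
    lo, hi = layout.linker_bounds[-1]
    return lo <= layout.length - pos <= hi


@dataclass
class RestraintSpec:
    """Compiled, design-indexed restraints for one placement.

    ``W`` is the symmetric pair-weight matrix with support exactly on
    restrained motif x motif pairs (``mask``); the four target arrays hold
    template bin indices copied to design indices (-1 off-support);
    ``fixed`` maps design positions to required identities;
    ``design_to_template`` maps every motif design position (gaps included)
    to its template author number.
    """

    length: int
    scheme: BinningScheme
    W: np.ndarray
    mask: np.ndarray
    dist: np.ndarray
    omega: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    fixed: dict[int, str]
    design_to_template: dict[int, int]

    @property
    def restrained_design_positions(self) -> np.ndarray:
        return np.where(self.mask.any(axis=1))[0]


def compile_restraints(
    placement: Placement,
    template: BinnedGeometry,
    template_numbering: list[int],
    motifs: list[MotifSpec],
    length: int,
) -> RestraintSpec:
    """Copy template pair targets onto design indices for one placement.

    Pair weights follow the multiplicative rule restricted to restrained
    motif positions; identity constraints are carried to design indices.
    Positions whose fixed identity is None (user-supplied placeholder) are
    omitted from the compiled constraint map.
    """
    t_index = {num: i for i, num in enumerate(template_numbering)}
    L = length
    design_to_template: dict[int, int] = {}
    restrained_design: list[int] = []
    restrained_template_rows: list[int] = []
    weights: list[int] = []
    fixed: dict[int, str] = {}

    for motif in motifs:
        if motif.name not in placement:
            raise ValueError(f"placement missing motif {motif.name!r}")
        start = placement[motif.name]
        if start < 0 or start + motif.length > L:
            raise ValueError(f"motif {motif.name!r} placed outside the design")
        gaps = motif.gap_positions
        for offset, tpos in enumerate(motif.template_positions):
            dpos = start + offset
            if dpos in design_to_template:
                raise ValueError("overlapping motifs in placement")
            design_to_template[dpos] = tpos
            if tpos in motif.fixed and motif.fixed[tpos] is not None:
                fixed[dpos] = motif.fixed[tpos]
            if tpos not in gaps:
                if tpos not in t_index:
                    raise ValueError(f"template position {tpos} not in template numbering")
                restrained_design.append(dpos)
                restrained_template_rows.append(t_index[tpos])
                weights.append(int(motif.weight_of(tpos)))

    W = np.zeros((L, L))
    mask = np.zeros((L, L), dtype=bool)
    dist = np.full((L, L), -1, dtype=int)
    omega = np.full((L, L), -1, dtype=int)
    theta = np.full((L, L), -1, dtype=int)
    phi = np.full((L, L), -1, dtype=int)

    di = np.array(restrained_design, dtype=int)
    ti = np.array(restrained_template_rows, dtype=int)
    wv = np.array(weights, dtype=float)
    if len(di) > 0:
        W[np.ix_(di, di)] = np.outer(wv, wv)
        mask[np.ix_(di, di)] = True
        np.fill_diagonal(mask, False)
        W[~mask] = 0.0
        dist[np.ix_(di, di)] = template.dist[np.ix_(ti, ti)]
        omega[np.ix_(di, di)] = template.omega[np.ix_(ti, ti)]
        theta[np.ix_(di, di)] = template.theta[np.ix_(ti, ti)]
        phi[np.ix_(di, di)] = template.phi[np.ix_(ti, ti)]

    return RestraintSpec(
        length=L,
        scheme=template.scheme,
        W=W,
        mask=mask,
        dist=dist,
        omega=omega,
        theta=theta,
        phi=phi,
        fixed=fixed,
        design_to_template=design_to_template,
    )


def shift_motif(
    placement: Placement,
    layout: ScaffoldLayout,
    motif_name: str,
    delta: int,
) -> Placement | None:
    """Shift one motif by ``delta`` residues; None if the move is infeasible.

    Infeasible shifts (overlap with a neighbouring motif, violation of
    linker bounds, or running off either scaffold end) signal rejection so
    the MCMC caller can auto-reject the proposal.
    """
    if motif_name not in {m.name for m in layout.motifs}:
        raise KeyError(f"unknown motif {motif_name!r}")
    candidate = dict(placement)
    candidate[motif_name] = placement[motif_name] + delta
    return candidate if _check_placement(layout, candidate) else None


def load_preset(source: str | Path) -> ScaffoldLayout:
    """Load a scaffold preset from a JSON file or a named built-in preset.

    Schema: ``{"length": int, "motifs": [{"name", "span": [lo, hi],
    "gaps": [[lo, hi], ...], "weights": {"medium": [...ranges...],
    "heavy": [...ranges...]}, "fixed": {"pos": "A" | null}}, ...],
    "linkers": [[min, max], ...]}``.  Weight ranges are inclusive
    ``[lo, hi]`` pairs or single positions.
    """
    path = Path(source)
    if path.suffix == ".json" and path.exists():
        data = json.loads(path.read_text())
    else:
        ref = resources.files("motifscaffold.presets").joinpath(f"{source}.json")
        data = json.loads(ref.read_text())

    def expand(items) -> list[int]:
        out: list[int] = []
        for item in items:
            if isinstance(item, list):
                out.extend(range(item[0], item[1] + 1))
            else:
                out.append(int(item))
        return out

    motifs = []
    for m in data["motifs"]:
        weights: dict[int, WeightCategory] = {}
        for label in ("medium", "heavy"):
            for pos in expand(m.get("weights", {}).get(label, [])):
                weights[pos] = WeightCategory.from_label(label)
        fixed = {int(k): v for k, v in m.get("fixed", {}).items()}
        motifs.append(
            MotifSpec(
                name=m["name"],
                span=tuple(m["span"]),
                gaps=[tuple(g) for g in m.get("gaps", [])],
                weights=weights,
                fixed=fixed,
            )
        )
    return ScaffoldLayout(
        length=data["length"],
        motifs=motifs,
        linker_bounds=[tuple(b) for b in data["linkers"]],
    )
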