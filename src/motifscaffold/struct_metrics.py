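"""Superposition and fluctuation metrics for design evaluation.

Kabsch least-squares superposition (proper rotations only) underlies every
RMSD reported by the package: whole-selection RMSD, subset RMSD after
fitting on a different atom set (e.g. side-chain RMSD of catalytic residues
after a backbone fit), and per-residue RMSF of coordinate ensembles after
iterative superposition onto the converged mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "CoordinateSet",
    "SuperpositionResult",
    "EnsembleStats",
    "kabsch_superpose",
    "kabsch_rmsd",
    "subset_rmsd",
    "min_sidechain_distance",
    "rmsf",
    "read_coordinate_set",
    "read_ensemble",
]

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class AtomRecord:
    residue: int
    res_name: str
    atom: str
    xyz: tuple[float, float, float]

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue, self.atom)

    @property
    def is_backbone(self) -> bool:
        return self.atom in _BACKBONE_NAMES

    @property
    def is_sidechain(self) -> bool:
        return not self.is_backbone


@dataclass
class CoordinateSet:
    """Ordered atom records with unique (residue, atom) keys."""

    atoms: list[AtomRecord]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, a in enumerate(self.atoms):
            if a.key in self._index:
                raise ValueError(f"duplicate atom {a.key}")
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates at {a.key}")
            self._index[a.key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def get(self, residue: int, atom: str) -> AtomRecord:
        try:
            return self.atoms[self._index[(residue, atom)]]
        except KeyError:
            raise KeyError(f"atom {atom!r} of residue {residue} not found") from None

    def select(self, selection) -> list[AtomRecord]:
        """Atoms matching a selection: 'CA', 'backbone', 'sidechain', an
        explicit list of (residue, atom) keys, or a predicate."""
        if selection == "CA":
            return [a for a in self.atoms if a.atom == "CA"]
        if selection == "backbone":
            return [a for a in self.atoms if a.is_backbone]
        if selection == "sidechain":
            return [a for a in self.atoms if a.is_sidechain]
        if callable(selection):
            return [a for a in self.atoms if selection(a)]
        out = []
        for key in selection:
            residue, atom = key
            if (residue, atom) not in self._index:
                raise KeyError(f"selection atom {atom!r} of residue {residue} not found")
            out.append(self.atoms[self._index[(residue, atom)]])
        return out

    def with_coords(self, coords: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(
            [
                AtomRecord(a.residue, a.res_name, a.atom, tuple(xyz))
                for a, xyz in zip(self.atoms, coords)
            ]
        )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # applied as x @ R.T + t
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _fit_kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    if np.linalg.matrix_rank(np.vstack([P, Q])) < 2:
        raise ValueError("degenerate (collinear) atom configuration")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])  # exclude reflections
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _paired_coords(mobile, target, pairing=None, selection="CA"):
    if isinstance(mobile, np.ndarray):
        return np.asarray(mobile, float), np.asarray(target, float)
    ma = mobile.select(selection)
    if pairing is None:
        ta = [target.get(a.residue, a.atom) for a in ma]
    else:
        ta = [target.get(pairing[a.residue], a.atom) for a in ma if a.residue in pairing]
        ma = [a for a in ma if a.residue in pairing]
    return np.array([a.xyz for a in ma]), np.array([a.xyz for a in ta])


def kabsch_superpose(mobile, target, pairing: dict[int, int] | None = None,
                     selection="CA") -> SuperpositionResult:
    """Optimal least-squares proper rotation + translation of mobile onto target.

    Accepts raw (n, 3) arrays (already paired) or two CoordinateSets with a
    selection and an optional residue-pairing map (mobile residue -> target
    residue; atoms paired by name).
    """
    m, t = _paired_coords(mobile, target, pairing, selection)
    return _fit_kabsch(m, t)


def kabsch_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    return kabsch_superpose(np.asarray(mobile, float), np.asarray(target, float)).rmsd


def subset_rmsd(
    a: CoordinateSet,
    b: CoordinateSet,
    selection,
    pairing: dict[int, int] | None = None,
    superpose_on="CA",
) -> tuple[float, int]:
    """RMSD over `selection` atoms after superposing on `superpose_on` atoms.

    The transform is fitted once on the superposition set and applied to the
    report set without re-fitting (e.g. backbone fit, side-chain report).
    Returns (rmsd, atom count reported).
    """
    fit = kabsch_superpose(a, b, pairing=pairing, selection=superpose_on)
    sa = a.select(selection)
    if pairing is not None:
        sa = [at for at in sa if at.residue in pairing]
    if not sa:
        raise ValueError("empty report selection")
    pa = np.array([at.xyz for at in sa])
    pb = np.array(
        [b.get(pairing[at.residue] if pairing else at.residue, at.atom).xyz for at in sa]
    )
    moved = fit.apply(pa)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return rmsd, len(sa)


def min_sidechain_distance(struct: CoordinateSet, res_a: int, res_b: int) -> float:
    """Minimum pairwise distance between two residues' side-chain heavy atoms."""
    a = [at for at in struct.atoms if at.residue == res_a and at.is_sidechain]
    b = [at for at in struct.atoms if at.residue == res_b and at.is_sidechain]
    for residue, atoms in ((res_a, a), (res_b, b)):
        if not atoms:
            raise ValueError(f"residue {residue} has no side-chain heavy atoms (glycine?)")
    pa = np.array([at.xyz for at in a])
    pb = np.array([at.xyz for at in b])
    return float(np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)))


@dataclass
class EnsembleStats:
    rmsf: np.ndarray  # per selected atom, A
    atoms: list[tuple[int, str]]
    n_frames: int
    mean_structure: np.ndarray


def rmsf(ensemble: list[CoordinateSet], selection="CA", tol: float = 1e-6,
         max_iter: int = 200) -> EnsembleStats:
    """Per-atom RMSF after iterative superposition onto the mean structure.

    Frames are superposed on the running mean; the mean is recomputed until
    it moves < tol (A).  RMSF_i = sqrt(mean_frames |x_i - xbar_i|^2).
    Rigid-body motion between frames is removed entirely, so a rigidly
    transformed ensemble has RMSF 0.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 frames")
    keys = [a.key for a in ensemble[0].select(selection)]
    frames = []
    for f, cs in enumerate(ensemble):
        sel = cs.select(selection)
        if [a.key for a in sel] != keys:
            raise ValueError(f"frame {f} atom keys differ from frame 0")
        frames.append(np.array([a.xyz for a in sel]))
    X = np.stack(frames)  # (F, n, 3)

    mean = X[0].copy()
    for _ in range(max_iter):
        aligned = np.empty_like(X)
        for f in range(X.shape[0]):
            fit = _fit_kabsch(X[f], mean)
            aligned[f] = fit.apply(X[f])
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        X = aligned
        if shift < tol:
            break
    per_atom = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return EnsembleStats(rmsf=per_atom, atoms=keys, n_frames=X.shape[0], mean_structure=mean)


def _chain_to_coordset(chain: gemmi.Chain) -> CoordinateSet:
    atoms = []
    for res in chain:
        if res.het_flag != "A":
            continue
        for atom in res:
            if atom.element == gemmi.Element("H"):
                continue
            atoms.append(
                AtomRecord(
                    residue=res.seqid.num,
                    res_name=res.name,
                    atom=atom.name,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
            )
    return CoordinateSet(atoms)


def read_coordinate_set(pdb_text: str, chain_id: str) -> CoordinateSet:
    """All heavy atoms of one chain from PDB text (first model)."""
    structure = gemmi.read_pdb_string(pdb_text)
    chain = structure[0].find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")
    return _chain_to_coordset(chain)


def read_ensemble(pdb_text: str, chain_id: str) -> list[CoordinateSet]:
    """One CoordinateSet per MODEL record of a multi-model PDB."""
    structure = gemmi.read_pdb_string(pdb_text)
    out = []
    for model in structure:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise ValueError(f"chain {chain_id!r} missing in model {model.name}")
        out.append(_chain_to_coordset(chain))
    if not out:
        raise ValueError("no models found")
    return out
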