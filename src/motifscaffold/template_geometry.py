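"""Template structures and binned inter-residue 6D geometry.

A design template (here the catalytic domain of a GH101
endo-alpha-N-acetylgalactosaminidase) is reduced to pairwise geometry in the
trRosetta output space: a Cbeta--Cbeta distance ``d`` and three orientation
angles per ordered residue pair — the ``omega`` dihedral
(CAi-CBi-CBj-CAj, symmetric), the ``theta`` dihedral (Ni-CAi-CBi-CBj,
asymmetric) and the ``phi`` planar angle (CAi-CBi-CBj, asymmetric).
Glycine, lacking a real Cbeta, gets an ideal virtual one.

Continuous maps are quantised on a declared :class:`BinningScheme`; pairs
beyond the distance cutoff fall in a dedicated no-contact bin and carry no
angle information.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "ChainStructure",
    "GeometryMaps",
    "BinningScheme",
    "BinnedGeometry",
    "parse_structure",
    "virtual_cbeta",
    "compute_6d",
    "bin_geometry",
    "save_binned",
    "load_binned",
]

# Ideal virtual-Cbeta internal coordinates (tetrahedral construction):
# |CA-CB| = 1.522 A, angle N-CA-CB = 110.4 deg, dihedral C-N-CA-CB = -122.55 deg.
CB_BOND_LENGTH = 1.522
CB_ANGLE_DEG = 110.4
CB_DIHEDRAL_DEG = -122.55

_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue: author number, 1-letter type, named heavy-atom coordinates."""

    number: int
    aa: str
    backbone: dict[str, np.ndarray]
    sidechain: dict[str, np.ndarray] = field(default_factory=dict)

    def atom(self, name: str) -> np.ndarray:
        if name in self.backbone:
            return self.backbone[name]
        return self.sidechain[name]

    @property
    def has_cb(self) -> bool:
        return "CB" in self.sidechain

    def cbeta(self) -> np.ndarray:
        """Real Cbeta if present, ideal virtual Cbeta otherwise (glycine)."""
        if self.has_cb:
            return self.sidechain["CB"]
        return virtual_cbeta(self.backbone["N"], self.backbone["CA"], self.backbone["C"])


@dataclass
class ChainStructure:
    """Ordered residues of one chain with strictly increasing author numbers."""

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(f"residue numbers not strictly increasing in chain {self.chain_id}")
        for r in self.residues:
            for name in ("N", "CA", "C"):
                if name not in r.backbone:
                    raise ValueError(f"residue {r.number} ({r.aa}) lacks backbone atom {name}")
            for xyz in list(r.backbone.values()) + list(r.sidechain.values()):
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinates in residue {r.number}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def numbering(self) -> list[int]:
        return [r.number for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


def parse_structure(pdb_text: str, chain_id: str) -> ChainStructure:
    """Parse ATOM records of one chain from PDB text.

    HETATM records are ignored.  Alternate locations are resolved to the
    highest-occupancy conformer (first listed on ties).  Insertion codes are
    rejected: silently renumbering them would corrupt author-numbered motif
    spans.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models in PDB text")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")

    residues: list[Residue] = []
    for res in chain:
        if res.het_flag != "A":  # HETATM (waters, ligands) ignored
            continue
        if res.seqid.icode not in ("", " ", "\x00"):
            raise ValueError(
                f"residue {res.seqid.num}{res.seqid.icode.strip()} has an insertion code; "
                "insertion codes are unsupported — renumber the chain first"
            )
        # altloc resolution: per atom name keep highest occupancy, first listed on tie
        best: dict[str, gemmi.Atom] = {}
        order: list[str] = []
        for atom in res:
            name = atom.name
            if name not in best:
                best[name] = atom
                order.append(name)
            elif atom.occ > best[name].occ:
                best[name] = atom
        backbone: dict[str, np.ndarray] = {}
        sidechain: dict[str, np.ndarray] = {}
        for name in order:
            atom = best[name]
            xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            if atom.element == gemmi.Element("H"):
                continue
            if name in _BACKBONE:
                backbone[name] = xyz
            else:
                sidechain[name] = xyz
        info = gemmi.find_tabulated_residue(res.name)
        aa = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
        residues.append(Residue(number=res.seqid.num, aa=aa, backbone=backbone, sidechain=sidechain))
    if not residues:
        raise ValueError(f"chain {chain_id!r} has no ATOM residues")
    return ChainStructure(chain_id=chain_id, residues=residues)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, length: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom d with |c-d|=length, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=dihedral (IUPAC sign convention)."""
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-9:
        raise ValueError("degenerate geometry: coincident points")
    bc = bc / nbc
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("collinear reference points")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * math.cos(angle),
            length * math.sin(angle) * math.cos(dihedral),
            length * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cbeta position from the backbone N, CA, C of one residue.

    Tetrahedral construction with the documented constants
    (1.522 A, 110.4 deg, -122.55 deg).  Raises on collinear input.
    """
    return _place_atom(
        np.asarray(c, float),
        np.asarray(n, float),
        np.asarray(ca, float),
        CB_BOND_LENGTH,
        math.radians(CB_ANGLE_DEG),
        math.radians(CB_DIHEDRAL_DEG),
    )


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral in (-pi, pi]; broadcasts over leading axes."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.arctan2(y, x)


def _planar_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    u = p0 - p1
    v = p2 - p1
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


@dataclass
class GeometryMaps:
    """Continuous pairwise 6D geometry.

    ``d`` symmetric distances (A); ``omega`` symmetric dihedral; ``theta``
    asymmetric dihedral; ``phi`` asymmetric planar angle (radians).
    """

    d: np.ndarray
    omega: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return self.d.shape[0]


def compute_6d(structure: ChainStructure) -> GeometryMaps:
    """Pairwise Cbeta distances and orientation angles for a chain.

    ``d(i,j) = |CBi - CBj|`` (virtual Cbeta for glycine);
    ``omega(i,j) = dihedral(CAi, CBi, CBj, CAj)``;
    ``theta(i,j) = dihedral(Ni, CAi, CBi, CBj)``;
    ``phi(i,j) = angle(CAi, CBi, CBj)``.
    Diagonal entries are zero / undefined-by-convention zero.
    """
    if len(structure) < 2:
        raise ValueError("need at least 2 residues")
    n = np.stack([r.backbone["N"] for r in structure.residues])
    ca = np.stack([r.backbone["CA"] for r in structure.residues])
    cb = np.stack([r.cbeta() for r in structure.residues])

    diff = cb[:, None, :] - cb[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))

    L = len(structure)
    ca_i = np.broadcast_to(ca[:, None, :], (L, L, 3))
    ca_j = np.broadcast_to(ca[None, :, :], (L, L, 3))
    cb_i = np.broadcast_to(cb[:, None, :], (L, L, 3))
    cb_j = np.broadcast_to(cb[None, :, :], (L, L, 3))
    n_i = np.broadcast_to(n[:, None, :], (L, L, 3))

    with np.errstate(invalid="ignore", divide="ignore"):
        omega = _dihedral(ca_i, cb_i, cb_j, ca_j)
        theta = _dihedral(n_i, ca_i, cb_i, cb_j)
        phi = _planar_angle(ca_i, cb_i, cb_j)
    for m in (omega, theta, phi):
        np.fill_diagonal(m, 0.0)
        np.nan_to_num(m, copy=False)
    np.fill_diagonal(d, 0.0)
    return GeometryMaps(d=d, omega=omega, theta=theta, phi=phi)


@dataclass(frozen=True)
class BinningScheme:
    """Bin layout for the four geometry channels (trRosetta convention).

    36 distance bins of 0.5 A over 2-20 A plus one trailing no-contact bin;
    24 omega/theta bins and 12 phi bins of 15 deg each.  Bins are
    right-open: a value exactly on an interior edge belongs to the bin that
    the edge lower-bounds (d = 3.0 A lands in bin 2, covering [3.0, 3.5)).
    """

    d_min: float = 2.0
    d_max: float = 20.0
    n_dist_bins: int = 36
    n_omega_bins: int = 24
    n_theta_bins: int = 24
    n_phi_bins: int = 12

    @property
    def dist_edges(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.n_dist_bins + 1)

    @property
    def no_contact_bin(self) -> int:
        return self.n_dist_bins  # trailing bin

    @property
    def n_dist_total(self) -> int:
        return self.n_dist_bins + 1

    @property
    def omega_edges(self) -> np.ndarray:
        return np.linspace(-math.pi, math.pi, self.n_omega_bins + 1)

    @property
    def theta_edges(self) -> np.ndarray:
        return np.linspace(-math.pi, math.pi, self.n_theta_bins + 1)

    @property
    def phi_edges(self) -> np.ndarray:
        return np.linspace(0.0, math.pi, self.n_phi_bins + 1)

    def n_bins(self, channel: str) -> int:
        return {
            "dist": self.n_dist_total,
            "omega": self.n_omega_bins,
            "theta": self.n_theta_bins,
            "phi": self.n_phi_bins,
        }[channel]

    def to_dict(self) -> dict:
        return {
            "d_min": self.d_min,
            "d_max": self.d_max,
            "n_dist_bins": self.n_dist_bins,
            "n_omega_bins": self.n_omega_bins,
            "n_theta_bins": self.n_theta_bins,
            "n_phi_bins": self.n_phi_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(**d)


@dataclass
class BinnedGeometry:
    """Per-pair bin indices for each channel.

    Angle channels hold -1 where no angle bin applies (no-contact pairs and
    the diagonal).  Exactly one distance bin per pair (binning is total).
    """

    scheme: BinningScheme
    dist: np.ndarray  # int, (L, L)
    omega: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return self.dist.shape[0]


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Right-open bin index (on-edge values start the next bin); clipped so
    out-of-range values join the terminal bins."""
    idx = np.digitize(values, edges) - 1
    return np.clip(idx, 0, len(edges) - 2)


def bin_geometry(maps: GeometryMaps, scheme: BinningScheme | None = None) -> BinnedGeometry:
    """Quantise continuous geometry maps on a binning scheme.

    Pairs with ``d`` above the cutoff (and the diagonal) land in the
    no-contact distance bin and carry no angle bins (-1).
    """
    scheme = scheme or BinningScheme()
    if not np.all(np.diff(scheme.dist_edges) > 0):
        raise ValueError("binning scheme edges must be strictly increasing")
    L = len(maps)
    dist = _digitize(maps.d, scheme.dist_edges)
    no_contact = maps.d > scheme.d_max
    np.fill_diagonal(no_contact, True)
    dist[no_contact] = scheme.no_contact_bin

    omega = _digitize(maps.omega, scheme.omega_edges)
    theta = _digitize(maps.theta, scheme.theta_edges)
    phi = _digitize(maps.phi, scheme.phi_edges)
    for m in (omega, theta, phi):
        m[no_contact] = -1
    return BinnedGeometry(scheme=scheme, dist=dist, omega=omega, theta=theta, phi=phi)


def save_binned(binned: BinnedGeometry, path: str | Path, numbering: list[int] | None = None) -> None:
    """Write binned geometry as an .npz array container with a JSON sidecar
    describing the binning scheme (and optional author numbering)."""
    path = Path(path)
    np.savez(
        path,
        dist=binned.dist,
        omega=binned.omega,
        theta=binned.theta,
        phi=binned.phi,
    )
    sidecar = {"scheme": binned.scheme.to_dict()}
    if numbering is not None:
        sidecar["numbering"] = list(numbering)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_binned(path: str | Path) -> tuple[BinnedGeometry, list[int] | None]:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    binned = BinnedGeometry(
        scheme=BinningScheme.from_dict(sidecar["scheme"]),
        dist=data["dist"],
        omega=data["omega"],
        theta=data["theta"],
        phi=data["phi"],
    )
    return binned, sidecar.get("numbering")
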