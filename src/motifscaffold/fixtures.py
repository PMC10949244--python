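"""Synthetic study inputs: toy templates, sequence families, melt curves,
coordinate ensembles.

Everything a desk-scale campaign needs is generated programmatically — an
idealized mixed alpha/beta template built from internal coordinates (with
author-numbering jumps mimicking discontinuous motif spans), two controlled
mutation families of sequences, melt curves simulated from the published
DSC parameter sets, and a multi-model coordinate ensemble with one mobile
loop.  No binary data ships with the package.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .hallucination import AMINO_ACIDS
from .template_geometry import _place_atom, virtual_cbeta
from .thermofit import DSC_PARAMS, TwoStateParams, simulate_melt

__all__ = [
    "build_backbone",
    "toy_template_pdb",
    "toy_template_segments",
    "sequence_families",
    "melt_curves",
    "ensemble_pdb",
    "generate_fixtures",
]

# ideal backbone internal coordinates (A / deg)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX = (-57.0, -47.0)
STRAND = (-139.0, 135.0)


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry backbone (N, CA, C, O per residue) from (phi, psi) in
    degrees, via sequential internal-coordinate (NeRF) placement with
    trans peptide bonds."""
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_N_CA, 0.0, 0.0])
    c = _place_atom(
        np.array([0.0, 1.0, 0.0]), n, ca, _CA_C, math.radians(_ANG_N_CA_C), math.radians(0.0)
    )
    residues.append({"N": n, "CA": ca, "C": c})
    for i in range(1, n_res):
        psi_prev = math.radians(phi_psi[i - 1][1])
        phi = math.radians(phi_psi[i][0])
        n_next = _place_atom(n, ca, c, _C_N, math.radians(_ANG_CA_C_N), psi_prev)
        ca_next = _place_atom(ca, c, n_next, _N_CA, math.radians(_ANG_C_N_CA), math.pi)
        c_next = _place_atom(c, n_next, ca_next, _CA_C, math.radians(_ANG_N_CA_C), phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
        n, ca, c = n_next, ca_next, c_next
    # carbonyl oxygens: anti to the next N (or to psi=180 for the last residue)
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            ref = residues[i + 1]["N"]
            o = _place_atom(
                res["N"], res["CA"], res["C"], _C_O, math.radians(_ANG_CA_C_O), math.pi
                + _signed_dihedral(res["N"], res["CA"], res["C"], ref)
            )
        else:
            o = _place_atom(
                res["N"], res["CA"], res["C"], _C_O, math.radians(_ANG_CA_C_O), math.pi
            )
        res["O"] = o
    return residues


def _signed_dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w))


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _atom_line(serial, name, res3, chain, resnum, xyz, occ=1.0, altloc=" ", element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{res3:<3} {chain}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


def write_pdb(
    residues: list[dict[str, np.ndarray]],
    sequence: str,
    numbering: list[int],
    chain: str = "A",
) -> str:
    """Render backbone residues (plus virtual CB on non-glycine) as PDB text."""
    lines = []
    serial = 1
    for res, aa, num in zip(residues, sequence, numbering):
        res3 = _AA3.get(aa, "ALA")
        atom_names = ["N", "CA", "C", "O"] if "O" in res else ["N", "CA", "C"]
        for name in atom_names:
            lines.append(_atom_line(serial, name, res3, chain, num, res[name]))
            serial += 1
        if aa != "G":
            cb = res.get("CB")
            if cb is None:
                cb = virtual_cbeta(res["N"], res["CA"], res["C"])
            lines.append(_atom_line(serial, "CB", res3, chain, num, cb, element="C"))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def toy_template_segments() -> list[tuple[int, int, tuple[float, float]]]:
    """Author-numbered segments of the toy template: (start, end, phi/psi).

    Numbering jumps between segments mimic discontinuous motif spans carved
    from a larger parent protein.
    """
    return [(10, 21, HELIX), (40, 49, STRAND), (60, 73, HELIX)]


def toy_template_pdb(seed: int = 0) -> tuple[str, str, list[int]]:
    """Idealized mixed alpha/beta template as (pdb_text, sequence, numbering)."""
    rng = np.random.default_rng(seed)
    phi_psi: list[tuple[float, float]] = []
    numbering: list[int] = []
    for start, end, (phi, psi) in toy_template_segments():
        for num in range(start, end + 1):
            jitter = rng.normal(0.0, 2.0, 2)  # small torsion jitter, keeps it protein-like
            phi_psi.append((phi + jitter[0], psi + jitter[1]))
            numbering.append(num)
    residues = build_backbone(phi_psi)
    seq = "".join(
        AMINO_ACIDS[int(rng.integers(20))] for _ in numbering
    )
    # one glycine guaranteed, to exercise virtual-CB handling
    seq = seq[:5] + "G" + seq[6:]
    return write_pdb(residues, seq, numbering), seq, numbering


def sequence_families(
    n_per_family: int = 10,
    length: int = 60,
    mutation_rate: float = 0.08,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Two controlled mutation families from two unrelated seed sequences.

    Within-family identity is about 1 - 2*rate (>= 0.8 at the default);
    between-family identity is the random-background 1/20.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        parent = "".join(AMINO_ACIDS[int(k)] for k in rng.integers(20, size=length))
        family = [parent]
        for _ in range(n_per_family - 1):
            seq = [
                AMINO_ACIDS[int(rng.integers(20))] if rng.random() < mutation_rate else aa
                for aa in parent
            ]
            family.append("".join(seq))
        out.append(family)
    return out[0], out[1]


def melt_curves(out_dir: str | Path, seed: int = 0, noise_sd: float = 0.005) -> list[Path]:
    """Simulated melt-curve CSVs for every published DSC parameter row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for name, (_, tm_c, dh) in DSC_PARAMS.items():
        grid = np.arange(20.0, min(tm_c + 15.0, 110.0) + 0.25, 0.5)
        params = TwoStateParams.from_celsius(tm_c, dh)
        curve = simulate_melt(params, grid, noise_sd=noise_sd, rng=rng)
        path = out_dir / f"melt_{name}.csv"
        curve.to_csv(path)
        paths.append(path)
    return paths


def ensemble_pdb(n_frames: int = 8, seed: int = 0, loop_amplitude: float = 2.0) -> str:
    """Multi-MODEL PDB of the toy template with one mobile loop residue.

    Frames differ by a random rigid transform (removed by superposition)
    plus a +-loop_amplitude displacement of one residue along x.
    """
    from scipy.spatial.transform import Rotation

    pdb, seq, numbering = toy_template_pdb(seed)
    base = []
    for line in pdb.splitlines():
        if line.startswith("ATOM"):
            base.append(line)
    coords = np.array(
        [[float(line[30:38]), float(line[38:46]), float(line[46:54])] for line in base]
    )
    mobile_res = numbering[len(numbering) // 2]
    mobile_idx = [i for i, line in enumerate(base) if int(line[22:26]) == mobile_res]

    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        x = coords.copy()
        x[mobile_idx] += np.array([loop_amplitude * (1 if f % 2 == 0 else -1), 0.0, 0.0])
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(0.0, 5.0, 3)
        x = x @ rot.T + shift
        lines = [f"MODEL     {f + 1:>4}"]
        for line, xyz in zip(base, x):
            lines.append(line[:30] + f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}" + line[54:])
        lines.append("ENDMDL")
        frames.append("\n".join(lines))
    return "\n".join(frames) + "\nEND\n"


def toy_preset(sequence: str, numbering: list[int]) -> dict:
    """Scaffold preset JSON matching the toy template's segments.

    Motifs cover the three author-numbered segments; the second position of
    each motif is heavy-weighted and identity-constrained to the template.
    """
    aa_of = dict(zip(numbering, sequence))
    segments = toy_template_segments()
    motifs = []
    for i, (start, end, _) in enumerate(segments):
        motifs.append(
            {
                "name": f"m{i + 1}",
                "span": [start, end],
                "weights": {"heavy": [start + 1, start + 2]},
                "fixed": {str(start + 1): aa_of[start + 1]},
            }
        )
    total = sum(end - start + 1 for start, end, _ in segments)
    linkers = [[0, 4]] + [[1, 4]] * (len(segments) - 1) + [[0, 4]]
    return {"length": total + 8, "linkers": linkers, "motifs": motifs}


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write one fixture family to disk; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "toy-template":
        pdb, seq, numbering = toy_template_pdb(seed)
        path = out_dir / "toy_template.pdb"
        path.write_text(pdb)
        fasta = out_dir / "toy_template.fasta"
        fasta.write_text(f">toy_template\n{seq}\n")
        preset = out_dir / "toy_preset.json"
        preset.write_text(json.dumps(toy_preset(seq, numbering), indent=1))
        return [path, fasta, preset]
    if kind == "sequence-families":
        fam_a, fam_b = sequence_families(seed=seed)
        path = out_dir / "families.fasta"
        with path.open("w") as fh:
            for label, family in (("a", fam_a), ("b", fam_b)):
                for i, seq in enumerate(family):
                    fh.write(f">family_{label}_{i}\n{seq}\n")
        return [path]
    if kind == "melt-curves":
        return melt_curves(out_dir, seed=seed)
    if kind == "ensemble":
        path = out_dir / "ensemble.pdb"
        path.write_text(ensemble_pdb(seed=seed))
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r}")
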