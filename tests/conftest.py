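"""Shared fixtures: toy trajectories and a minimal multi-model PDB writer."""

from __future__ import annotations

import numpy as np
import pytest

from bindcalor.loop_dynamics import Atom, TrajectoryCoords


def to_pdb_text(traj: TrajectoryCoords) -> str:
    """Serialize TrajectoryCoords as a multi-model PDB (test-side writer,
    independent of the package's reader)."""
    lines = []
    for m in range(traj.n_frames):
        lines.append(f"MODEL     {m + 1:>4}")
        for i, atom in enumerate(traj.atoms):
            x, y, z = traj.frames[m, i]
            name = atom.atom_name if len(atom.atom_name) == 4 else f" {atom.atom_name:<3}"
            lines.append(
                f"ATOM  {i + 1:>5} {name:<4} ALA A{atom.residue_id:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{atom.atom_name[0]}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_protein_traj(
    n_residues: int = 6, n_frames: int = 3, seed: int = 0, dt: float = 1.0,
    first_resid: int = 1,
) -> TrajectoryCoords:
    """A toy 'protein': N/CA/C/O per residue at random but frame-constant
    positions (callers perturb frames as needed)."""
    rng = np.random.default_rng(seed)
    atoms = []
    coords = []
    for r in range(n_residues):
        resid = first_resid + r
        base = np.array([3.8 * r, 0.0, 0.0])
        for name, offset in (
            ("N", [0.0, 0.0, 0.0]),
            ("CA", [1.2, 0.8, 0.3]),
            ("C", [2.4, 0.2, -0.2]),
            ("O", [2.6, -1.0, 0.1]),
        ):
            atoms.append(Atom(atom_id=len(atoms), residue_id=resid, atom_name=name))
            coords.append(base + np.asarray(offset) + rng.normal(0, 0.05, 3))
    frame = np.asarray(coords)
    frames = np.repeat(frame[None, :, :], n_frames, axis=0)
    return TrajectoryCoords(atoms=tuple(atoms), frames=frames, dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_traj():
    return make_protein_traj()
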