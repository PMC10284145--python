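"""Trajectory geometry and loop-state assignment.

Superposition is least-squares (Kabsch, proper rotation enforced); dihedrals
follow the IUPAC sign convention; per-frame ZA1/ZA2 labels come from the two
hinge dihedrals with a dwell-time filter to suppress flicker.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

ZA1 = "ZA1"
ZA2 = "ZA2"
UNASSIGNED = "UNASSIGNED"

#: ZA loop span and hinge residues (author numbering)
ZA_LOOP_RESIDUES = range(76, 107)
PSI_HINGE_RESID = 88
PHI_HINGE_RESID = 96

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class Atom(NamedTuple):
    atom_id: int
    residue_id: int
    atom_name: str


@dataclass(frozen=True)
class TrajectoryCoords:
    """Coordinates (Å) for a fixed atom roster over frames."""

    atoms: tuple[Atom, ...]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float = 1.0  # ps

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != len(self.atoms):
            raise ValueError("atom roster does not match coordinate width")
        if not np.all(np.isfinite(frames)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def select(self, predicate: Callable[[Atom], bool]) -> np.ndarray:
        """Indices of atoms matching a predicate."""
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)


@dataclass(frozen=True)
class DihedralSeries:
    """Per-frame signed dihedral (degrees in (-180, 180])."""

    angles: np.ndarray
    definition: str
    dt: float = 1.0

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if np.any((angles <= -180.0) | (angles > 180.0)):
            raise ValueError("angles must be wrapped into (-180, 180]")

    def __len__(self):
        return self.angles.size


@dataclass(frozen=True)
class StateTrace:
    """Per-frame loop-state labels."""

    labels: np.ndarray  # of {ZA1, ZA2, UNASSIGNED}
    dt: float = 1.0

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        bad = set(labels) - {ZA1, ZA2, UNASSIGNED}
        if bad:
            raise ValueError(f"unknown state labels: {bad}")
        object.__setattr__(self, "labels", labels)

    def __len__(self):
        return self.labels.size


# --- selections -------------------------------------------------------------

def is_backbone(atom: Atom) -> bool:
    return atom.atom_name in BACKBONE_ATOMS


def parse_selection(expr: str) -> Callable[[Atom], bool]:
    """Parse a tiny selection grammar: "backbone", "resid A-B",
    "resid A-B and backbone", "all"."""
    expr = expr.strip().lower()
    if expr == "all":
        return lambda a: True
    clauses = [c.strip() for c in expr.split(" and ")]
    preds = []
    for clause in clauses:
        if clause == "backbone":
            preds.append(is_backbone)
        elif clause.startswith("resid "):
            lo, _, hi = clause[6:].strip().partition("-")
            lo_i, hi_i = int(lo), int(hi or lo)
            preds.append(lambda a, lo_i=lo_i, hi_i=hi_i: lo_i <= a.residue_id <= hi_i)
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return lambda a: all(p(a) for p in preds)


# --- multi-model PDB --------------------------------------------------------

def read_multimodel_pdb(source, dt: float = 1.0) -> TrajectoryCoords:
    """Read a multi-model PDB (MODEL/ENDMDL records) into TrajectoryCoords.

    Author residue numbers are kept as-is. Delegates parsing to biotite.
    """
    from biotite.structure.io.pdb import PDBFile

    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    pdb = PDBFile.read(source)
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    atoms = tuple(
        Atom(atom_id=i, residue_id=int(stack.res_id[i]), atom_name=str(stack.atom_name[i]))
        for i in range(stack.array_length())
    )
    return TrajectoryCoords(atoms=atoms, frames=coords, dt=dt)


# --- superposition ----------------------------------------------------------

def kabsch_rmsd(
    reference: np.ndarray, mobile: np.ndarray, fit_indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of mobile onto reference.

    Returns (rotation 3x3, translation 3, rmsd over the fit selection).  The
    rotation is proper (det = +1).  Apply as ``mobile @ R.T + t``.
    """
    reference = np.asarray(reference, float)
    mobile = np.asarray(mobile, float)
    if fit_indices is None:
        fit_indices = np.arange(reference.shape[0])
    ref = reference[fit_indices]
    mob = mobile[fit_indices]
    if ref.shape != mob.shape or ref.shape[0] < 3:
        raise ValueError("need >= 3 index-matched fit atoms")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    H = (mob - mob_c).T @ (ref - ref_c)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[1] < 1e-12:  # rank < 2: collinear or coincident selection
        raise ValueError("degenerate fit: fewer than 3 non-collinear atoms")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def _rmsd_raw(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def loop_rmsd_series(
    traj: TrajectoryCoords,
    reference: np.ndarray,
    fit_selection: Callable[[Atom], bool],
    measure_selection: Callable[[Atom], bool],
    pairwise: bool = False,
) -> np.ndarray:
    """Per-frame RMSD of a measured selection after fitting on another.

    Each frame is superposed onto the reference using ``fit_selection``; the
    RMSD is then computed over ``measure_selection`` without refitting.  With
    ``pairwise=True`` returns the symmetric frame-by-frame RMSD matrix
    instead (frame j fit onto frame i over the fit selection).
    """
    fit_idx = traj.select(fit_selection)
    meas_idx = traj.select(measure_selection)
    if fit_idx.size == 0 or meas_idx.size == 0:
        raise ValueError("selection resolves to zero atoms")
    reference = np.asarray(reference, float)

    if pairwise:
        n = traj.n_frames
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                R, t, _ = kabsch_rmsd(traj.frames[i], traj.frames[j], fit_idx)
                moved = traj.frames[j] @ R.T + t
                mat[i, j] = mat[j, i] = _rmsd_raw(moved[meas_idx], traj.frames[i][meas_idx])
        return mat

    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        R, t, _ = kabsch_rmsd(reference, traj.frames[k], fit_idx)
        moved = traj.frames[k] @ R.T + t
        out[k] = _rmsd_raw(moved[meas_idx], reference[meas_idx])
    return out


def backbone_rmsf(
    traj: TrajectoryCoords,
    fit_selection: Callable[[Atom], bool],
    measure_selection: Callable[[Atom], bool],
) -> dict[int, float]:
    """Per-residue RMSF (Å) after one fit-to-mean iteration.

    Frames are first fit onto frame 0, the mean structure of those fits is
    taken, every frame is re-fit onto that mean, and RMSF_i is the root mean
    squared displacement of atom i about its time-average position, averaged
    within each residue of the measure selection.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    fit_idx = traj.select(fit_selection)
    meas_idx = traj.select(measure_selection)
    if fit_idx.size == 0 or meas_idx.size == 0:
        raise ValueError("selection resolves to zero atoms")

    def fit_all(target: np.ndarray) -> np.ndarray:
        fitted = np.empty_like(traj.frames)
        for k in range(traj.n_frames):
            R, t, _ = kabsch_rmsd(target, traj.frames[k], fit_idx)
            fitted[k] = traj.frames[k] @ R.T + t
        return fitted

    fitted = fit_all(traj.frames[0])
    mean_structure = fitted.mean(axis=0)
    fitted = fit_all(mean_structure)

    avg_pos = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - avg_pos) ** 2, axis=2), axis=0))

    by_residue: dict[int, list[float]] = {}
    for i in meas_idx:
        by_residue.setdefault(traj.atoms[i].residue_id, []).append(per_atom[i])
    return {resid: float(np.mean(v)) for resid, v in sorted(by_residue.items())}


# --- dihedrals --------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, (-180, 180]) per the IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if angle <= -180.0 + 1e-12 else float(angle)


def compute_dihedral_series(
    traj: TrajectoryCoords, quadruple: Sequence[tuple[int, str]], name: str
) -> DihedralSeries:
    """Dihedral over four atoms identified as (residue_id, atom_name)."""
    indices = []
    for resid, atom_name in quadruple:
        matches = traj.select(lambda a, r=resid, n=atom_name: a.residue_id == r and a.atom_name == n)
        if matches.size == 0:
            raise ValueError(f"atom {atom_name} of residue {resid} not found")
        indices.append(int(matches[0]))
    angles = np.array(
        [
            dihedral_angle(*(traj.frames[k][i] for i in indices))
            for k in range(traj.n_frames)
        ]
    )
    return DihedralSeries(angles=angles, definition=name, dt=traj.dt)


def psi_hinge_quadruple(resid: int = PSI_HINGE_RESID):
    """psi(i): N(i)-CA(i)-C(i)-N(i+1)."""
    return [(resid, "N"), (resid, "CA"), (resid, "C"), (resid + 1, "N")]


def phi_hinge_quadruple(resid: int = PHI_HINGE_RESID):
    """phi(i): C(i-1)-N(i)-CA(i)-C(i)."""
    return [(resid - 1, "C"), (resid, "N"), (resid, "CA"), (resid, "C")]


# --- state assignment -------------------------------------------------------

def assign_states_dihedral(
    psi: DihedralSeries,
    phi: DihedralSeries,
    psi_cut: float = 5.0,
    phi_cut: float = -105.0,
) -> StateTrace:
    """Label frames ZA1/ZA2 from the two hinge dihedrals.

    ZA1 iff psi > psi_cut and phi < phi_cut; ZA2 iff psi <= psi_cut and
    phi >= phi_cut; frames where the hinges disagree stay UNASSIGNED.  The
    default cuts sit midway between the two states' modal values
    (psi 50 vs -40, phi -150 vs -60).
    """
    if len(psi) != len(phi):
        raise ValueError("psi and phi series must be frame-aligned")
    za1 = (psi.angles > psi_cut) & (phi.angles < phi_cut)
    za2 = (psi.angles <= psi_cut) & (phi.angles >= phi_cut)
    labels = np.full(len(psi), UNASSIGNED, dtype=object)
    labels[za1] = ZA1
    labels[za2] = ZA2
    return StateTrace(labels=labels, dt=psi.dt)


def assign_states_rmsd(rmsd_series: np.ndarray, cutoff: float = 2.5, dt: float = 1.0) -> StateTrace:
    """RMSD cross-check classifier: ZA2 iff loop RMSD to the crystal-like
    reference exceeds the cutoff (Å)."""
    labels = np.where(np.asarray(rmsd_series, float) > cutoff, ZA2, ZA1).astype(object)
    return StateTrace(labels=labels, dt=dt)


def smooth_trace(trace: StateTrace, min_dwell: int = 5) -> StateTrace:
    """Dwell filter: runs shorter than min_dwell inherit the previous state.

    UNASSIGNED frames are carried forward from the last assigned state first
    (and backward at the very start), so the dwell rule operates on a fully
    assigned trace.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    labels = list(trace.labels)
    n = len(labels)
    # forward/backward fill UNASSIGNED
    last = None
    for i in range(n):
        if labels[i] == UNASSIGNED:
            if last is not None:
                labels[i] = last
        else:
            last = labels[i]
    nxt = None
    for i in range(n - 1, -1, -1):
        if labels[i] == UNASSIGNED:
            if nxt is not None:
                labels[i] = nxt
        else:
            nxt = labels[i]
    if labels and labels[0] == UNASSIGNED:
        raise ValueError("cannot smooth an all-UNASSIGNED trace")
    # merge short runs into the preceding state
    runs: list[list] = []  # [label, length]
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    merged: list[list] = []  # first run is kept regardless of its length
    for lab, length in runs:
        if merged and (length < min_dwell or lab == merged[-1][0]):
            merged[-1][1] += length  # flicker inherits the previous state
        else:
            merged.append([lab, length])
    out = np.array([lab for lab, length in merged for _ in range(length)], dtype=object)
    return StateTrace(labels=out, dt=trace.dt)


class TransitionEvent(NamedTuple):
    frame: int
    time_ns: float
    from_state: str
    to_state: str


@dataclass(frozen=True)
class TransitionStats:
    occupancy: dict
    events: tuple[TransitionEvent, ...]
    first_za1_to_za2_ns: float | None
    n_reverse: int  # ZA2 -> ZA1 events
    smoothed: StateTrace


def transition_stats(trace: StateTrace, min_dwell: int = 1) -> TransitionStats:
    """Occupancies and dwell-filtered transition events of one trace.

    Occupancy is the fraction of *assigned* frames per state (before
    smoothing).  A transition is registered when the new state persists at
    least ``min_dwell`` frames; times are in ns (frame index × dt).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    labels = trace.labels
    assigned = labels != UNASSIGNED
    n_assigned = int(assigned.sum())
    if n_assigned == 0:
        raise ValueError("all frames UNASSIGNED: occupancy undefined")
    occupancy = {
        ZA1: float(np.sum(labels == ZA1)) / n_assigned,
        ZA2: float(np.sum(labels == ZA2)) / n_assigned,
    }
    smoothed = smooth_trace(trace, min_dwell=min_dwell)
    events = []
    sm = smoothed.labels
    ps_to_ns = trace.dt / 1000.0
    for i in range(1, len(sm)):
        if sm[i] != sm[i - 1]:
            events.append(
                TransitionEvent(
                    frame=i,
                    time_ns=i * ps_to_ns,
                    from_state=str(sm[i - 1]),
                    to_state=str(sm[i]),
                )
            )
    first = next(
        (e.time_ns for e in events if e.from_state == ZA1 and e.to_state == ZA2), None
    )
    n_reverse = sum(1 for e in events if e.from_state == ZA2 and e.to_state == ZA1)
    return TransitionStats(
        occupancy=occupancy,
        events=tuple(events),
        first_za1_to_za2_ns=first,
        n_reverse=n_reverse,
        smoothed=smoothed,
    )


def mean_first_transition_time(traces: Sequence[StateTrace], min_dwell: int = 1):
    """Mean and SEM (ns) of the first ZA1→ZA2 transition over replicas.

    Replicas that never transition are excluded (and counted)."""
    times = []
    n_missing = 0
    for trace in traces:
        stats = transition_stats(trace, min_dwell=min_dwell)
        if stats.first_za1_to_za2_ns is None:
            n_missing += 1
        else:
            times.append(stats.first_za1_to_za2_ns)
    if not times:
        raise ValueError("no replica exhibits a ZA1→ZA2 transition")
    times = np.asarray(times)
    sem = float(np.sqrt(np.var(times, ddof=1) / times.size)) if times.size > 1 else 0.0
    return float(times.mean()), sem, n_missing


def pair_distance_series(traj: TrajectoryCoords, atom_a: tuple[int, str], atom_b: tuple[int, str]) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two atoms given as
    (residue_id, atom_name)."""
    idx = []
    for resid, name in (atom_a, atom_b):
        matches = traj.select(lambda a, r=resid, n=name: a.residue_id == r and a.atom_name == n)
        if matches.size == 0:
            raise ValueError(f"atom {name} of residue {resid} not found")
        idx.append(int(matches[0]))
    delta = traj.frames[:, idx[0], :] - traj.frames[:, idx[1], :]
    return np.sqrt(np.sum(delta * delta, axis=1))
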