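"""Periodic distances, backbone dihedrals, centres of mass, hydrogen bonds.

Angles are signed degrees in (-180, +180] under the IUPAC convention
(cis = 0, trans = 180, sign by the right-hand rule about the central bond),
which is the convention under which a cis prolyl bond twisted in the
negative direction reads, e.g., -12 degrees.  Distances use the
minimum-image convention for rectangular periodic boxes.

Selections
----------
Atom selections are either explicit integer index arrays, ``(chain, resid)``
tuples, or strings with the grammar::

    term (";" term)*
    term     := CHAIN [":" RESRANGE ["@" NAMES]]
    RESRANGE := "*" | INT | INT "-" INT | INT ("," INT)*
    NAMES    := NAME ("," NAME)*

e.g. ``"H:103"``, ``"H:98-108@CA,C,N"``, ``"A;B"`` (union of chains A and B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    CompletenessError,
    GeometryError,
    SelectionError,
    ValidationError,
)
from .model_io import Frame, Residue, Structure, Trajectory

_DEGENERACY_TOL = 1e-9  # nm^2, cross-product norm below which points are collinear


# ---------------------------------------------------------------------------
# angle helpers
# ---------------------------------------------------------------------------

def wrap_angle(angle):
    """Map angles in degrees onto (-180, +180]."""
    a = np.asarray(angle, dtype=float)
    w = ((a + 180.0) % 360.0) - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(angle) or w.ndim == 0 else w


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _parse_resrange(token: str) -> set[int] | None:
    if token == "*":
        return None
    if "-" in token[1:]:  # allow negative start, though resids are positive
        lo, hi = token.split("-", 1) if not token.startswith("-") else (token, "")
        return set(range(int(lo), int(hi) + 1))
    return {int(t) for t in token.split(",")}


def select(structure: Structure, sel) -> np.ndarray:
    """Resolve a selection to sorted atom indices into ``structure.positions``."""
    if isinstance(sel, np.ndarray):
        return sel.astype(int)
    if isinstance(sel, (list,)) and sel and isinstance(sel[0], (int, np.integer)):
        return np.asarray(sel, dtype=int)
    if isinstance(sel, tuple) and len(sel) == 2:
        return structure.residue(sel[0], sel[1]).atom_indices
    if not isinstance(sel, str):
        raise SelectionError(f"unsupported selection {sel!r}")

    indices: list[int] = []
    for term in sel.split(";"):
        term = term.strip()
        if not term:
            continue
        names = None
        if "@" in term:
            term, name_part = term.split("@", 1)
            names = {n.strip() for n in name_part.split(",")}
        if ":" in term:
            chain, res_part = term.split(":", 1)
            resids = _parse_resrange(res_part.strip())
        else:
            chain, resids = term, None
        chain = chain.strip()
        chains = structure.chains
        if chain not in chains:
            raise SelectionError(f"no chain {chain!r} in structure")
        for r in chains[chain]:
            if resids is not None and r.index not in resids:
                continue
            for a in r.atoms:
                if names is not None and a.name not in names:
                    continue
                indices.append(a.index)
    if not indices:
        raise SelectionError(f"selection {sel!r} matched no atoms")
    return np.array(sorted(set(indices)), dtype=int)


def _atom_lookup(structure: Structure) -> list[tuple[Residue, "object"]]:
    flat = [None] * structure.n_atoms
    for r, a in structure.atoms():
        flat[a.index] = (r, a)
    return flat


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def minimum_image_displacement(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors (nm)."""
    d = np.asarray(d, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    if not np.all(box > 0):
        raise ValidationError(f"box lengths must be positive, got {box}")
    return d - box * np.round(d / box)


def minimum_image_distance(p1, p2, box=None) -> float:
    """Distance between two points (nm) to the nearest periodic image."""
    d = minimum_image_displacement(np.asarray(p2, float) - np.asarray(p1, float), box)
    return float(np.linalg.norm(d))


def pairwise_min_distance(
    pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray | None
) -> float:
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d = minimum_image_displacement(d, box)
    return float(np.sqrt((d ** 2).sum(axis=-1)).min())


def _filter_heavy(structure: Structure, idx: np.ndarray) -> np.ndarray:
    flat = _atom_lookup(structure)
    keep = [i for i in idx if flat[i][1].element.upper() != "H"]
    return np.asarray(keep, dtype=int)


def min_residue_distance(
    structure: Structure,
    frame: Frame,
    sel_a,
    sel_b,
    mode: str = "all-atom",
) -> float:
    """Minimum inter-atomic distance between two selections in one frame.

    ``mode`` is ``"all-atom"`` (default) or ``"heavy-atom"`` (hydrogens
    excluded on both sides).
    """
    if mode not in ("all-atom", "heavy-atom"):
        raise ValidationError(f"unknown distance mode {mode!r}")
    ia, ib = select(structure, sel_a), select(structure, sel_b)
    if mode == "heavy-atom":
        ia, ib = _filter_heavy(structure, ia), _filter_heavy(structure, ib)
    if len(ia) == 0 or len(ib) == 0:
        raise SelectionError("empty selection after filtering")
    return pairwise_min_distance(frame.positions[ia], frame.positions[ib], frame.box)


@dataclass
class ContactTimeSeries:
    """Per-frame minimum distance between two selections."""

    times: np.ndarray        # ps
    min_distance: np.ndarray  # nm
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.min_distance = np.asarray(self.min_distance, dtype=float)
        if np.any(self.min_distance < 0):
            raise ValidationError("distances must be non-negative")


def contact_series(
    traj: Trajectory, sel_a, sel_b, mode: str = "all-atom"
) -> ContactTimeSeries:
    dists = [
        min_residue_distance(traj.topology, f, sel_a, sel_b, mode=mode)
        for f in traj.frames
    ]
    return ContactTimeSeries(
        times=traj.times, min_distance=np.array(dists), pair=(str(sel_a), str(sel_b))
    )


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def _dihedral_arrays(p1, p2, p3, p4, check: bool = True) -> np.ndarray:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if check:
        if np.any(np.linalg.norm(n1, axis=-1) < _DEGENERACY_TOL) or np.any(
            np.linalg.norm(n2, axis=-1) < _DEGENERACY_TOL
        ):
            raise GeometryError(
                "degenerate dihedral: three consecutive points are collinear "
                "or coincident"
            )
    b2_hat = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = (n1 * n2).sum(axis=-1)
    y = (np.cross(n1, n2) * b2_hat).sum(axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees) of four points about the p2-p3 axis.

    IUPAC convention: 0 for the syn (cis) planar arrangement, 180 for anti
    (trans); positive sign for clockwise rotation of the far bond viewed
    from p2 towards p3 (right-hand rule).
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    return float(_dihedral_arrays(*pts))


@dataclass
class OmegaSeries:
    """Per-frame peptide-bond omega angles for one Xaa-Pro (or any) bond."""

    times: np.ndarray        # ps
    angles: np.ndarray       # degrees in (-180, 180]
    peptide_bond: tuple[tuple[str, int], tuple[str, int]]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValidationError("omega angles must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return len(self.angles)


@dataclass
class RamachandranSeries:
    """Per-frame phi/psi angles for one residue; NaN marks undefined termini."""

    residue: tuple[str, int]
    times: np.ndarray
    phi: np.ndarray          # degrees or NaN
    psi: np.ndarray


def _backbone_atom(res: Residue, name: str) -> int:
    a = res.atom(name)
    if a is None:
        raise CompletenessError(
            f"residue {res.chain_id}:{res.index} ({res.name}) is missing "
            f"backbone atom {name}"
        )
    return a.index


def _stacked_positions(traj: Trajectory, indices: list[int]) -> list[np.ndarray]:
    stack = np.stack([f.positions for f in traj.frames])  # (n_frames, n_atoms, 3)
    return [stack[:, i, :] for i in indices]


def omega_series(traj: Trajectory, res_i, res_j=None) -> OmegaSeries:
    """Omega series of the peptide bond between residue i and residue i+1.

    Omega is the CA(i)-C(i)-N(i+1)-CA(i+1) dihedral; ~180 deg is trans,
    ~0 deg is cis.  ``res_i``/``res_j`` are ``(chain, resid)``; ``res_j``
    defaults to the residue that follows ``res_i`` in its chain.
    """
    top = traj.topology
    ri = top.residue(*res_i)
    chain = top.chains[ri.chain_id]
    pos_in_chain = chain.index(ri)
    if res_j is None:
        if pos_in_chain + 1 >= len(chain):
            raise ValidationError(f"residue {res_i} has no successor in its chain")
        rj = chain[pos_in_chain + 1]
    else:
        rj = top.residue(*res_j)
        if pos_in_chain + 1 >= len(chain) or chain[pos_in_chain + 1] is not rj:
            raise ValidationError(
                f"residue {res_j} does not immediately follow {res_i} in the chain"
            )
    idx = [
        _backbone_atom(ri, "CA"),
        _backbone_atom(ri, "C"),
        _backbone_atom(rj, "N"),
        _backbone_atom(rj, "CA"),
    ]
    angles = _dihedral_arrays(*_stacked_positions(traj, idx))
    return OmegaSeries(
        times=traj.times,
        angles=np.atleast_1d(angles),
        peptide_bond=(ri.key, rj.key),
    )


def phi_psi_series(traj: Trajectory, residue) -> RamachandranSeries:
    """Phi/psi series for one residue; chain termini yield NaN, not errors.

    phi = C(i-1)-N(i)-CA(i)-C(i); psi = N(i)-CA(i)-C(i)-N(i+1).
    """
    top = traj.topology
    r = top.residue(*residue)
    chain = top.chains[r.chain_id]
    pos = chain.index(r)
    n_frames = traj.n_frames
    nan = np.full(n_frames, np.nan)

    n_i, ca_i, c_i = (
        _backbone_atom(r, "N"),
        _backbone_atom(r, "CA"),
        _backbone_atom(r, "C"),
    )
    phi = nan.copy()
    psi = nan.copy()
    if pos > 0:
        c_prev = _backbone_atom(chain[pos - 1], "C")
        phi = np.atleast_1d(
            _dihedral_arrays(*_stacked_positions(traj, [c_prev, n_i, ca_i, c_i]))
        )
    if pos + 1 < len(chain):
        n_next = _backbone_atom(chain[pos + 1], "N")
        psi = np.atleast_1d(
            _dihedral_arrays(*_stacked_positions(traj, [n_i, ca_i, c_i, n_next]))
        )
    return RamachandranSeries(residue=r.key, times=traj.times, phi=phi, psi=psi)


# ---------------------------------------------------------------------------
# centre of mass
# ---------------------------------------------------------------------------

def center_of_mass(structure: Structure, frame: Frame, sel) -> np.ndarray:
    """Mass-weighted mean position (nm) of a selection.

    Positions are used as stored: molecules must be whole (not split across
    the periodic boundary); no unwrapping is attempted.
    """
    idx = select(structure, sel)
    masses = structure.param_arrays()["mass"][idx]
    if np.any(np.isnan(masses)):
        raise ValidationError("masses are not attached; read a parameter table first")
    total = masses.sum()
    if not total > 0:
        raise ValidationError("selection has zero total mass")
    return (frame.positions[idx] * masses[:, None]).sum(axis=0) / total


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (conventional defaults).

    ``d_max``: donor-acceptor heavy-atom distance ceiling (nm);
    ``angle_min``: donor-H-acceptor angle floor (degrees).
    """

    d_max: float = 0.35
    angle_min: float = 120.0

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValidationError("d_max must be positive")
        if not (0 < self.angle_min <= 180):
            raise ValidationError("angle_min must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    donor: int       # atom index of the donor heavy atom
    hydrogen: int
    acceptor: int
    distance: float  # donor-acceptor, nm
    angle: float     # donor-H-acceptor, degrees


_DONOR_ELEMENTS = {"N", "O"}
_ACCEPTOR_ELEMENTS = {"N", "O", "F"}
_BOND_DH_MAX = 0.125  # nm; covalent D-H attachment threshold


def detect_hbonds(
    structure: Structure,
    frame: Frame,
    donors,
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Geometric hydrogen-bond detection between two selections.

    Donors are N/O atoms of the donor selection with a covalently attached
    hydrogen, resolved geometrically (an H in the same residue within
    0.125 nm); donors without a resolvable hydrogen are skipped with a
    warning.  A bond is reported when the donor-acceptor minimum-image
    distance is <= ``d_max`` and the D-H...A angle is >= ``angle_min``.
    """
    flat = _atom_lookup(structure)
    pos, box = frame.positions, frame.box
    d_idx = select(structure, donors)
    a_idx = select(structure, acceptors)

    acceptor_atoms = [i for i in a_idx if flat[i][1].element.upper() in _ACCEPTOR_ELEMENTS]
    out: list[HBond] = []
    for d in d_idx:
        res_d, atom_d = flat[d]
        if atom_d.element.upper() not in _DONOR_ELEMENTS:
            continue
        hydrogens = [
            a.index
            for a in res_d.atoms
            if a.element.upper() == "H"
            and minimum_image_distance(pos[a.index], pos[d], box) <= _BOND_DH_MAX
        ]
        if not hydrogens:
            warnings.warn(
                f"donor {res_d.chain_id}:{res_d.index}/{atom_d.name} has no "
                "resolvable hydrogen; skipped"
            )
            continue
        for acc in acceptor_atoms:
            if acc == d or flat[acc][0] is res_d:
                continue
            dist = minimum_image_distance(pos[d], pos[acc], box)
            if dist > criteria.d_max:
                continue
            for h in hydrogens:
                v1 = minimum_image_displacement(pos[d] - pos[h], box)
                v2 = minimum_image_displacement(pos[acc] - pos[h], box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang >= criteria.angle_min:
                    out.append(
                        HBond(donor=int(d), hydrogen=int(h), acceptor=int(acc),
                              distance=dist, angle=ang)
                    )
    return out
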