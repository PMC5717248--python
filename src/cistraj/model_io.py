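"""Structures, trajectories, parameter tables and residue-pair lists.

Unit conventions, used everywhere downstream:

* length  nm  (PDB Angstrom converted on read, factor 0.1)
* time    ps  (multi-model PDB carries no time metadata; frames are then
  numbered 0, 1, 2, ... in frame units)
* mass    u, charge e, energy kJ/mol

Coordinate I/O is delegated to MDAnalysis; this module only adapts between
MDAnalysis universes and the lightweight domain types below, which carry the
per-atom nonbonded parameters (mass, charge, Lennard-Jones sigma/epsilon)
that the energetics layer needs.  Force-field parameter assignment is out of
scope: parameters come from a plain TSV table (see
:func:`read_topology_params`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    ParseError,
    SchemaError,
    SelectionError,
    ShapeError,
    UsageError,
    ValidationError,
)

ANGSTROM_PER_NM = 10.0

_PARAM_COLUMNS = ("chain", "res", "atom", "mass_u", "charge_e", "sigma_nm", "epsilon_kjmol")
_PAIR_COLUMNS = ("chain_a", "res_a", "chain_b", "res_b", "r_crystal_nm")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom: identity plus the nonbonded parameters energetics needs.

    Parameters default to NaN until :func:`read_topology_params` (or a
    synthetic generator) attaches them; geometry-only workflows never need
    them.
    """

    serial: int
    name: str
    element: str = ""
    mass: float = math.nan          # u
    charge: float = math.nan        # e
    lj_sigma: float = math.nan      # nm
    lj_epsilon: float = math.nan    # kJ/mol
    index: int = -1                 # row in the owning Structure's positions

    @property
    def has_params(self) -> bool:
        return not any(
            math.isnan(v) for v in (self.mass, self.charge, self.lj_sigma, self.lj_epsilon)
        )


@dataclass
class Residue:
    """A residue keyed by author numbering (preserved exactly from input)."""

    index: int
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def atom_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms], dtype=int)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.index)


@dataclass
class Structure:
    """Chains -> residues -> atoms plus one coordinate set (nm).

    ``box`` is the rectangular periodic box edge lengths in nm, or ``None``
    for a non-periodic system.  Triclinic boxes are not supported.
    """

    residues: list[Residue]
    positions: np.ndarray            # (n_atoms, 3), nm
    box: np.ndarray | None = None    # (3,), nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValidationError(f"box lengths must be positive, got {self.box}")
        n = sum(len(r.atoms) for r in self.residues)
        if n != len(self.positions):
            raise ValidationError(
                f"positions count {len(self.positions)} != atom count {n}"
            )
        seen: set[tuple[str, int]] = set()
        for r in self.residues:
            if not r.atoms:
                raise ValidationError(f"residue {r.chain_id}:{r.index} has no atoms")
            if r.key in seen:
                raise ValidationError(f"duplicate residue key {r.key}")
            seen.add(r.key)
        self._by_key = {r.key: r for r in self.residues}

    # -- access helpers ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def residue(self, chain_id: str, index: int) -> Residue:
        try:
            return self._by_key[(chain_id, int(index))]
        except KeyError:
            raise SelectionError(f"no residue {chain_id}:{index} in structure") from None

    def has_residue(self, chain_id: str, index: int) -> bool:
        return (chain_id, int(index)) in self._by_key

    def param_arrays(self) -> dict[str, np.ndarray]:
        """Per-atom parameter/bookkeeping arrays for vectorised energetics."""
        n = self.n_atoms
        q = np.empty(n)
        sig = np.empty(n)
        eps = np.empty(n)
        mass = np.empty(n)
        chain_code = np.empty(n, dtype=int)
        resid = np.empty(n, dtype=int)
        chain_ids = list(self.chains)
        for r in self.residues:
            c = chain_ids.index(r.chain_id)
            for a in r.atoms:
                q[a.index] = a.charge
                sig[a.index] = a.lj_sigma
                eps[a.index] = a.lj_epsilon
                mass[a.index] = a.mass
                chain_code[a.index] = c
                resid[a.index] = r.index
        return {
            "charge": q,
            "sigma": sig,
            "epsilon": eps,
            "mass": mass,
            "chain": chain_code,
            "resid": resid,
        }


@dataclass
class Frame:
    """One time point of a trajectory."""

    time: float                      # ps (or frame index when no metadata)
    positions: np.ndarray            # (n_atoms, 3), nm
    box: np.ndarray | None = None    # (3,), nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)


@dataclass
class Trajectory:
    topology: Structure
    frames: list[Frame]

    def __post_init__(self) -> None:
        for f in self.frames:
            if len(f.positions) != self.topology.n_atoms:
                raise ShapeError(
                    f"frame at t={f.time} has {len(f.positions)} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ResiduePair:
    """An antigen/antibody residue pair with its crystal reference distance."""

    res_a: tuple[str, int]
    res_b: tuple[str, int]
    r_crystal: float                 # nm

    def __post_init__(self) -> None:
        if not self.r_crystal > 0:
            raise ValidationError(
                f"r_crystal must be positive for pair {self.res_a}-{self.res_b}, "
                f"got {self.r_crystal}"
            )


@dataclass
class ResiduePairList:
    pairs: list[ResiduePair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("pair list is empty; similarity score undefined")
        keys = [(p.res_a, p.res_b) for p in self.pairs]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate residue pairs: {dupes}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# format helpers
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    s = name.strip()
    while s and s[0].isdigit():
        s = s[1:]
    return s[0].upper() if s else ""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("pdb", "gro"):
        raise UsageError(f"unknown structure format {fmt!r}; expected 'pdb' or 'gro'")
    return fmt


def _box_from_dimensions(dims) -> np.ndarray | None:
    """Convert an MDAnalysis dimensions array (A, deg) to nm box lengths.

    A unitary 1x1x1 A cell is the placeholder MDAnalysis writes for
    non-periodic systems and is read back as "no box".
    """
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    lengths, angles = dims[:3], dims[3:]
    if np.all(lengths <= 0):
        return None
    if np.allclose(lengths, 1.0, atol=1e-6):
        return None
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise ValidationError(
            f"only rectangular boxes are supported; got angles {angles}"
        )
    return lengths / ANGSTROM_PER_NM


def _universe_chain_ids(u) -> list[str]:
    """Per-residue chain identifiers, tolerating format differences."""
    out = []
    for r in u.residues:
        cid = ""
        if hasattr(r.atoms, "chainIDs") and len(r.atoms):
            cid = str(r.atoms.chainIDs[0]).strip()
        if not cid and hasattr(r, "segid"):
            cid = str(r.segid).strip()
        if not cid or cid == "SYSTEM":
            cid = "A"
        out.append(cid)
    return out


def _structure_from_universe(u) -> Structure:
    chain_ids = _universe_chain_ids(u)
    # GRO carries no chain field; when every residue lands in the same
    # default chain, a decrease in the author numbering marks a new molecule
    # and starts a new chain (A, B, C, ...).
    resids = [int(r.resid) for r in u.residues]
    if len(set(chain_ids)) == 1 and any(b < a for a, b in zip(resids, resids[1:])):
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        block = 0
        chain_ids = []
        for i, resid in enumerate(resids):
            if i > 0 and resid < resids[i - 1]:
                block += 1
            chain_ids.append(letters[block % len(letters)])
    has_elements = hasattr(u.atoms, "elements")
    has_ids = hasattr(u.atoms, "ids")
    residues: list[Residue] = []
    idx = 0
    for r, cid in zip(u.residues, chain_ids):
        res = Residue(index=int(r.resid), name=str(r.resname), chain_id=cid)
        for a in r.atoms:
            elem = str(a.element).strip() if has_elements else ""
            if not elem:
                elem = _guess_element(str(a.name))
            serial = int(a.id) if has_ids else idx + 1
            res.atoms.append(
                Atom(serial=serial, name=str(a.name), element=elem, index=idx)
            )
            idx += 1
        residues.append(res)
    positions = u.atoms.positions.astype(float) / ANGSTROM_PER_NM
    box = _box_from_dimensions(u.dimensions)
    return Structure(residues=residues, positions=positions, box=box)


def _load_universe(path: Path, fmt: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path), format=fmt, topology_format=fmt)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or GRO coordinate file into a :class:`Structure`.

    Author residue numbering and chain identifiers are preserved; PDB
    coordinates (Angstrom) are converted to nm, GRO coordinates are already
    nm.  The format is inferred from the file suffix when ``fmt`` is None.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        u = _load_universe(path, fmt)
    except UsageError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted types on bad input
        raise ParseError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _structure_from_universe(u)


def read_trajectory(path, topology: Structure) -> Trajectory:
    """Read a multi-model PDB as a trajectory over the given topology.

    One :class:`Frame` per MODEL; times are frame indices 0, 1, 2, ...
    (multi-model PDB stores no time metadata).  Frames without a box inherit
    the topology box.
    """
    path = Path(path)
    try:
        u = _load_universe(path, _infer_format(path, None))
    except UsageError:
        raise
    except Exception as exc:
        raise ParseError(f"could not parse trajectory {path}: {exc}") from exc
    if u.atoms.n_atoms != topology.n_atoms:
        raise ShapeError(
            f"trajectory {path} has {u.atoms.n_atoms} atoms, "
            f"topology expects {topology.n_atoms}"
        )
    frames = []
    for i, ts in enumerate(u.trajectory):
        box = _box_from_dimensions(ts.dimensions)
        frames.append(
            Frame(
                time=float(i),
                positions=ts.positions.astype(float) / ANGSTROM_PER_NM,
                box=box if box is not None else topology.box,
            )
        )
    return Trajectory(topology=topology, frames=frames)


def read_pair_list(path) -> ResiduePairList:
    """Read a residue-pair TSV (chain_a, res_a, chain_b, res_b, r_crystal_nm)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"could not read pair list {path}: {exc}") from exc
    missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pair list {path} missing columns: {missing}")
    if df.empty:
        raise ValidationError(f"pair list {path} has no rows")
    if not (df["r_crystal_nm"] > 0).all():
        bad = df.loc[~(df["r_crystal_nm"] > 0)]
        raise ValidationError(f"non-positive r_crystal_nm rows:\n{bad}")
    pairs = [
        ResiduePair(
            res_a=(str(row.chain_a), int(row.res_a)),
            res_b=(str(row.chain_b), int(row.res_b)),
            r_crystal=float(row.r_crystal_nm),
        )
        for row in df.itertuples()
    ]
    return ResiduePairList(pairs=pairs)


def read_topology_params(path, structure: Structure) -> Structure:
    """Attach per-atom mass/charge/LJ parameters from a TSV table.

    Columns: chain, res, atom, mass_u, charge_e, sigma_nm, epsilon_kjmol.
    Optional header comments of the form ``# net_charge CHAIN VALUE`` are
    validated against the summed charges of that chain (tolerance 1e-6 e).
    Every atom of ``structure`` must be covered; the structure is modified
    in place and returned.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"could not read parameter table {path}: {exc}") from exc
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter table {path} missing columns: {missing}")

    table: dict[tuple[str, int, str], tuple[float, float, float, float]] = {}
    for row in df.itertuples():
        table[(str(row.chain), int(row.res), str(row.atom))] = (
            float(row.mass_u),
            float(row.charge_e),
            float(row.sigma_nm),
            float(row.epsilon_kjmol),
        )

    unmatched = []
    for res, atom in structure.atoms():
        key = (res.chain_id, res.index, atom.name)
        if key not in table:
            unmatched.append("/".join(map(str, key)))
            continue
        mass, charge, sigma, eps = table[key]
        if not mass > 0 or sigma < 0 or eps < 0:
            raise ValidationError(
                f"invalid parameters for atom {key}: mass={mass}, sigma={sigma}, "
                f"epsilon={eps}"
            )
        atom.mass, atom.charge, atom.lj_sigma, atom.lj_epsilon = mass, charge, sigma, eps
    if unmatched:
        raise CompletenessError(
            f"no parameter rows for {len(unmatched)} atoms: {', '.join(unmatched)}"
        )

    for line in path.read_text().splitlines():
        if line.startswith("# net_charge"):
            _, _, chain, value = line.split()
            total = sum(
                a.charge for r, a in structure.atoms() if r.chain_id == chain
            )
            if abs(total - float(value)) > 1e-6:
                raise ValidationError(
                    f"chain {chain} charges sum to {total:.8f}, "
                    f"header declares {value}"
                )
    return structure


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _to_universe(structure: Structure):
    import MDAnalysis as mda

    n_res = len(structure.residues)
    atom_resindex = np.concatenate(
        [[i] * len(r.atoms) for i, r in enumerate(structure.residues)]
    )
    chain_order = list(structure.chains)
    residue_segindex = np.array(
        [chain_order.index(r.chain_id) for r in structure.residues]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            structure.n_atoms,
            n_residues=n_res,
            atom_resindex=atom_resindex,
            residue_segindex=residue_segindex,
            n_segments=len(chain_order),
            trajectory=True,
        )
        names, elements, chain_per_atom = [], [], []
        for r, a in structure.atoms():
            names.append(a.name)
            elements.append(a.element or _guess_element(a.name))
            chain_per_atom.append(r.chain_id)
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", elements)
        u.add_TopologyAttr("chainIDs", chain_per_atom)
        u.add_TopologyAttr("resids", [r.index for r in structure.residues])
        u.add_TopologyAttr("resnames", [r.name for r in structure.residues])
        u.add_TopologyAttr("segids", chain_order)
        u.add_TopologyAttr("occupancies", np.ones(structure.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(structure.n_atoms))
        u.atoms.positions = structure.positions * ANGSTROM_PER_NM
        if structure.box is not None:
            u.dimensions = np.concatenate(
                [structure.box * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
            )
    return u


def write_structure(structure: Structure, path, fmt: str | None = None) -> None:
    """Write a :class:`Structure` as PDB or GRO (format from suffix by default)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    u = _to_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    path = Path(path)
    u = _to_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, multiframe=True) as w:
            for f in traj.frames:
                u.atoms.positions = f.positions * ANGSTROM_PER_NM
                if f.box is not None:
                    u.dimensions = np.concatenate(
                        [f.box * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
                    )
                w.write(u.atoms)


def write_pair_list(pairs: ResiduePairList, path) -> None:
    df = pd.DataFrame(
        [
            {
                "chain_a": p.res_a[0],
                "res_a": p.res_a[1],
                "chain_b": p.res_b[0],
                "res_b": p.res_b[1],
                "r_crystal_nm": p.r_crystal,
            }
            for p in pairs.pairs
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_topology_params(structure: Structure, path, net_charge_chains: Sequence[str] = ()) -> None:
    """Write the parameter table read by :func:`read_topology_params`."""
    rows = []
    for r, a in structure.atoms():
        rows.append(
            {
                "chain": r.chain_id,
                "res": r.index,
                "atom": a.name,
                "mass_u": a.mass,
                "charge_e": a.charge,
                "sigma_nm": a.lj_sigma,
                "epsilon_kjmol": a.lj_epsilon,
            }
        )
    df = pd.DataFrame(rows)
    path = Path(path)
    with path.open("w") as fh:
        for chain in net_charge_chains:
            total = df.loc[df["chain"] == chain, "charge_e"].sum()
            fh.write(f"# net_charge {chain} {total:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)
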