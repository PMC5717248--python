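"""Short-range nonbonded interaction energies and their decomposition.

The interaction energy between two atom groups, E_int, is the sum over all
cross-group atom pairs of a cutoff Coulomb term and a switched
Lennard-Jones term evaluated at minimum-image distances:

* Coulomb: f q_i q_j / r for r < r_cut (default 1.0 nm), sharply truncated;
  f = 138.935458 kJ mol^-1 nm e^-2.  Only the real-space part of the
  electrostatics is computed: no reciprocal-space (mesh Ewald)
  contribution, so absolute Coulomb totals are short-range energies only.
* Lennard-Jones: 4 eps [(sigma/r)^12 - (sigma/r)^6] multiplied by a
  smoothstep switching function equal to 1 below 0.8 nm and 0 above 0.9 nm
  (defaults), with Lorentz-Berthelot combining rules.

Bonded exclusions are approximated by residue separation: atom pairs in the
same chain are summed only when their author residue indices differ by at
least 2 (bonded topology itself is out of scope).  Inter-chain pairs are
always summed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SelectionError, ValidationError
from .geometry import minimum_image_displacement, select
from .model_io import Frame, Structure, Trajectory

COULOMB_CONSTANT = 138.935458  # kJ mol^-1 nm e^-2

POSE_BIN_LABELS = (
    "<=-800",
    "(-800,-700]",
    "(-700,-600]",
    "(-600,-500]",
    "(-500,-400]",
    ">-400",
)
_POSE_EDGES = (-800.0, -700.0, -600.0, -500.0, -400.0)


@dataclass(frozen=True)
class NonbondedParams:
    """Cutoff / switching parameters for the nonbonded model."""

    coulomb_constant: float = COULOMB_CONSTANT
    r_cut_coulomb: float = 1.0       # nm
    lj_switch_start: float = 0.8     # nm
    lj_switch_end: float = 0.9       # nm
    combining_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        if not (0 < self.lj_switch_start < self.lj_switch_end <= self.r_cut_coulomb):
            raise ValidationError(
                "require 0 < lj_switch_start < lj_switch_end <= r_cut_coulomb, got "
                f"{self.lj_switch_start}, {self.lj_switch_end}, {self.r_cut_coulomb}"
            )
        if self.combining_rule != "lorentz-berthelot":
            raise ValidationError(
                f"unsupported combining rule {self.combining_rule!r}"
            )


@dataclass(frozen=True)
class EnergyTerms:
    """Coulomb + Lennard-Jones energies (kJ/mol); total is their exact sum."""

    coulomb: float
    lj: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lj

    def __add__(self, other: "EnergyTerms") -> "EnergyTerms":
        return EnergyTerms(self.coulomb + other.coulomb, self.lj + other.lj)


def _switch(r, start: float, end: float):
    """Quintic smoothstep from 1 at ``start`` to 0 at ``end`` (C2-continuous)."""
    x = np.clip((np.asarray(r, dtype=float) - start) / (end - start), 0.0, 1.0)
    return 1.0 - x ** 3 * (10.0 - 15.0 * x + 6.0 * x ** 2)


def coulomb_pair(r: float, q1: float, q2: float, params: NonbondedParams = NonbondedParams()) -> float:
    """Truncated Coulomb energy (kJ/mol) of one charge pair at distance r (nm)."""
    if not r > 0:
        raise ValidationError(f"Coulomb energy is singular at r={r}")
    if r >= params.r_cut_coulomb:
        return 0.0
    return params.coulomb_constant * q1 * q2 / r


def lj_pair(r: float, sigma: float, epsilon: float, params: NonbondedParams = NonbondedParams()) -> float:
    """Switched Lennard-Jones energy (kJ/mol) of one pair at distance r (nm)."""
    if not r > 0:
        raise ValidationError(f"Lennard-Jones energy is singular at r={r}")
    if r >= params.lj_switch_end:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6) * float(_switch(r, params.lj_switch_start, params.lj_switch_end))


def _require_params(arrays: dict[str, np.ndarray], idx: np.ndarray) -> None:
    for key in ("charge", "sigma", "epsilon"):
        if np.any(np.isnan(arrays[key][idx])):
            raise ValidationError(
                "nonbonded parameters are not attached for all selected atoms; "
                "read a parameter table first"
            )


def _pair_energy_vectorised(
    positions: np.ndarray,
    box: np.ndarray | None,
    ia: np.ndarray,
    ib: np.ndarray,
    arrays: dict[str, np.ndarray],
    params: NonbondedParams,
) -> EnergyTerms:
    d = positions[ia][:, None, :] - positions[ib][None, :, :]
    d = minimum_image_displacement(d, box)
    r = np.sqrt((d ** 2).sum(axis=-1))
    if np.any(r < 1e-12):
        raise ValidationError("zero interatomic distance in energy evaluation")

    same_chain = arrays["chain"][ia][:, None] == arrays["chain"][ib][None, :]
    near_bonded = np.abs(arrays["resid"][ia][:, None] - arrays["resid"][ib][None, :]) < 2
    include = ~(same_chain & near_bonded)

    qq = arrays["charge"][ia][:, None] * arrays["charge"][ib][None, :]
    coul = np.where(
        include & (r < params.r_cut_coulomb), params.coulomb_constant * qq / r, 0.0
    )

    sig = 0.5 * (arrays["sigma"][ia][:, None] + arrays["sigma"][ib][None, :])
    eps = np.sqrt(arrays["epsilon"][ia][:, None] * arrays["epsilon"][ib][None, :])
    with np.errstate(over="ignore"):
        sr6 = (sig / r) ** 6
        lj_raw = 4.0 * eps * (sr6 * sr6 - sr6) * _switch(
            r, params.lj_switch_start, params.lj_switch_end
        )
    lj = np.where(include & (r < params.lj_switch_end), lj_raw, 0.0)
    return EnergyTerms(coulomb=float(coul.sum()), lj=float(lj.sum()))


def group_energy(
    structure: Structure,
    frame: Frame,
    group_a,
    group_b,
    params: NonbondedParams = NonbondedParams(),
) -> EnergyTerms:
    """E_int between two disjoint atom groups in one frame (kJ/mol)."""
    ia, ib = select(structure, group_a), select(structure, group_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("groups overlap at the atom level")
    arrays = structure.param_arrays()
    _require_params(arrays, np.concatenate([ia, ib]))
    return _pair_energy_vectorised(frame.positions, frame.box, ia, ib, arrays, params)


# ---------------------------------------------------------------------------
# time / ensemble averaging
# ---------------------------------------------------------------------------

def window_average(times, values, window: tuple[float, float]) -> float:
    """Arithmetic mean of ``values`` over frames with t0 <= t <= t1 (closed)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t0, t1 = window
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ValidationError(f"no frames inside window [{t0}, {t1}]")
    return float(values[mask].mean())


@dataclass
class ResidueEnergyStats:
    """Across-trajectory statistics for one residue's interaction energy."""

    mean: float           # kJ/mol (total)
    se: float             # kJ/mol; 0 when only one trajectory
    n_trajectories: int
    mean_coulomb: float
    mean_lj: float
    per_trajectory: np.ndarray  # per-trajectory window-averaged totals


@dataclass
class EnergyBreakdown:
    """Per-residue interaction-energy decomposition with ensemble errors.

    The sum of per-residue means equals the mean whole-molecule total (the
    decomposition is exact because every cross-group pair belongs to exactly
    one residue of the chosen side).
    """

    entries: dict[tuple[str, int, str], ResidueEnergyStats]
    side: str
    window: tuple[float, float]
    n_trajectories: int

    def total_mean(self) -> float:
        return float(sum(s.mean for s in self.entries.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chain, resid, resname), s in self.entries.items():
            rows.append(
                {
                    "chain": chain,
                    "res": resid,
                    "resname": resname,
                    "mean_total": s.mean,
                    "se_total": s.se,
                    "mean_coulomb": s.mean_coulomb,
                    "mean_lj": s.mean_lj,
                    "n_trajectories": s.n_trajectories,
                }
            )
        return pd.DataFrame(rows)


def residue_breakdown(
    trajectories: Sequence[Trajectory],
    mol_a,
    mol_b,
    window: tuple[float, float],
    side: str = "a",
    params: NonbondedParams = NonbondedParams(),
) -> EnergyBreakdown:
    """Per-residue breakdown of the group-group interaction energy.

    For each residue of the chosen side the energy against the *entire*
    other molecule is averaged over the frames inside ``window`` (closed
    interval), then the mean and standard error are taken across the
    independent trajectories (SE = sample sd / sqrt(n); 0 for n = 1).
    """
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    if side not in ("a", "b"):
        raise ValidationError(f"side must be 'a' or 'b', got {side!r}")
    t0, t1 = window
    if not t1 >= t0:
        raise ValidationError(f"empty window ({t0}, {t1})")

    top = trajectories[0].topology
    ia, ib = select(top, mol_a), select(top, mol_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("molecule selections overlap")
    own, other = (ia, ib) if side == "a" else (ib, ia)
    arrays = top.param_arrays()
    _require_params(arrays, np.concatenate([ia, ib]))

    own_set = set(own.tolist())
    residues = [
        r for r in top.residues if any(a.index in own_set for a in r.atoms)
    ]
    res_idx = [
        np.array([a.index for a in r.atoms if a.index in own_set]) for r in residues
    ]

    per_traj = {r.key: {"total": [], "coulomb": [], "lj": []} for r in residues}
    for traj in trajectories:
        mask = (traj.times >= t0) & (traj.times <= t1)
        if not mask.any():
            raise ValidationError(
                f"window [{t0}, {t1}] contains no frames of a trajectory"
            )
        frames = [f for f, m in zip(traj.frames, mask) if m]
        for r, idx in zip(residues, res_idx):
            terms = [
                _pair_energy_vectorised(f.positions, f.box, idx, other, arrays, params)
                for f in frames
            ]
            per_traj[r.key]["total"].append(np.mean([t.total for t in terms]))
            per_traj[r.key]["coulomb"].append(np.mean([t.coulomb for t in terms]))
            per_traj[r.key]["lj"].append(np.mean([t.lj for t in terms]))

    n = len(trajectories)
    entries: dict[tuple[str, int, str], ResidueEnergyStats] = {}
    for r in residues:
        totals = np.array(per_traj[r.key]["total"])
        se = float(totals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        entries[(r.chain_id, r.index, r.name)] = ResidueEnergyStats(
            mean=float(totals.mean()),
            se=se,
            n_trajectories=n,
            mean_coulomb=float(np.mean(per_traj[r.key]["coulomb"])),
            mean_lj=float(np.mean(per_traj[r.key]["lj"])),
            per_trajectory=totals,
        )
    return EnergyBreakdown(entries=entries, side=side, window=window, n_trajectories=n)


# ---------------------------------------------------------------------------
# pose classification
# ---------------------------------------------------------------------------

def classify_pose(e_int: float) -> str:
    """Bin an interaction energy (kJ/mol) into the half-open pose classes.

    Bins: <=-800, (-800,-700], (-700,-600], (-600,-500], (-500,-400], >-400.
    """
    if e_int <= _POSE_EDGES[0]:
        return POSE_BIN_LABELS[0]
    for lo, label in zip(_POSE_EDGES[1:], POSE_BIN_LABELS[1:-1]):
        if e_int <= lo:
            return label
    return POSE_BIN_LABELS[-1]
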