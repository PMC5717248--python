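"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here:

* idealized peptide backbones with prescribed omega/phi/psi dihedrals
  (exact by construction, so dihedral code can be validated by round-trip);
* two-molecule toy complexes with known charges and Lennard-Jones
  parameters in rectangular periodic boxes, plus an O(N^2) brute-force
  energy oracle;
* ensembles of independent omega time series following wrapped-normal
  distributions with optional linear drift of the mean, emulating the slow
  positive/negative shifts of a cis prolyl bond's omega angle under
  changing interactions (e.g. a mean drifting from -6.3 to +2.7 degrees).

All generators are deterministic given their seed.  None of this is
molecular dynamics: the trajectories are geometry plus noise, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import EnergyTerms, NonbondedParams, coulomb_pair, lj_pair
from .errors import ConstructionError, ValidationError
from .geometry import OmegaSeries, minimum_image_distance, select, wrap_angle
from .model_io import Atom, Frame, Residue, Structure, Trajectory

# Ideal backbone internal coordinates (nm / degrees); any chemically
# reasonable constants satisfy the dihedral round-trip contract.
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 120.0
ANGLE_C_N_CA = 120.0

_ELEMENT_MASS = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008}


def _place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place point d with |cd| = length, angle(b,c,d) and dihedral(a,b,c,d).

    Torsion follows the package's dihedral sign convention (IUPAC,
    right-hand rule about b->c).
    """
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ConstructionError("collinear reference atoms in peptide builder")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    return c + length * (
        -np.cos(theta) * bc_hat
        + np.sin(theta) * (np.cos(tau) * m_hat + np.sin(tau) * n_hat)
    )


def _per_bond(values, n: int, default: float, what: str) -> list[float]:
    if values is None:
        return [default] * n
    if np.isscalar(values):
        values = [float(values)] * n
    values = [float(v) for v in values]
    if len(values) != n:
        raise ValidationError(f"need {n} {what} values, got {len(values)}")
    for v in values:
        if not (-180.0 < v <= 180.0):
            raise ValidationError(f"{what} angle {v} outside (-180, 180]")
    return values


def make_peptide(
    n_residues: int,
    omega=None,
    phi=None,
    psi=None,
    chain_id: str = "A",
) -> Structure:
    """Idealized backbone (N, CA, C per residue) with prescribed dihedrals.

    ``omega`` has one value per peptide bond (n_residues - 1), ``phi``/
    ``psi`` one value per residue (terminal phi/psi requests are accepted
    but only interior ones are geometrically realised).  Scalars broadcast;
    defaults are the extended chain (omega = phi = psi = 180).  Measured
    dihedrals equal the requested values to within 1e-6 degrees.
    """
    if n_residues < 2:
        raise ValidationError("need at least 2 residues for a peptide bond")
    omegas = _per_bond(omega, n_residues - 1, 180.0, "omega")
    phis = _per_bond(phi, n_residues, 180.0, "phi")
    psis = _per_bond(psi, n_residues, 180.0, "psi")

    coords: list[np.ndarray] = []
    # First residue in a fixed frame: N at origin, CA along +x, C in the
    # xy-plane at the ideal N-CA-C angle.
    coords.append(np.zeros(3))                                # N1
    coords.append(np.array([BOND_N_CA, 0.0, 0.0]))            # CA1
    th = np.radians(180.0 - ANGLE_N_CA_C)
    coords.append(coords[1] + BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0]))  # C1

    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, omegas[i - 1])
        c_i = _place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords.extend([n_i, ca_i, c_i])

    residues = []
    k = 0
    for i in range(n_residues):
        res = Residue(index=i + 1, name="ALA", chain_id=chain_id)
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C")):
            res.atoms.append(
                Atom(serial=k + 1, name=name, element=elem,
                     mass=_ELEMENT_MASS[elem], index=k)
            )
            k += 1
        residues.append(res)
    return Structure(residues=residues, positions=np.array(coords))


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

_MIN_SEPARATION = 0.1  # nm
_MAX_TRIES = 500


def make_toy_complex(
    n_atoms_a: int,
    n_atoms_b: int,
    box=2.5,
    seed: int = 0,
    atoms_per_residue: int = 2,
) -> Structure:
    """Random two-molecule complex with attached nonbonded parameters.

    Chains "A" and "B" in a rectangular periodic box (nm); atoms are placed
    uniformly with a 0.1 nm minimum-image separation floor.  Charges are
    uniform in [-1, 1] e, shifted so each molecule carries an integer net
    charge; sigma in [0.25, 0.35] nm, epsilon in [0.1, 1.0] kJ/mol, mass
    12 u.  Deterministic given ``seed``.
    """
    if n_atoms_a < 1 or n_atoms_b < 1:
        raise ValidationError("both molecules need at least one atom")
    box = np.full(3, float(box)) if np.isscalar(box) else np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    n = n_atoms_a + n_atoms_b

    positions = None
    for _ in range(_MAX_TRIES):
        cand = rng.uniform(0.0, box, size=(n, 3))
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if minimum_image_distance(cand[i], cand[j], box) < _MIN_SEPARATION:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            positions = cand
            break
    if positions is None:
        raise ConstructionError(
            f"could not place {n} atoms with {_MIN_SEPARATION} nm separation "
            f"in box {box} after {_MAX_TRIES} attempts"
        )

    charges = rng.uniform(-1.0, 1.0, size=n)
    for sl in (slice(0, n_atoms_a), slice(n_atoms_a, n)):
        total = charges[sl].sum()
        charges[sl] += (round(total) - total) / (sl.stop - sl.start)
    sigmas = rng.uniform(0.25, 0.35, size=n)
    epsilons = rng.uniform(0.1, 1.0, size=n)

    residues = []
    k = 0
    for chain, n_atoms in (("A", n_atoms_a), ("B", n_atoms_b)):
        placed = 0
        resid = 0
        while placed < n_atoms:
            resid += 1
            res = Residue(index=resid, name="TOY", chain_id=chain)
            for j in range(min(atoms_per_residue, n_atoms - placed)):
                res.atoms.append(
                    Atom(
                        serial=k + 1,
                        name=f"X{j + 1}",
                        element="C",
                        mass=12.0,
                        charge=charges[k],
                        lj_sigma=sigmas[k],
                        lj_epsilon=epsilons[k],
                        index=k,
                    )
                )
                k += 1
                placed += 1
            residues.append(res)
    return Structure(residues=residues, positions=positions, box=box)


def make_complex_trajectory(
    structure: Structure,
    n_frames: int,
    jitter_sd: float = 0.01,
    seed: int = 0,
    dt: float = 1.0,
) -> Trajectory:
    """Trajectory of Gaussian positional jitter around a structure.

    Frame k has time k*dt and positions perturbed by isotropic N(0,
    jitter_sd^2) noise (nm).  Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise ValidationError("need at least one frame")
    rng = np.random.default_rng(seed)
    frames = [
        Frame(
            time=k * dt,
            positions=structure.positions
            + rng.normal(0.0, jitter_sd, size=structure.positions.shape),
            box=structure.box,
        )
        for k in range(n_frames)
    ]
    return Trajectory(topology=structure, frames=frames)


# ---------------------------------------------------------------------------
# omega ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmegaEnsembleSpec:
    """Wrapped-normal omega ensemble: n_trajectories series of n_frames.

    With ``drift_to`` set, the underlying mean moves linearly from ``mean``
    to ``drift_to`` across the frames of every trajectory.  ``sd`` is the
    (unwrapped) normal standard deviation in degrees.
    """

    n_trajectories: int
    n_frames: int
    mean: float          # degrees
    sd: float            # degrees
    drift_to: float | None = None
    seed: int = 0
    dt: float = 1.0      # time spacing of snapshots

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError("sd must be positive")
        if self.n_frames < 1 or self.n_trajectories < 1:
            raise ValidationError("need >= 1 frame and >= 1 trajectory")


def make_omega_ensemble(
    spec: OmegaEnsembleSpec,
    peptide_bond=(("H", 102), ("H", 103)),
) -> list[OmegaSeries]:
    """Sample an ensemble of independent wrapped-normal omega series."""
    rng = np.random.default_rng(spec.seed)
    if spec.drift_to is None:
        means = np.full(spec.n_frames, spec.mean)
    else:
        means = np.linspace(spec.mean, spec.drift_to, spec.n_frames)
    times = np.arange(spec.n_frames) * spec.dt
    out = []
    for _ in range(spec.n_trajectories):
        samples = wrap_angle(rng.normal(means, spec.sd))
        out.append(
            OmegaSeries(times=times.copy(), angles=np.atleast_1d(samples),
                        peptide_bond=peptide_bond)
        )
    return out


# ---------------------------------------------------------------------------
# brute-force energy oracle
# ---------------------------------------------------------------------------

def brute_force_energy(
    structure: Structure,
    frame: Frame,
    group_a,
    group_b,
    params: NonbondedParams = NonbondedParams(),
) -> EnergyTerms:
    """O(N^2) scalar-loop reference for the group interaction energy.

    Same physics and exclusion rule as ``energetics.group_energy`` (same
    chain and residue separation < 2 excluded) but computed pair by pair
    with the scalar potentials and scalar minimum-image distances — an
    independent summation path used as the test oracle.
    """
    ia = select(structure, group_a)
    ib = select(structure, group_b)
    arrays = structure.param_arrays()
    coul = 0.0
    lj = 0.0
    for i in ia:
        for j in ib:
            if (
                arrays["chain"][i] == arrays["chain"][j]
                and abs(arrays["resid"][i] - arrays["resid"][j]) < 2
            ):
                continue
            r = minimum_image_distance(
                frame.positions[i], frame.positions[j], frame.box
            )
            coul += coulomb_pair(r, arrays["charge"][i], arrays["charge"][j], params)
            lj += lj_pair(
                r,
                0.5 * (arrays["sigma"][i] + arrays["sigma"][j]),
                float(np.sqrt(arrays["epsilon"][i] * arrays["epsilon"][j])),
                params,
            )
    return EnergyTerms(coulomb=coul, lj=lj)
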