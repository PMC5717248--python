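import numpy as np
import pytest
from hypothesis import settings

from cistraj.model_io import Atom, Frame, Residue, Structure

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def frame_of(structure: Structure) -> Frame:
    return Frame(time=0.0, positions=structure.positions, box=structure.box)


def point_structure(points, chain_ids=None, names=None, elements=None, masses=None):
    """One single-atom residue per point; convenient for geometry tests."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    chain_ids = chain_ids or ["A"] * n
    names = names or [f"X{i+1}" for i in range(n)]
    elements = elements or ["C"] * n
    masses = masses if masses is not None else [12.0] * n
    residues = []
    counters = {}
    for i in range(n):
        counters[chain_ids[i]] = counters.get(chain_ids[i], 0) + 1
        residues.append(
            Residue(
                index=counters[chain_ids[i]],
                name="TOY",
                chain_id=chain_ids[i],
                atoms=[
                    Atom(
                        serial=i + 1,
                        name=names[i],
                        element=elements[i],
                        mass=masses[i],
                        index=i,
                    )
                ],
            )
        )
    return Structure(residues=residues, positions=points)


@pytest.fixture
def toy_complex():
    from cistraj.synthetic import make_toy_complex

    return make_toy_complex(12, 12, box=2.5, seed=11)


def end_to_end_inputs(dirpath, n_frames=12, seed=0):
    """Write a complete synthetic input set and return a pipeline config dict.

    Chain A is a 3-residue peptide whose first omega angle drifts from -20
    to +20 degrees across the frames (so the windowed mean changes sign);
    chain B is a small probe molecule carrying an N-H donor aimed at the
    peptide's N-terminal nitrogen plus a lone O acceptor.
    """
    from pathlib import Path

    import yaml

    from cistraj.geometry import min_residue_distance
    from cistraj.model_io import (
        Frame,
        ResiduePair,
        ResiduePairList,
        Structure,
        Trajectory,
        write_pair_list,
        write_structure,
        write_topology_params,
        write_trajectory,
    )
    from cistraj.synthetic import make_peptide

    dirpath = Path(dirpath)
    rng = np.random.default_rng(seed)
    omegas = np.linspace(-20.0, 20.0, n_frames)

    def build_positions(omega, jitter=None):
        pep = make_peptide(3, omega=[omega, 180.0])
        probe = np.array(
            [
                [-0.29, 0.0, 0.0],   # B:1 N (donor, aimed at peptide N1 at origin)
                [-0.19, 0.0, 0.0],   # B:1 H
                [-0.50, 0.3, 0.0],   # B:2 O
            ]
        )
        if jitter is not None:
            probe = probe + jitter
        return np.vstack([pep.positions, probe]), pep

    pos0, pep0 = build_positions(omegas[0])
    n_pep = pep0.n_atoms
    residues = list(pep0.residues)
    probe_spec = [
        (1, "N", "N", 14.007, -0.3, 0.30, 0.40),
        (1, "H", "H", 1.008, 0.3, 0.10, 0.10),
        (2, "O", "O", 15.999, 0.0, 0.30, 0.40),
    ]
    probe_residues = {}
    for k, (resid, name, elem, mass, charge, sig, eps) in enumerate(probe_spec):
        r = probe_residues.setdefault(
            resid, Residue(index=resid, name="PRB", chain_id="B")
        )
        r.atoms.append(
            Atom(
                serial=n_pep + k + 1,
                name=name,
                element=elem,
                mass=mass,
                charge=charge,
                lj_sigma=sig,
                lj_epsilon=eps,
                index=n_pep + k,
            )
        )
    residues += list(probe_residues.values())
    # modest charges on the peptide backbone, zero net per residue
    for r in residues[:3]:
        for a, q in zip(r.atoms, (0.1, -0.1, 0.0)):
            a.charge, a.lj_sigma, a.lj_epsilon = q, 0.30, 0.40
    topology = Structure(residues=residues, positions=pos0, box=np.full(3, 4.0))

    frames = []
    for k, omega in enumerate(omegas):
        jitter = rng.normal(0.0, 0.003, size=(3, 3))
        pos, _ = build_positions(omega, jitter)
        frames.append(Frame(time=float(k), positions=pos, box=topology.box))
    traj = Trajectory(topology=topology, frames=frames)

    write_structure(topology, dirpath / "topology.pdb")
    write_topology_params(topology, dirpath / "params.tsv", net_charge_chains=("A", "B"))
    write_trajectory(traj, dirpath / "traj.pdb")
    pairs = ResiduePairList(
        [
            ResiduePair(("A", 1), ("B", 1),
                        min_residue_distance(topology, frames[0], ("A", 1), ("B", 1))),
            ResiduePair(("A", 3), ("B", 2),
                        min_residue_distance(topology, frames[0], ("A", 3), ("B", 2))),
        ]
    )
    write_pair_list(pairs, dirpath / "pairs.tsv")

    config = {
        "topology": str(dirpath / "topology.pdb"),
        "parameters": str(dirpath / "params.tsv"),
        "trajectories": [str(dirpath / "traj.pdb")],
        "pair_list": str(dirpath / "pairs.tsv"),
        "molecule_a": "A",
        "molecule_b": "B",
        "omega": {"chain": "A", "residue": 1},
        "rama": {"chain": "A"},
        "contact": {"res_a": "A:1", "res_b": "A:3"},
        "windows": [[0, n_frames // 2 - 1], [n_frames // 2, n_frames - 1]],
        "correlate_window": n_frames // 4,
        "out_dir": str(dirpath / "out"),
        "seed": seed,
    }
    (dirpath / "config.yaml").write_text(yaml.safe_dump(config))
    return config
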