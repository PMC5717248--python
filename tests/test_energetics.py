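"""Nonbonded pair potentials, group energies, breakdowns, pose bins."""

import numpy as np
import pytest

from cistraj.energetics import (
    COULOMB_CONSTANT,
    EnergyTerms,
    NonbondedParams,
    classify_pose,
    coulomb_pair,
    group_energy,
    lj_pair,
    residue_breakdown,
    window_average,
)
from cistraj.errors import SelectionError, ValidationError
from cistraj.model_io import Atom, Frame, Residue, Structure, Trajectory
from cistraj.synthetic import brute_force_energy, make_toy_complex

from conftest import frame_of

P = NonbondedParams()


# -- pair potentials --------------------------------------------------------

def test_coulomb_pair_values():
    assert coulomb_pair(0.5, 1.0, 1.0, P) == pytest.approx(277.870916, abs=1e-6)
    assert coulomb_pair(1.5, 3.0, -2.0, P) == 0.0          # beyond cutoff
    assert coulomb_pair(0.3, 0.0, 1.0, P) == 0.0           # zero charge
    with pytest.raises(ValidationError):
        coulomb_pair(0.0, 1.0, 1.0, P)


def test_lj_pair_zero_crossing_minimum_and_switch_off():
    sigma, eps = 0.3, 0.5
    assert lj_pair(sigma, sigma, eps, P) == pytest.approx(0.0, abs=1e-12)
    r_min = 2 ** (1 / 6) * sigma
    assert r_min < P.lj_switch_start
    assert lj_pair(r_min, sigma, eps, P) == pytest.approx(-eps, rel=1e-12)
    assert lj_pair(0.95, sigma, eps, P) == 0.0             # beyond switch end
    with pytest.raises(ValidationError):
        lj_pair(0.0, sigma, eps, P)


def test_lj_switch_is_c1_continuous_at_both_boundaries():
    sigma, eps = 0.34, 0.8
    h = 1e-6
    for r0 in (P.lj_switch_start, P.lj_switch_end):
        # value continuity
        below = lj_pair(r0 - h, sigma, eps, P)
        above = lj_pair(r0 + h, sigma, eps, P)
        assert above == pytest.approx(below, abs=1e-6)
        # one-sided numerical derivatives agree
        d_below = (lj_pair(r0 - h, sigma, eps, P) - lj_pair(r0 - 2 * h, sigma, eps, P)) / h
        d_above = (lj_pair(r0 + 2 * h, sigma, eps, P) - lj_pair(r0 + h, sigma, eps, P)) / h
        assert d_above == pytest.approx(d_below, abs=1e-3)


def test_nonbonded_params_validation():
    with pytest.raises(ValidationError):
        NonbondedParams(lj_switch_start=0.9, lj_switch_end=0.8)
    with pytest.raises(ValidationError):
        NonbondedParams(lj_switch_end=1.5, r_cut_coulomb=1.0)


# -- group energies ---------------------------------------------------------

def _pair_system(r, q1=0.1, q2=0.2, sigma=0.3, eps=0.4, box=None):
    residues = [
        Residue(index=1, name="TOY", chain_id="A",
                atoms=[Atom(1, "X1", "C", 12.0, q1, sigma, eps, index=0)]),
        Residue(index=1, name="TOY", chain_id="B",
                atoms=[Atom(2, "X1", "C", 12.0, q2, sigma, eps, index=1)]),
    ]
    pos = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return Structure(residues=residues, positions=pos, box=box)


def test_two_single_atom_groups_equal_scalar_pair_sum():
    s = _pair_system(0.45)
    e = group_energy(s, frame_of(s), "A", "B", P)
    assert e.coulomb == pytest.approx(coulomb_pair(0.45, 0.1, 0.2, P), rel=1e-12)
    assert e.lj == pytest.approx(lj_pair(0.45, 0.3, 0.4, P), rel=1e-12)
    assert e.total == e.coulomb + e.lj


def test_groups_beyond_all_cutoffs_have_zero_energy():
    s = _pair_system(1.2)
    e = group_energy(s, frame_of(s), "A", "B", P)
    assert e.total == 0.0


def test_group_energy_symmetric_and_disjointness_enforced(toy_complex):
    f = frame_of(toy_complex)
    ab = group_energy(toy_complex, f, "A", "B", P)
    ba = group_energy(toy_complex, f, "B", "A", P)
    assert ab.total == pytest.approx(ba.total, rel=1e-12)
    with pytest.raises(SelectionError):
        group_energy(toy_complex, f, "A", "A:1", P)


def test_group_energy_matches_brute_force(toy_complex):
    f = frame_of(toy_complex)
    fast = group_energy(toy_complex, f, "A", "B", P)
    slow = brute_force_energy(toy_complex, f, "A", "B", P)
    assert fast.coulomb == pytest.approx(slow.coulomb, rel=1e-12)
    assert fast.lj == pytest.approx(slow.lj, rel=1e-12)


def test_charge_scaling_scales_coulomb_quadratically(toy_complex):
    f = frame_of(toy_complex)
    base = group_energy(toy_complex, f, "A", "B", P)
    lam = 0.5
    for _, a in toy_complex.atoms():
        a.charge *= lam
    scaled = group_energy(toy_complex, f, "A", "B", P)
    assert scaled.coulomb == pytest.approx(lam**2 * base.coulomb, rel=1e-12)
    assert scaled.lj == pytest.approx(base.lj, rel=1e-12)


def test_same_chain_near_neighbours_excluded():
    # two residues 1 and 2 in one chain: separation < 2 -> no interaction
    residues = [
        Residue(index=1, name="TOY", chain_id="A",
                atoms=[Atom(1, "X1", "C", 12.0, 1.0, 0.3, 0.4, index=0)]),
        Residue(index=2, name="TOY", chain_id="A",
                atoms=[Atom(2, "X1", "C", 12.0, 1.0, 0.3, 0.4, index=1)]),
        Residue(index=4, name="TOY", chain_id="A",
                atoms=[Atom(3, "X1", "C", 12.0, 1.0, 0.3, 0.4, index=2)]),
    ]
    pos = np.array([[0.0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
    s = Structure(residues=residues, positions=pos)
    f = frame_of(s)
    e12 = group_energy(s, f, ("A", 1), ("A", 2), P)
    assert e12.total == 0.0
    e14 = group_energy(s, f, ("A", 1), ("A", 4), P)
    assert e14.total == pytest.approx(
        coulomb_pair(0.8, 1.0, 1.0, P) + lj_pair(0.8, 0.3, 0.4, P), rel=1e-12
    )


# -- window average ---------------------------------------------------------

def test_window_average_cases():
    assert window_average([1, 2, 3], [1.0, 2.0, 3.0], (2, 3)) == pytest.approx(2.5)
    assert window_average([0, 1, 2], [7.0, 7.0, 7.0], (0, 2)) == 7.0
    assert window_average([0, 1, 2], [1.0, 5.0, 9.0], (1, 1)) == 5.0
    with pytest.raises(ValidationError):
        window_average([0, 1], [1.0, 2.0], (5, 6))


# -- residue breakdown ------------------------------------------------------

def _distance_controlled_trajectories(energies):
    """One trajectory per requested energy: a single +q/+q' pair placed at
    the distance whose truncated-Coulomb energy equals that value (no LJ)."""
    q1q2 = 0.001
    trajs = []
    for e in energies:
        r = COULOMB_CONSTANT * q1q2 / e
        s = _pair_system(r, q1=0.001, q2=1.0, sigma=0.0, eps=0.0)
        trajs.append(Trajectory(topology=s, frames=[frame_of(s)]))
    return trajs


def test_breakdown_mean_and_standard_error_across_trajectories():
    trajs = _distance_controlled_trajectories([1.0, 3.0])
    bd = residue_breakdown(trajs, "A", "B", (0, 0), side="a")
    stats = bd.entries[("A", 1, "TOY")]
    assert stats.mean == pytest.approx(2.0, rel=1e-9)
    assert stats.se == pytest.approx(1.0, rel=1e-9)  # sd([1,3])/sqrt(2)
    assert stats.n_trajectories == 2


def test_breakdown_single_trajectory_has_zero_se(toy_complex):
    from cistraj.synthetic import make_complex_trajectory

    traj = make_complex_trajectory(toy_complex, 3, seed=8)
    bd = residue_breakdown([traj], "A", "B", (0, 2), side="a")
    assert all(s.se == 0.0 for s in bd.entries.values())


def test_breakdown_sums_to_whole_molecule_total(toy_complex):
    from cistraj.synthetic import make_complex_trajectory

    trajs = [make_complex_trajectory(toy_complex, 4, seed=s) for s in (1, 2, 3)]
    window = (0, 3)
    for side in ("a", "b"):
        bd = residue_breakdown(trajs, "A", "B", window, side=side)
        whole = np.mean(
            [
                np.mean(
                    [group_energy(toy_complex, f, "A", "B", P).total for f in t.frames]
                )
                for t in trajs
            ]
        )
        assert bd.total_mean() == pytest.approx(whole, rel=1e-9)


def test_breakdown_residue_out_of_range_is_zero():
    # molecule B far beyond every cutoff from A: all means and SEs zero
    s = _pair_system(2.0)
    trajs = [Trajectory(topology=s, frames=[frame_of(s)]) for _ in range(2)]
    bd = residue_breakdown(trajs, "A", "B", (0, 0), side="a")
    stats = bd.entries[("A", 1, "TOY")]
    assert stats.mean == 0.0 and stats.se == 0.0


def test_breakdown_empty_window_rejected(toy_complex):
    from cistraj.synthetic import make_complex_trajectory

    traj = make_complex_trajectory(toy_complex, 3, seed=8)
    with pytest.raises(ValidationError):
        residue_breakdown([traj], "A", "B", (10, 20), side="a")


# -- pose bins --------------------------------------------------------------

@pytest.mark.parametrize(
    "e,label",
    [
        (-877.0, "<=-800"),
        (-800.0, "<=-800"),
        (-750.0, "(-800,-700]"),
        (-700.0, "(-800,-700]"),
        (-650.0, "(-700,-600]"),
        (-550.0, "(-600,-500]"),
        (-450.0, "(-500,-400]"),
        (-400.0, "(-500,-400]"),
        (-350.0, ">-400"),
        (10.0, ">-400"),
    ],
)
def test_pose_bins_partition_the_line(e, label):
    assert classify_pose(e) == label
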