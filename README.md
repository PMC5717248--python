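# cistraj

Trajectory analysis of prolyl cis–trans isomerisation in antibody CDR loops.

Proline is the one amino acid whose peptide bond populates both the cis and
the trans conformer, and antibodies can exploit this: in some
antigen–antibody systems a proline in the third heavy-chain
complementarity-determining region (CDR-H3) switches conformer upon antigen
binding. Detecting and explaining such a switch from simulation output
requires a specific set of post-processing steps, and `cistraj` packages
them for structural bioinformaticians working on antibody–antigen
complexes:

- **ω-angle statistics** — the peptide-bond dihedral
  ω = Cα(i)–C(i)–N(i+1)–Cα(i+1) per frame, classified as cis (|ω| small),
  trans (|ω| near 180°) or twisted (|ω| near the 90° transition state),
  with normalized 1°-binned distributions, windowed circular means, drift
  detection and distance–ω correlation;
- **crystal-similarity pose scoring** — for a list of antigen/antibody
  residue pairs with reference crystal minimum distances r_pair^crystal,

      score = sqrt( Σ_pairs (r_pair − r_pair^crystal)² / N_pairs )   [nm]

  the RMS deviation of pair minimum distances, used to rank candidate
  bound poses (lower = more crystal-like);
- **per-residue interaction-energy decomposition** — short-range nonbonded
  energies E_int = E_Coulomb + E_LJ between two molecules, with a sharp
  1.0 nm Coulomb cutoff, a Lennard-Jones potential switched smoothly to
  zero over 0.8–0.9 nm, Lorentz–Berthelot combining rules and
  minimum-image periodic distances; residue-by-residue breakdowns with
  means and standard errors across independent trajectories, and
  interaction-energy pose bins;
- **geometry utilities** — minimum-image distances, residue–residue
  minimum-distance time courses, Ramachandran φ/ψ series, centres of mass,
  geometric hydrogen-bond detection;
- **synthetic data with known ground truth** — peptide backbones with
  prescribed dihedrals, charged toy complexes in periodic boxes with an
  O(N²) brute-force energy oracle, and wrapped-normal ω ensembles with
  optional mean drift, so every operation is testable without simulation
  data.

Structures are read from PDB or GRO (via MDAnalysis), trajectories from
multi-model PDB; per-atom masses, charges and Lennard-Jones parameters come
from a plain TSV table. All internal units are nm / ps / u / e / kJ·mol⁻¹.

## Worked example

Emulate an ensemble of three independent trajectories whose cis-proline ω
angle drifts from −6.3° towards +2.7° (wrapped-normal noise, sd 8°), then
ask whether the windowed mean changes sign:

```python
import numpy as np
from cistraj import (
    OmegaEnsembleSpec, make_omega_ensemble, windowed_mean_omega,
    classify_omega, omega_distribution,
)

spec = OmegaEnsembleSpec(n_trajectories=3, n_frames=5000, mean=-6.3, sd=8.0,
                         drift_to=2.7, seed=42)
ensemble = make_omega_ensemble(spec)
windows = [(0, 499), (4500, 4999)]          # first and last tenth
for k, series in enumerate(ensemble):
    early, late = windowed_mean_omega(series, windows)
    print(f"trajectory {k}: early mean {early:+6.2f} deg ({classify_omega(early)}), "
          f"late mean {late:+6.2f} deg ({classify_omega(late)})")

dist = omega_distribution(ensemble[0], window=(4500, 4999))
peak = dist.edges[:-1][np.argmax(dist.heights)]
print(f"late-window distribution: peak bin [{peak:g}, {peak+1:g}) deg, "
      f"height {dist.heights.max():.3f}, total mass {dist.heights.sum():.1f}")
```

Output:

```
trajectory 0: early mean  -5.96 deg (cis), late mean  +1.81 deg (cis)
trajectory 1: early mean  -5.59 deg (cis), late mean  +2.20 deg (cis)
trajectory 2: early mean  -6.16 deg (cis), late mean  +2.45 deg (cis)
late-window distribution: peak bin [4, 5) deg, height 0.064, total mass 1.0
```

Every trajectory starts with a clearly negative mean ω and ends positive —
the signature of the bond being twisted towards the isomerisation
direction — while never leaving the cis basin (|ω| ≪ 60°). The late-window
distribution is a proper probability mass function (heights sum to 1) with
its mode near the drift target.

## Command-line pipeline

All analyses are also exposed as pipeline stages driven by one YAML config
(inputs, windows, thresholds; every default is echoed into the output
summary):

```bash
cistraj run --config analysis.yaml --stages score,energy,breakdown,omega
cistraj omega --config analysis.yaml --out results/
```

Each stage writes tidy CSVs plus a `summary.json`; re-running with the same
config and inputs is byte-identical. Exit codes: 0 success,
2 configuration error, 1 computation error.

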