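# dntpore

Analysis pipeline for simulations of **membrane-spanning DNA nanotubes**
(DNTs) — synthetic nanopores built from six interconnected B-DNA duplexes,
anchored in a lipid bilayer by hydrophobic (ethylated) surface bands. It is
aimed at people who run coarse-grained or atomistic MD of DNA nanopores in
membranes and want the full structural/functional analysis stack as tested,
reusable code:

* **Pore geometry** — HOLE-style largest-inscribed-sphere radius profiles
  R(z) per frame and time-averaged (mean ± SD), and ohmic conductance
  prediction from them,
  g_PORE = πR²/(ρL) or its series form 1/g = (ρ/π)·∫dz/R(z)².
* **Bilayer perturbation** — radial number densities and phosphate–phosphate
  thickness in 0.1 nm × 4 nm cylindrical shells around the pore axis,
  lipid-tail order parameters S = ⟨(3cos²θ − 1)/2⟩ on 1 × 1 nm² grids,
  DNA–lipid radial distribution functions, lumen Na⁺:Cl⁻ selectivity.
* **Dynamics** — lipid residence times at the DNA grooves (0.5 nm contact
  cutoff), tube tilt distributions, centre-of-mass displacement
  relaxation/exit classification, steered-MD force-profile barrier
  extraction (with kJ mol⁻¹ nm⁻¹ → pN conversion), transmembrane vs
  outside-the-membrane r.m.s.d., membrane surface deformation tracks.
* **Model building** — an idealized six-duplex tube on a hexagonal grid
  (inter-helix spacing d = 2.0 nm), hydrophobic band layouts, and an
  elastic-network specification.
* **Synthetic data** — generators for membrane/DNT trajectories, SMD force
  traces and displacement traces with recorded ground truth, so the whole
  pipeline is exercisable and testable without any MD run.

Input structures and trajectories are read with MDAnalysis/mdtraj
(PDB, GRO, multi-frame PDB/GRO, XTC); bead/atom names are mapped to semantic
roles through editable YAML "dialects" (`cg-martini`, `at-charmm-like`
bundled). All outputs are CSV/JSON with units and a config hash.

## Worked example

Generate a synthetic DNT-in-bilayer trajectory (18 × 18 × 25 nm box, 400
POPC lipids per leaflet, lumen cation:anion ratio 14, bilayer thinning
h(r) = h0 − A·e^(−(r−r_wall)/λ) with h0 = 4.0, A = 0.8, λ = 1.0 nm) and run
the core analyses:

```python
from dntpore.synth import MembraneSystemParams, generate_membrane_system
from dntpore.membrane import thickness_profile, fit_thinning, ion_selectivity
from dntpore.pore import pore_profile_over_time, conductance_estimate

params = MembraneSystemParams(seed=1)
traj, gt = generate_membrane_system(params, n_frames=10)

prof = pore_profile_over_time(traj, z_range=(-4, 4), dz=0.2, seed=1)
est = conductance_estimate(prof, resistivity_ohm_cm=8.9)  # 1.0 M KCl
r, th = thickness_profile(traj, shell_width=0.1)
h0, a, lam = fit_thinning(r, th, gt["wall_radius"])
sel = ion_selectivity(traj, lumen_radius=gt["lumen_radius"],
                      lumen_half_length=gt["tube_length"] / 2)
```

This prints:

```
TM pore radius:  0.86 nm
g (1.0 M KCl):   3.14 nS  (series integral, L = 8.0 nm)
thinning fit:    h0 = 4.01 nm, A = 0.74 nm, lambda = 1.12 nm
lumen Na+:Cl-:   14.0  (95% CI 11.4-17.3)
```

Reading the numbers: the transmembrane lumen stays open at ~0.9 nm radius
(the ideal six-duplex tube has a 1.0 nm open lumen; bead radii and thermal
jitter narrow it slightly), giving a single-pore conductance of a few nS in
1.0 M KCl. The thickness fit recovers the generator's thinning amplitude and
decay length within ~10 %, and the lumen ion ratio recovers the generated
cation selectivity inside its binomial confidence interval.

The same analyses run from the command line on files:

```bash
dntpore build --band-layout 7-band --out model/       # idealized tube + bands
dntpore synth --n-frames 10 --seed 1 --out system/    # synthetic trajectory
dntpore run pipeline.yaml --out results/              # configured multi-stage run
```

## Documentation

`docs/methods.md` describes the models, conventions, defaults and numerical
choices in detail, including what the synthetic-data validation does and
does not demonstrate about real simulation data.
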