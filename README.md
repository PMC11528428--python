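# smlmeq

Protein–protein **association (K_a)** and **dissociation (K_d)** equilibrium
constants measured *in situ* from single-molecule localization microscopy
(SMLM) data.

Many protein interactions happen in two dimensions (membranes) or between a
membrane and the cytosol, where solution-phase techniques do not apply. With
a quantitative SMLM map — e.g. DNA-PAINT data counted by qPAINT — the
equilibrium constant follows directly from counting associated and isolated
molecules and measuring the area they occupy:

```
A + B <-> AB          K_a = [AB] / ([A]·[B])
```

with concentrations per unit surface, so that

```
K_a = n_pairs · A / (n_free_A · n_free_B)        (µm² scale)
```

For membrane–cytosol dissociation the occupied area times the TIRF
illumination depth (100–250 nm) converts surface counts to molar
concentrations, giving `K_d = c_free_ligand · n_free_receptor / n_pairs`.

The package implements the complete analysis chain plus the simulation
engine used to validate it:

- **`locio`** — localization tables (CSV, Picasso-style HDF5) and molecule
  maps; nm / µm² / s internal units; YAML run configuration.
- **`qpaint`** — qPAINT molecular counting: localization clustering, dark
  times, qPAINT indexes (QPI = 1/mean dark time), Gaussian-mixture fit of
  the QPI histogram with peaks constrained to integer multiples of the
  single-site QPI, and spatial splitting of multi-molecule clusters.
- **`pattern`** — the occupied area accessible to the molecules, from three
  estimators parametrized by the mean first nearest-neighbor distance
  (µ_NND): Delaunay tessellation (triangles with area ≤ (F_D·µ_NND)²),
  Voronoi tessellation (bounded cells ≤ (F_V·µ_NND)²), and **ks-density**, a
  Gaussian kernel surface density with σ = F_K·µ_NND thresholded at
  TH = c/(2πσ²N) so isolated molecules and voids are excluded; pixel-wise
  confusion/F1 scoring against ground truth.
- **`equilibrium`** — NND distributions, complete-spatial-randomness (CSR)
  references, proximity-threshold scans, exclusive greedy pair matching,
  K_a / K_d computation, infinite-dilution extrapolation, stepwise cluster
  constants K_a,j = [N_j/(N_{j−1}·N_1)]·A, and Langmuir-type cluster
  occupancy.
- **`simulate`** — cell-shaped patterns with two species placed at
  mass-action equilibrium (densities ~120–400 µm⁻², log K_a from −3 to 0 on
  the µm² scale), localization noise, and DNA-PAINT blinking traces.
- **`cli`** — `smlmeq simulate | area | qpaint | associate | extrapolate |
  clusters | validate-grid`, all seeded, with JSON reports.

## Worked example

Simulate a 100 µm² cell-shaped region at 160 molecules/µm² with
log K_a = −2, recover the pattern with ks-density, and estimate K_a:

```python
import smlmeq as sq

gt, frame = sq.simulate_field(160.0, -2.0, pattern_area_um2=100.0, seed=7)
rec = sq.recover_cell(gt, frame, "ksdensity")
res = rec["result"]
print(f"recovered area: {rec['mask'].area_um2:.1f} um2, F1 = {rec['f1']:.3f}")
print(f"pairs: {res.n_pairs}, free A: {res.n_free_a}, free B: {res.n_free_b}")
print(f"log Ka = {res.log_k:.2f} (input -2.00)")
```

prints

```
recovered area: 88.7 um2, F1 = 0.936
pairs: 2912, free A: 5042, free B: 5045
log Ka = -1.99 (input -2.00)
```

i.e. from 16 000 simulated molecules the pipeline recovers the occupied
area (F1 = 0.94 against the true polygon) and the input affinity within
0.01 log units; across the full density × affinity validation grid the
recovery stays within ±0.3 (±0.4 in the worst high-density/low-affinity
corner). The same flow from the shell:

```sh
smlmeq simulate --density 160 --log-ka -2 --area-um2 100 --seed 7 --out-dir run/
smlmeq area --input run/molecules.csv --method ksdensity --out run/area.json
smlmeq associate --molecules run/molecules.csv --proximity 15 --out run/ka.json
```

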