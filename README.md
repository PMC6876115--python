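# fiducialign

Radiation-free registration of the intraoral dentoalveolar position to an
extraoral 3D facial surface, using extraoral fiducial geometries (sphere or
cross) mounted on a modified impression tray. The package provides the full
digital workflow in silico:

- **fiducial_factory** — parametric sphere/cross markers and their cylindrical
  mount, with binary + ASCII STL I/O (all units millimetres).
- **scan_sim** — a virtual structured-light scanner (surface densification,
  normal-directed Gaussian noise, Laplacian edge rounding, back-face coverage
  culling) plus deterministic face and dental-arch surrogate surfaces.
- **register** — Kabsch landmark fitting, point-to-point ICP with
  correspondence rejection and a guaranteed monotone RMS trace, rigid
  transform algebra, and the six-step chain that places maxilla and mandible
  models into the face-scan frame.
- **deviation** — exact point-to-triangle distances, nearest-point-on-surface
  queries, and surface-deviation RMSE reports with half-up table rounding.
- **meshops** — normal inversion (impression → positive counterfeit),
  connected components, declarative plane/box cropping.
- **stats** — exact Wilcoxon signed-rank and Mann–Whitney rank-sum tests by
  enumeration (ties and zero policies handled), summary tables, and the
  packaged per-participant RMSE fixture tables.
- **pipeline** — the six-step workflow on synthetic scenes with known ground
  truth, the sphere-vs-cross marker comparison experiments, repetition
  variance analysis, and fixture-table reproduction.

## CLI

```bash
fiducialign generate --kind sphere --out marker.stl --with-base
fiducialign scan-sim --in marker.stl --out scan.stl --sigma 0.05 --spacing 0.5 --smooth 3 --seed 42
fiducialign register --source scan.stl --target marker.stl \
    --landmarks-a a.pts --landmarks-b b.pts --out T.json
fiducialign deviate --source scan.stl --reference marker.stl --out report.json
fiducialign segment --in scan.stl --plane 0 0 1 5.0 --out part.stl
fiducialign invert --in impression.stl --out positive.stl
fiducialign stats --table table.csv --test rank-sum --out stats.json
fiducialign compare --n 10 --seed 7 --out table.csv
fiducialign pipeline --config run.yaml
fiducialign tables
```

Landmark files are plain text (`label x y z` per line, mm); transforms are
serialized as 4×4 row-major JSON matrices; workflow configs are YAML
(see `fiducialign.pipeline.WorkflowConfig` for the keys).

## Notes

- Everything is metric (mm); no scaling or reflection is ever fitted.
- The table1 fixture's cross column carries a reference mean of 0.36, while
  the arithmetic mean of its values is 0.354 (rounds to 0.35); `fiducialign
  tables` flags this cell as a mismatch by design.
- The per-participant RMSE magnitudes in the fixture tables derive from real
  human scans and are not reproducible in silico; they are covered by the
  packaged fixtures, while the simulation reproduces the qualitative result
  (sphere markers scan and register better than cross markers under
  edge-rounding distortion).
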