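# tsakit

Analysis toolkit for metallocarboxypeptidase complexes with N-sulfamoyl
transition-state analogs (SGlu, SArg, SPhe, SLeu), joining two tracks:

* **Geometry** — altloc-aware PDB/mmCIF reading, rigid superposition over
  all shared C-alpha atoms (SVD/Kabsch with proper-rotation correction),
  per-atom displacement tables between superposed complexes, and
  ligand-to-catalytic-subsite distance tables (Zn–S18 gap, the Glu277 and
  Tyr255 hydrogen bonds, the Arg129/Asn146/Arg147/Thr205 contacts).
* **Kinetics** — initial-rate Michaelis–Menten fitting (k_cat, K_M), the
  integrated-rate progress-curve linearization `t/ln(s0/s)` vs
  `(s0−s)/ln(s0/s)` giving apparent K_M/V_max, and competitive-inhibition
  K_I from `(K_M/V_max)app = (K_M/V_max)0 (1 + I/K_I)`.  The closed-form
  integrated Michaelis–Menten law (Wright-omega/Lambert-W) doubles as the
  simulator backbone and an analytic oracle.

A correlation stage joins per-ligand geometry and kinetics and quantifies
the affinity-vs-Zn–S-gap ordering; a seeded synthetic-data module makes
every stage testable offline.

## CLI

```sh
superpose --ref 6SN6.pdb --mobile 6GO2.pdb --table displacements.tsv \
          --write-transformed fitted.pdb
distances --pdb 6SN6.pdb --out distances.tsv        # 16 default rows
kifit --curves curves_dir/ --out ki.tsv             # progress-curve K_I
mmfit --csv rates.csv --enzyme-conc 1e-8 --out mm.tsv
simulate progress --config sim.yaml --out curves_dir/
correlate --out report.tsv --plot report.svg        # packaged fixtures
```

All commands are also subcommands of `tsakit`.  Progress-curve files are
delimited text with `#s0=`, `#I=`, optional `#epsilon=`/`#path_cm=` header
lines and `time_s` + (`substrate_M` | `absorbance_AU`) columns; absorbance
is converted with A = ε·l·c (default ε₂₂₅ = 376 M⁻¹cm⁻¹, 1 cm path).

## Layout

```
src/tsakit/
  structure_io.py   PDB/mmCIF reading (biotite-backed), atom addressing,
                    TSV/PDB writing
  geometry.py       Kabsch superposition, displacement & distance tables
  kinetics.py       MM fitting, progress-curve linearization, K_I
  ligands.py        ligand catalog, formula-weight utility
  simulate.py       seeded simulators (curves, rates, structure pairs)
  correlate.py      ligand-table join, rank correlation, report/plot
  datasets.py       deposited-entry access & fetch helper
  data/             packaged distance/kinetics fixtures
```
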