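# recepstruct

Post hoc structure–function analysis for engineered two-chain receptors.
Given predicted structure models (ectodomain–ligand complexes and
transmembrane-domain dimers, PDB format) and a per-design performance table,
the package quantifies six structural features and relates them to receptor
performance through a transparent linear-regression workflow.

## What it computes

**Structural features** (per receptor design):

| feature | units | definition |
| --- | --- | --- |
| `ecd_distance` | Å | Cα–Cα distance between the last secondary-structure residue of each ectodomain chain |
| `ecd_contacts` | count | inter-chain atom pairs with vdW overlap ≥ −0.40 Å (signed cutoff, configurable) |
| `tmd_distance` | Å | Cα–Cα distance between the final residues of the TMD dimer |
| `tmd_contacts` | count | inter-chain vdW-overlap contacts between the two TMD helices |
| `tmd_crossing_angle` | degrees | signed inter-helix crossing angle (right-handed packing positive) |
| `tmd_exit_angle` | degrees | angle in [0°, 180°] between the membrane-plane projections of the final-residue Cα→C vectors |

Heterodimeric TMD pairs are measured in both chain orderings and averaged;
2α+2β receptor tetramers average ECD measurements over the two closest
α↔β chain pairings. Secondary structure is assigned with a hydrogen-bond
pattern method (Kabsch–Sander-style electrostatic energy, −0.5 kcal/mol
threshold).

**Regression workflow** (per receptor family): optional log10 of the
dependent variable (on-state signal or fold induction) → single-feature
regressions → Pearson correlation matrix → full OLS model on standardized
features → VIF screening (threshold 10) → backward elimination (α = 0.05)
→ reduced structural model; plus full/reduced one-hot categorical models
(every factor level encoded, no reference drop) and an optional combined
model. Every removal is recorded in a reduction trace and reports are
byte-deterministic.

A synthetic-data module generates ideal-helix structures with tunable
inter-chain geometry, enumerates combinatorial design spaces, and simulates
performance tables with planted coefficients, so the whole pipeline is
testable without any downloads.

## CLI

```bash
# end-to-end demo on a bundled synthetic family (~5 s)
recepstruct demo --out demo_out --seed 0

# extract features from a manifest of structure files
recepstruct features --manifest manifest.csv --out features.csv \
    [--overlap-cutoff -0.4] [--radii radii.yml] [--skip-errors]

# regression workflow on existing tables
recepstruct regress --features features.csv --performance perf.csv \
    --dv os --log-dv --family vegf --out report/

# both stages in one run (config file optional; flags override it)
recepstruct run --manifest manifest.csv --performance perf.csv --out out/

# synthetic structures / design tables
recepstruct simulate --kind dimer|ecd|family --spec spec.yml --seed 1 --out dir/
```

The manifest is a CSV with columns `design_id, structure_file,
receptor_chain_a, receptor_chain_b, ligand_chains, complex_kind,
tmd_file_ab, tmd_file_ba` (paths relative to the manifest; tetramers list
two `+`-separated chain ids per receptor side; `tmd_file_ba` is empty for
homodimeric TMD pairs). The performance table needs `design_id, os_meptr,
fi` plus the categorical columns `ntev_ecd, ntev_tmd, ctev_ecd, ctev_tmd,
ligand`.

Outputs: `features.csv`, `report.json` (machine-readable, includes the full
config snapshot and reduction traces), `report.md`, `coefficients.csv`,
`run.log`.

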