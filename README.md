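# mechcycle

Analysis pipeline for classifying an enzyme inhibitor's mechanism from
docking-derived equilibrium constants, and for quantifying α-amylase
inhibition from a starch-iodine assay, with the accompanying group
statistics.

The package implements three connected analyses:

1. **Inhibition-mode classification** (`mechcycle.mode_classifier`). For the
   four equilibria E+S⇌ES (K1), E+I⇌EI (Ka), EI+S⇌EIS (K4) and ES+I⇌ESI
   (Kb), thermodynamic-cycle closure forces `Kb = K4·Ka/K1`. A ligand whose
   directly estimated Kb agrees with the cycle prediction within a fold
   threshold (default 1.5) is classified *noncompetitive*; otherwise
   *competitive-or-uncompetitive* (the test cannot separate those two).
2. **Starch-iodine assay analysis** (`mechcycle.assay`). Absorbance pairs →
   activity units `(E_B1 − E_S)/E_B1 × 800` → % inhibition `(B − A)/B × 100`
   → maximum-likelihood probit regression on log10(concentration) → IC50 →
   replicate mean ± SEM. `mechcycle.thermo` converts between binding free
   energy, Ki, IC50 and mass concentration (Cheng–Prusoff family;
   `Ki = exp(ΔG/RT)` with R = 1.98719e-3 kcal·mol⁻¹·K⁻¹, T = 298.15 K).
3. **Group statistics** (`mechcycle.invivo_stats`). One-way ANOVA with
   Fisher LSD post-hoc comparisons, implemented from first principles.

`mechcycle.synthetic_data` generates every input with known ground truth:
labeled docking-constant sets, Michaelis–Menten-based assay plates (for the
noncompetitive model the implied IC50 equals Ki exactly, the identity the
pipeline must recover), and normally distributed group measurements.

Two reference fixtures ship with the package (`mechcycle/data/`): the
four-ligand docking-constant table (`table4.csv`) and the six replicate IC50
values of the extract assay (`table1.csv`).

## CLI

```bash
mechcycle classify --in docking.csv --threshold 1.5 --out results.csv
mechcycle assay --plate plate.csv --out report.json
mechcycle ic50 --in dose.csv --out fit.json [--plot curve.png]
mechcycle stats --in groups.csv --alpha 0.01
mechcycle simulate docking|assay|groups --seed N --out file.csv [--config sim.toml]
mechcycle reproduce            # recompute and verify the bundled reference results
```

Global flags `--config run.toml`, `--seed`, `--log-level` apply to every
subcommand; every run logs its configuration hash and seed. Exit codes:
0 success, 2 validation error, 3 failed consistency check in `reproduce`.

CSV inputs are comma-delimited UTF-8 with a header row; decimal commas
("0,14") are normalized on read. Expected columns:

| command    | columns |
|------------|---------|
| `classify` | `ligand_id, substrate_id, target_id, K1_uM, Ka_uM, K4_uM, Kb_direct_uM[, e_binding_kcal_mol]` |
| `assay`    | `replicate_id, concentration_mg_ml, eb1, es` (concentration 0 = control) |
| `ic50`     | `concentration_mg_ml, inhibition_pct` |
| `stats`    | `group_label, value[, timepoint]` |

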