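# pswdesign

Design and structure-based virtual screening of **azobenzene
photoswitchable ligands** ("photopharmacology"), for medicinal and
computational chemists who want to turn known binders into light-switchable
tool compounds.

Azobenzene photoswitches isomerize reversibly between a planar, thermally
stable *trans* (E) form and a bent, metastable *cis* (Z) form under UV /
visible illumination. A good photoswitchable ligand binds its target well in
one isomeric state and poorly in the other, so that light toggles activity.
`pswdesign` automates the standard design loop:

1. **miner** — mine parent ligands from a local ChEMBL-schema SQLite
   snapshot: retrieve bioactivities per target (class/subclass/family
   browsing), apply quality curation (binding assays, exact `=` relations,
   molar-convertible units, MW/heavy-atom windows, validity flags, duplicate
   collapse), aggregate measurements into a unified
   **pAffinity = −log₁₀ K (molar)** (per-ligand median), classify by
   user thresholds, and pick chemically diverse parents by hierarchical
   clustering on Tanimoto fingerprint similarity.
2. **reactor** — enumerate photoswitchable analogs via SMARTS reactions:
   *azologization* (a 0–3 atom linker between two (hetero)aromatic rings, or
   a mono-/disubstituted naphthalene-like bicycle, is replaced by an azo
   bond / azobenzene) and *azoextension* (a phenyldiazene is appended at
   every free aromatic C–H, or replaces a small substituent). Products are
   deduplicated by canonical constitution and emitted as *trans*/*cis*
   (E/Z) pairs with constitution-level descriptors (logP, TPSA, MW,
   fraction sp³).
3. **prep** — generate protonation/tautomer variants at pH 7.4, embed them
   in 3D and minimize under MMFF94 with the azo E/Z geometry restrained;
   prepare the receptor chain and define the docking sphere around a bound
   reference ligand (+2.0 Å by default).
4. **dockscore** — dock through a pluggable engine (PLANTS adapter, or the
   built-in deterministic mock engine), pick each variant's representative
   pose by **4-objective Pareto ranking** (max contacts, min clashes, min
   uncontacted ligand atoms, min ChemPLP-style score; ties → lowest score),
   and predict the **isomeric shift**:

   ```
   pKi_pred(isomer) = pAffinity(parent) · score(isomer) / score(parent)
   ΔpKi             = pKi_pred(cis) − pKi_pred(trans)      (median over variant pairs)
   FC               = 10^|ΔpKi|                            (fold-change)
   ```

   The consensus active isomer is *cis*-ON for median ΔpKi > 0, *trans*-ON
   for < 0; a ≥ 50-fold filter (ΔpKi ≥ 1.7, since 10^1.7 ≈ 50.1) is applied
   by default and can be relaxed or disabled.

Every stage is also exposed as a `psw` subcommand communicating through
plain files, and the `fixtures` module fabricates all inputs (mini ChEMBL
database with an expected-count manifest, mock engine, toy molecule catalog,
synthetic receptor pocket) so the whole pipeline runs offline.

## Worked example

```bash
python - <<'EOF'
from pswdesign import fixtures
fixtures.generate_mini_chembl("mini.db")
fixtures.write_toy_pocket("pocket.pdb")
EOF
psw mine --db mini.db --target-query adrenergic --paffinity-min 8.0 --outdir out
psw react --outdir out
psw prep --receptor pocket.pdb --chain A --ref-het LIG --outdir out
psw dock --engine mock --poses 10 --workers 2 --outdir out
psw predict --min-fold 0 --outdir out
psw report --outdir out
```

prints (mock-engine scores, so the numbers illustrate the mechanics):

```
1 parent ligands -> out/parents.smi
4 unique designs -> out/designs.tsv
12 prepared variants -> out/ligands.sdf
120 poses -> out/poses.sdf
4/4 families pass the 0.0-fold filter -> out/report.tsv
                family_id active_isomer  parent_paffinity  parent_score  ...  delta_pki  fold_change  fold_change_display
L2|Naphtho_1_8_ABz_2a2b|0         trans                 9      -84.8786  ...  -0.492581      3.10872              3.10872
L2|Naphtho_1_8_ABz_2a5b|1         trans                 9      -70.8746  ...  -0.489394      3.08599              3.08599
L2|Naphtho_1_8_ABz_2a5b|0           cis                 9      -81.9119  ...   0.328274      2.12948             -2.12948
L2|Naphtho_1_8_ABz_5a5b|0         trans                 9      -82.5449  ...  -0.069926      1.17470              1.17470
```

Reading it: the mining stage kept one diverse parent with median
pAffinity ≥ 8; the reactor replaced its 1,8-disubstituted naphthalene core
with azobenzene in four position mappings; for each design family, the
median ΔpKi over trans/cis variant pairs gives the predicted fold-change,
shown negative for *cis*-ON families in the display column.

Library-level use mirrors the same steps
(`miner.mine → reactor.enumerate_designs → prep.prepare_design_family →
dockscore.dock → dockscore.predict_family_shift`).

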