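# Methods

## Scope and model

`pswdesign` implements a design-and-screen workflow for azobenzene
photopharmacology: curated bioactivity mining, rule-based enumeration of
photoswitchable analogs, and a docking-score-based predictor of the
binding-affinity shift between the *trans* (E) and *cis* (Z) photoisomers.
The package is engine-agnostic: any docking program that returns scored
poses can drive the prediction; the shipped adapters are PLANTS (external
binary, ChemPLP convention: lower score = better) and a deterministic mock
engine used throughout the test suite.

## Bioactivity mining

The miner operates on a local relational snapshot in the ChEMBL SQLite
dialect (tables `target_dictionary`, `target_components`,
`component_class`, `protein_classification`, `assays`, `activities`,
`molecule_dictionary`, `compound_structures`). Access uses the standard
library `sqlite3`; no ORM is required for this table subset.

Curation defaults (all overridable in `MinerConfig`):

* binding assays only (`assay_type = 'B'`); a permissive flag keeps
  censored `<`/`<=` upper bounds, otherwise only exact `=` relations pass;
* affinity types Ki/Kd/IC50/EC50 pooled into one pAffinity (an optional
  flag restricts to Ki/Kd);
* `standard_value` present and > 0, units convertible to molar
  (M…fM); records with data-validity flags dropped; exact duplicate
  (ligand, assay, type, value, unit) rows collapsed;
* molecular weight in [100, 800] Da and 7–60 heavy atoms.

Per measurement, pAffinity = −log₁₀(value in mol/L); per (ligand, target)
the **median** is reported with the measurement count, making the
aggregation unit-invariant and permutation-invariant. Classification bins
records by ordered thresholds (default 6.0/8.0); the minimum-pAffinity
filter is boundary-inclusive (≥ 8.0 keeps 8.0).

Diversity selection builds circular fingerprints (Morgan, radius 2,
2048 bits), clusters on 1 − Tanimoto with average linkage and cuts the tree
at the similarity threshold (default 0.50); each cluster is represented by
its highest-pAffinity member (ties → lexicographically smallest id).
Because no linkage cut by itself guarantees that *representatives* of
different clusters are pairwise below the threshold, a final greedy sweep
in descending pAffinity order drops any representative within threshold
similarity of an already-accepted one. This makes the advertised contract
("no two selected parents more similar than the threshold") an invariant
rather than a tendency, and on well-separated sets it coincides with a
plain greedy selection, which the tests use as an independent oracle.

## Transformation rules

All transformations are RDKit reaction SMARTS, built and named
deterministically:

* **Typical azologization** (`Azolog_2atom`): an acyclic, unbranched
  two-atom linker (C/N/O/S, any bond order) joining two aromatic carbons is
  replaced by N=N — the classic stilbene→azobenzene swap, conserving the
  heavy-atom count.
* **Atypical azologization**: ring–ring single bond (`Azolog_0atom`,
  +2 heavy atoms), one-atom linker with ≤1-atom branch
  (`Azolog_1atom[_branched]`), and three-atom linkers where each linker
  atom may bear one extra atom (`Azolog_3atom_*`, 8 branch patterns).
  Linker atoms are restricted to acyclic C/N/O/S so no ring is opened.
* **Naphthalene-like azologization** (`Naphtho_i[_j]_ABz_…`): a fused 6-6
  fully aromatic bicycle carrying exactly one (mono) or two (di)
  substituents is replaced by azobenzene. The position mapping lays each
  ring of the bicycle onto one phenyl of azobenzene with a ring-fusion atom
  becoming the ipso (azo-bearing) carbon; since either fusion atom can take
  that role, both orientations are emitted per ring and duplicates removed.
  Consequences: a 2-substituted bicycle yields the *meta*- and
  *para*-azobenzenes; a 2,6-disubstituted one yields the 3,3′ / 3,4′ /
  4,4′ set. Larger fused systems (three or more rings) are deliberately not
  matched. This mapping table is a design choice of this package; other
  conventions are conceivable, so rule names encode the positions to keep
  provenance inspectable.
* **Typical azoextension** (`Azoext_CH`): a phenyldiazene (–N=N–C₆H₅) is
  appended at every free aromatic C–H, exhaustively; symmetry-equivalent
  products collapse in deduplication (benzene → 1 unique design,
  toluene → 3).
* **Atypical azoextension** (`Azoext_repl*`): the phenyldiazene replaces a
  substituent of up to `max_replaced_substituent` heavy atoms
  (default 1 — halogens, OH, CH₃, NH₂; configurable to 3, where both chain
  and branched three-atom groups are covered).

Every product is validated: heavy-atom delta per rule asserted, exactly one
new aromatic-C–N=N–C-aromatic motif added. The newly formed azo bond is
tracked through reaction atom bookkeeping (atoms absent from the reactant
side), never by substructure diffing, so parents that already contain azo
groups keep their original geometry; E/Z assignment touches only the new
bond. An azo bond landing in a ring smaller than 9 atoms cannot
photoisomerize and drops the design with a warning. Deduplication keys on
the canonical flat (constitution-level) SMILES and merges rule provenance.
Parent→product atom correspondence is computed by iterated maximum-common-
substructure search (matched atoms are masked and the search repeated), so
disconnected conserved fragments — both phenyls of a bibenzyl parent — are
mapped while the replaced linker stays unmapped.

## Ligand and receptor preparation

Protonation at pH 7.4 is rule-based: non-amide, non-anilinic amines gain a
proton; carboxylic acids lose one. Tautomers are enumerated with RDKit's
canonical enumerator, capped at 4 per molecule (configurable); tautomers
that lose the azo stereo annotation are discarded. Each variant is embedded
by distance geometry (ETKDGv3, seed 42 by default, up to 10 attempts) and
minimized in MMFF94 with a torsion restraint holding the azo C–N=N–C
dihedral at 180° (trans) or 0° (cis); a variant is accepted only if
minimization did not raise the energy and the final dihedral is within 30°
of its target.

Receptor preparation keeps a single chain, drops waters, ions and foreign
heteroatoms (except requested het groups, e.g. the bound reference ligand),
strips alternate locations, and *flags* residues with missing backbone
atoms rather than rebuilding them — rebuilding coordinates is outside this
package's scope and the flags make incomplete pockets visible to the user.
Optional hydrogen addition is delegated to the OpenBabel CLI. The docking
site is a sphere centered on the reference ligand's heavy-atom centroid
with radius = distance to its most distal heavy atom + 2.0 Å (default).

## Docking, pose selection and shift prediction

Contacts/clashes are heavy-atom pair counts at 4.0 Å / 2.5 Å cutoffs
(configurable; clashing pairs also count as contacts); "uncontacted" counts
ligand heavy atoms with no receptor atom within the contact cutoff. The
representative pose per variant is chosen on the 4-objective Pareto front
(max contacts; min clashes, uncontacted, total score); among front members
the lowest score wins and remaining ties go to the lowest pose index,
making selection total and deterministic.

The score→affinity mapping is proportional scaling against the parent:
pKi_pred = pAffinity(parent) · score/score(parent). It uses exactly the
three quantities available after docking (parent score, parent measured
pAffinity, variant score), reduces to the parent's measured affinity when a
variant scores like its parent, and gives a positive ΔpKi when the cis pose
scores better (more negative). **This mapping is a reconstruction, not a
calibrated model**; it is isolated behind `score_to_pki` so an alternative
(e.g. a fitted linear model) can be plugged in without touching the rest of
the pipeline. Per family, ΔScore and ΔpKi are computed per
protonation/tautomer pair (pairing by label; unpaired variants dropped),
medians across pairs define the consensus, FC = 10^|median ΔpKi|, and the
display fold-change is negated for *cis*-ON families. The default filter
keeps |FC| ≥ 50, equivalent to |ΔpKi| ≥ 1.7 (10^1.7 ≈ 50.1).

## Synthetic data

The fixture generator emulates the *shape* of the real inputs, not their
statistics:

* The mini database seeds three targets (two monoamine-receptor-like, one
  kinase) plus an activity-free orphan, 18 curated measurements — including
  one dirty record per quality rule (censored relation, missing value,
  missing units, functional assay, duplicate row, unparsable SMILES,
  out-of-range size, validity flag) — and a β-blocker-like analog series
  that forms exactly one diversity cluster. Affinities span pKi 5–10 so
  every classification bin and the ≥ 8 filter are populated. A JSON
  manifest of expected per-stage counts is computed during generation from
  the generator's own bookkeeping (including a greedy diversity oracle),
  independently of the mining code. Same spec → byte-identical file.
* The mock engine returns the input conformer translated to the site
  center with scores from a configured table (keyed by variant id, role or
  role|label) or from a stable hash — deterministic across runs and worker
  counts. `shift_recovery_table` constructs score tables whose predicted
  ΔpKi equals a requested value exactly, which the tests use for end-to-end
  parameter recovery.
* The toy pocket is 20 glycine backbones on a lattice ring around one
  6-atom het ligand — sufficient for parsing, chain selection, site
  geometry and contact counting, with no pretense of protein realism.
* The toy catalog includes a synthetic 2,6-disubstituted naphthalene parent
  (amide + piperidinylpropoxy) standing in for a histamine-H3-like
  template; it is labelled synthetic and used only to exercise the
  disubstituted mapping rules.

Passing tests on these fixtures demonstrate correctness of the mechanics
(curation rules, enumeration chemistry, Pareto logic, shift arithmetic,
determinism), not predictive accuracy on real targets — the latter depends
on a real docking engine, real structures and the score→affinity mapping
above.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
fixture scale (one mined parent, 4 design families, ~12 prepared variants,
10 poses each; 200 random Pareto instances of ≤ 12 poses), which keeps a
complete run in seconds while covering every code path. Floating-point
tolerances: pAffinity unit invariance and FC/ΔpKi identities are asserted
to 1e−9; geometric assertions use the 30° dihedral tolerance. All
randomness (database spec, conformer embedding, random oracle instances)
is seed-controlled.

## Known limitations

* The ΔpKi formula is an uncalibrated reconstruction (above); absolute
  fold-change magnitudes from any real engine should be treated as ranking
  scores.
* The naphthalene position-mapping table is a package design choice;
  tri-cyclic aromatic systems are not transformed.
* Protonation is rule-based (no pKa prediction); missing receptor loops and
  side chains are flagged, not modeled.
* Photochemistry (absorption wavelengths, photostationary state, thermal
  half-life) is out of scope, as are photoswitch classes other than
  azobenzene.
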