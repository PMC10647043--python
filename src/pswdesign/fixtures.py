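"""Deterministic synthetic inputs for every pipeline stage.

Nothing here touches the network: the module fabricates

* a miniature relational database in the ChEMBL SQLite dialect, seeded
  with clean and deliberately dirty bioactivity records plus a JSON
  manifest of the counts the mining pipeline is expected to produce;
* a deterministic mock docking engine satisfying the
  :class:`~pswdesign.dockscore.DockingEngine` contract;
* a catalog of toy parent molecules with known transformation outcomes
  for every reaction category;
* a 20-residue synthetic receptor pocket (PDB) with a bound ligand.

The synthetic affinities span pKi 5-10 so both the activity
classification bins and the pAffinity >= 8 filter are non-trivially
populated.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

from .dockscore import DockedPose
from .prep import BindingSite, PreparedLigand, Receptor

# ---------------------------------------------------------------------------
# mini ChEMBL database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic database.  Same spec -> same bytes."""

    seed: int = 42
    n_extra_ligands_per_target: int = 0
    organisms: tuple[str, str] = ("Homo sapiens", "Rattus norvegicus")
    paff_range: tuple[float, float] = (5.0, 10.0)
    low_quality_fraction: float = 0.25


_POOL = [  # spare valid scaffolds for randomly added clean ligands
    "CCN(CC)CCOc1ccccc1", "COc1ccc(CCN2CCCC2)cc1",
    "CC(=O)Nc1ccc(O)cc1", "c1ccc(CN2CCN(C)CC2)cc1",
    "OCC1CCCN1Cc1ccccc1", "CC(C)Oc1ccccc1C(N)=O",
    "Clc1ccccc1CN1CCOCC1", "CCOC(=O)c1ccc(N)cc1",
    "CC1CCN(CCc2ccccc2)CC1", "COc1cccc(C(=O)NCC2CC2)c1",
    "Fc1ccc(OCCN2CCCC2)cc1", "CN(C)CCCNc1ccccn1",
]

# curated ligand catalog; beta-blocker-like series L1-L3 is internally
# similar (one diversity cluster), the rest are mutually dissimilar
_LIGANDS = {
    "L1": "CC(C)NCC(O)COc1cccc2ccccc12",          # propranolol
    "L2": "CC(C)NCC(O)COc1cccc2cccc(Cl)c12",      # chloro analog of L1
    "L3": "CC(C)NCC(O)COc1cccc2cccc(C)c12",       # methyl analog of L1
    "L4": "CN1CCC(c2ccccc2O)CC1",
    "L5": "O=C(O)c1ccc(OCCN2CCCC2)cc1",
    "L6": "NCCc1ccc(-c2ccccc2)cc1",
    "L7": "NC(=O)c1ccc2cc(OCCCN3CCCCC3)ccc2c1",   # synthetic H3-like parent
    "L8": "Cc1cccc(OCCCN2CCCC2)c1",
    "L9": "C1CC",                                 # unparsable on purpose
    "L10": "C" * 70,                              # MW/NHA out of range
    "L11": "Clc1ccc(CCNCC2CCCCC2)cc1",
    "L12": "Nc1ncnc2[nH]cnc12",
}

# (target_key, ligand, type, relation, value, units, assay_type, validity)
_RECORDS = [
    # T1: exactly 12 seeded measurements (7 clean, 5 dirty)
    ("T1", "L1", "Ki", "=", 10.0, "nM", "B", None),
    ("T1", "L1", "Ki", "=", 0.01, "uM", "B", None),
    ("T1", "L1", "IC50", "=", 100.0, "nM", "B", None),
    ("T1", "L2", "Ki", "=", 1.0, "nM", "B", None),
    ("T1", "L3", "Kd", "=", 5.0, "nM", "B", None),
    ("T1", "L4", "Ki", "=", 50.0, "nM", "B", None),
    ("T1", "L5", "Ki", "=", 1000.0, "nM", "B", None),
    ("T1", "L6", "Ki", ">", 2.0, "nM", "B", None),          # censored
    ("T1", "L4", "Ki", "=", None, "nM", "B", None),         # no value
    ("T1", "L5", "Ki", "=", 10.0, None, "B", None),         # no units
    ("T1", "L1", "Ki", "=", 10.0, "nM", "F", None),         # functional
    ("T1", "L2", "Ki", "=", 1.0, "nM", "B", "dup"),         # duplicate row
    # T2 (rat): structure-level dirt
    ("T2", "L7", "Ki", "=", 3.0, "nM", "B", None),
    ("T2", "L9", "Ki", "=", 10.0, "nM", "B", None),         # bad SMILES
    ("T2", "L10", "Ki", "=", 10.0, "nM", "B", None),        # out of range
    ("T2", "L11", "Ki", "=", 10.0, "nM", "B",
     "Potential transcription error"),
    ("T2", "L1", "Ki", "=", 100.0, "nM", "B", None),
    # T3 (kinase)
    ("T3", "L12", "Ki", "=", 20.0, "nM", "B", None),
]

_UNIT_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}

_SCHEMA = """
CREATE TABLE protein_classification (
    protein_class_id INTEGER PRIMARY KEY, parent_id INTEGER,
    pref_name TEXT, class_level INTEGER);
CREATE TABLE target_dictionary (
    tid INTEGER PRIMARY KEY, chembl_id TEXT, pref_name TEXT,
    organism TEXT, target_type TEXT);
CREATE TABLE target_components (tid INTEGER, component_id INTEGER);
CREATE TABLE component_class (component_id INTEGER,
    protein_class_id INTEGER);
CREATE TABLE assays (assay_id INTEGER PRIMARY KEY, chembl_id TEXT,
    tid INTEGER, assay_type TEXT);
CREATE TABLE activities (activity_id INTEGER PRIMARY KEY,
    assay_id INTEGER, molregno INTEGER, standard_type TEXT,
    standard_relation TEXT, standard_value REAL, standard_units TEXT,
    data_validity_comment TEXT);
CREATE TABLE molecule_dictionary (molregno INTEGER PRIMARY KEY,
    chembl_id TEXT);
CREATE TABLE compound_structures (molregno INTEGER,
    canonical_smiles TEXT);
CREATE TABLE version (name TEXT);
"""


def _record_clean(lig: str, rel, value, units, assay_type, validity,
                  mw_range=(100.0, 800.0), nha_range=(7, 60),
                  seen=None) -> bool:
    """Generator-side bookkeeping of whether a record passes the default
    curation rules (independent of the mining implementation)."""
    if assay_type != "B" or rel != "=":
        return False
    if value is None or value <= 0 or units not in _UNIT_MOLAR:
        return False
    if validity == "dup":
        return False
    if validity:
        return False
    mol = Chem.MolFromSmiles(_LIGANDS.get(lig, lig))
    if mol is None:
        return False
    from rdkit.Chem import Descriptors
    mw = Descriptors.MolWt(mol)
    if not mw_range[0] <= mw <= mw_range[1]:
        return False
    if not nha_range[0] <= mol.GetNumHeavyAtoms() <= nha_range[1]:
        return False
    return True


def greedy_diverse_count(smiles_paff: Sequence[tuple[str, float]],
                         threshold: float = 0.5) -> int:
    """Brute-force greedy diversity oracle: accept molecules in
    descending-affinity order unless more similar than ``threshold`` to
    an already-accepted one."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    items = sorted(smiles_paff, key=lambda t: (-t[1], t[0]))
    fps = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s, _ in items]
    accepted: list[int] = []
    for i in range(len(items)):
        if all(TanimotoSimilarity(fps[i], fps[j]) <= threshold
               for j in accepted):
            accepted.append(i)
    return len(accepted)


def generate_mini_chembl(path: str | Path,
                         spec: FixtureSpec | None = None) -> Path:
    """Write the miniature ChEMBL-dialect database and its JSON manifest
    (``<path>.manifest.json``) of expected pipeline counts."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(str(path))
    conn.executescript(_SCHEMA)
    conn.execute("INSERT INTO version VALUES ('pswdesign-fixture-1')")

    classes = [
        (1, None, "Membrane receptor", 1),
        (2, 1, "Family A G protein-coupled receptor", 2),
        (3, 2, "Monoamine receptor", 3),
        (4, None, "Enzyme", 1),
        (5, 4, "Kinase", 2),
        (6, 5, "Protein kinase", 3),
    ]
    conn.executemany("INSERT INTO protein_classification VALUES (?,?,?,?)",
                     classes)
    human, other = spec.organisms
    targets = {
        "T1": (1, "CHEMBL_T1", "Beta-2 adrenergic receptor", human, 3),
        "T2": (2, "CHEMBL_T2", "Histamine H3 receptor", other, 3),
        "T3": (3, "CHEMBL_T3", "Tyrosine kinase X", human, 6),
        # orphan target: present but without any activity data
        "T4": (4, "CHEMBL_T4", "Orphan receptor", human, 3),
    }
    for key, (tid, cid, name, org, pclass) in targets.items():
        conn.execute("INSERT INTO target_dictionary VALUES (?,?,?,?,?)",
                     (tid, cid, name, org, "SINGLE PROTEIN"))
        conn.execute("INSERT INTO target_components VALUES (?,?)",
                     (tid, tid * 10))
        conn.execute("INSERT INTO component_class VALUES (?,?)",
                     (tid * 10, pclass))

    records = [r for r in _RECORDS
               if spec.low_quality_fraction > 0
               or _record_clean(r[1], *r[3:])]
    # optional random clean/dirty padding per target
    ligands = dict(_LIGANDS)
    for tkey in ("T1", "T2", "T3"):
        for i in range(spec.n_extra_ligands_per_target):
            smi = _POOL[int(rng.integers(len(_POOL)))]
            lid = f"LX_{tkey}_{i}"
            ligands[lid] = smi
            paff = rng.uniform(*spec.paff_range)
            value_nm = 10 ** (9.0 - paff)
            if rng.random() < spec.low_quality_fraction:
                records.append((tkey, lid, "Ki", ">", value_nm, "nM", "B",
                                None))
            else:
                records.append((tkey, lid, "Ki", "=", value_nm, "nM", "B",
                                None))

    mol_ids = {lig: i + 1 for i, lig in enumerate(sorted(ligands))}
    for lig, molregno in mol_ids.items():
        conn.execute("INSERT INTO molecule_dictionary VALUES (?,?)",
                     (molregno, lig))
        conn.execute("INSERT INTO compound_structures VALUES (?,?)",
                     (molregno, ligands[lig]))

    assay_ids: dict[tuple[str, str], int] = {}
    next_assay = 1
    for i, (tkey, lig, stype, rel, value, units, atype, validity) in \
            enumerate(records, start=1):
        akey = (tkey, atype)
        if akey not in assay_ids:
            assay_ids[akey] = next_assay
            conn.execute("INSERT INTO assays VALUES (?,?,?,?)",
                         (next_assay, f"CHEMBL_A{next_assay}",
                          targets[tkey][0], atype))
            next_assay += 1
        conn.execute("INSERT INTO activities VALUES (?,?,?,?,?,?,?,?)",
                     (i, assay_ids[akey], mol_ids[lig], stype, rel, value,
                      units, None if validity == "dup" else validity))
    conn.commit()
    conn.close()

    manifest = _build_manifest(spec, records, ligands, targets)
    manifest_path = path.with_name(path.name + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _build_manifest(spec: FixtureSpec, records, ligands, targets) -> dict:
    """Expected post-filter counts, derived from generation-time
    bookkeeping (not by running the mining pipeline)."""
    per_target: dict[str, dict] = {}
    for tkey, (tid, cid, name, org, _) in targets.items():
        trecs = [r for r in records if r[0] == tkey]
        seen: set[tuple] = set()
        clean = []
        for r in trecs:
            _, lig, stype, rel, value, units, atype, validity = r
            ok = _record_clean(lig, rel, value, units, atype, validity)
            key = (lig, atype, stype, value, units)
            if ok and key in seen:
                ok = False
            if ok:
                seen.add(key)
                clean.append(r)
        paff: dict[str, list[float]] = {}
        for _, lig, stype, rel, value, units, atype, validity in clean:
            paff.setdefault(lig, []).append(
                float(-np.log10(value * _UNIT_MOLAR[units])))
        medians = {lig: float(np.median(v)) for lig, v in paff.items()}
        ge8 = [(ligands[lig], m) for lig, m in medians.items() if m >= 8.0]
        per_target[cid] = {
            "n_records": len(trecs),
            "n_quality_pass": len(clean),
            "n_paffinity_records": len(medians),
            "n_paffinity_ge8": len(ge8),
            "n_diverse_ge8_t050": greedy_diverse_count(ge8, 0.5),
        }
    return {
        "seed": spec.seed,
        "n_activities": len(records),
        "per_target": per_target,
    }


# ---------------------------------------------------------------------------
# mock docking engine
# ---------------------------------------------------------------------------


@dataclass
class MockEngineConfig:
    """``score_table`` maps a variant id (or its ``role`` or
    ``role|label`` suffix) to a list of (score, n_contacts, n_clashes,
    n_uncontacted) tuples, one per pose; variants not in the table fall
    back to a deterministic hash-based score."""

    n_poses: int = 10
    score_table: dict = field(default_factory=dict)
    base_score: float = -60.0


class MockEngine:
    """Deterministic stand-in engine: poses are the input conformer
    translated to the site center; scores come from the configured table
    or a stable hash of the variant id."""

    name = "mock"

    def __init__(self, config: MockEngineConfig | None = None):
        self.config = config or MockEngineConfig()

    def _lookup(self, variant_id: str):
        table = self.config.score_table
        if variant_id in table:
            return table[variant_id]
        parts = variant_id.rsplit("|", 2)
        if len(parts) == 3:
            _, role, label = parts
            for key in (f"{role}|{label}", role):
                if key in table:
                    return table[key]
        return None

    @staticmethod
    def _hash_unit(key: str) -> float:
        h = int.from_bytes(hashlib.sha256(key.encode()).digest()[:6], "big")
        return h / float(1 << 48)

    def dock_one(self, receptor: Receptor, site: BindingSite,
                 ligand: PreparedLigand, n_poses: int) -> list[DockedPose]:
        coords = ligand.heavy_coords
        coords = coords - coords.mean(axis=0) + np.asarray(site.center)
        entries = self._lookup(ligand.variant_id)
        poses = []
        for i in range(n_poses):
            if entries is not None and i < len(entries):
                score, nc, ncl, nu = entries[i]
            elif entries is not None:
                break  # table rows define the pose count for that variant
            else:
                u = self._hash_unit(f"{ligand.variant_id}:{i}")
                score = self.config.base_score - 30.0 * u + 1.5 * i
                nc = 15 + int(20 * self._hash_unit(f"c{ligand.variant_id}:{i}"))
                ncl = int(3 * self._hash_unit(f"x{ligand.variant_id}:{i}"))
                nu = int(4 * self._hash_unit(f"u{ligand.variant_id}:{i}"))
            poses.append(DockedPose(
                variant_id=ligand.variant_id, pose_index=i,
                coords=coords.copy(), total_score=float(score),
                score_terms={"chemplp": float(score)},
                n_contacts=int(nc), n_clashes=int(ncl),
                n_uncontacted=int(nu)))
        return poses


def make_mock_engine(config: MockEngineConfig | None = None) -> MockEngine:
    return MockEngine(config)


def shift_recovery_table(parent_score: float, parent_paffinity: float,
                         delta_pki: float) -> dict:
    """Score table that makes the shift predictor recover exactly
    ``delta_pki``: the parent and trans variants score at
    ``parent_score``; the cis variant is offset so that
    parent_paffinity * (score_cis - score_trans) / parent_score equals
    the requested shift."""
    score_cis = parent_score * (1.0 + delta_pki / parent_paffinity)
    metrics = (20, 0, 0)
    return {
        "parent": [(parent_score, *metrics)],
        "trans": [(parent_score, *metrics)],
        "cis": [(score_cis, *metrics)],
    }


# ---------------------------------------------------------------------------
# toy molecule catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyCase:
    """A parent molecule with its expected products per rule category.

    ``expected`` maps a category to the set of product SMILES (compared
    after canonicalization); ``expected_counts`` to the number of unique
    designs the category should yield after deduplication.
    """

    name: str
    smiles: str
    expected: dict
    expected_counts: dict


_AZOBENZENE = "c1ccc(N=Nc2ccccc2)cc1"


def toy_library() -> dict[str, ToyCase]:
    """Worked transformation examples with hand-derived outcomes."""
    cases = [
        ToyCase("bibenzyl", "C(c1ccccc1)Cc1ccccc1",
                {"typical_azologization": {_AZOBENZENE}},
                {"typical_azologization": 1}),
        ToyCase("stilbene", "C(=C/c1ccccc1)\\c1ccccc1",
                {"typical_azologization": {_AZOBENZENE}},
                {"typical_azologization": 1}),
        ToyCase("biphenyl", "c1ccc(-c2ccccc2)cc1",
                {"atypical_azologization": {_AZOBENZENE}},
                {"atypical_azologization": 1}),
        ToyCase("diphenylmethane", "C(c1ccccc1)c1ccccc1",
                {"atypical_azologization": {_AZOBENZENE}},
                {"atypical_azologization": 1}),
        ToyCase("benzophenone", "O=C(c1ccccc1)c1ccccc1",
                {"atypical_azologization": {_AZOBENZENE}},
                {"atypical_azologization": 1}),
        ToyCase("1,3-diphenylpropane", "C(CCc1ccccc1)c1ccccc1",
                {"atypical_azologization": {_AZOBENZENE}},
                {"atypical_azologization": 1}),
        ToyCase("benzene", "c1ccccc1",
                {"typical_azoextension": {_AZOBENZENE}},
                {"typical_azoextension": 1}),
        ToyCase("toluene", "Cc1ccccc1",
                {"typical_azoextension": {
                    "Cc1ccccc1N=Nc1ccccc1",
                    "Cc1cccc(N=Nc2ccccc2)c1",
                    "Cc1ccc(N=Nc2ccccc2)cc1"}},
                {"typical_azoextension": 3}),
        ToyCase("fluorobenzene", "Fc1ccccc1",
                {"atypical_azoextension": {_AZOBENZENE}},
                {"atypical_azoextension": 1}),
        ToyCase("2-methylnaphthalene", "Cc1ccc2ccccc2c1",
                {"naphthalene_azologization": {
                    "Cc1cccc(N=Nc2ccccc2)c1",
                    "Cc1ccc(N=Nc2ccccc2)cc1"}},
                {"naphthalene_azologization": 2}),
        ToyCase("2,6-dimethylnaphthalene", "Cc1ccc2cc(C)ccc2c1",
                {"naphthalene_azologization": {
                    "Cc1cccc(N=Nc2cccc(C)c2)c1",
                    "Cc1ccc(N=Nc2cccc(C)c2)cc1",
                    "Cc1ccc(N=Nc2ccc(C)cc2)cc1"}},
                {"naphthalene_azologization": 3}),
        # synthetic stand-in for a naphthalene-core H3 antagonist
        ToyCase("h3-naphthalene-parent-synthetic",
                "NC(=O)c1ccc2cc(OCCCN3CCCCC3)ccc2c1",
                {}, {"naphthalene_azologization": 4}),
    ]
    return {c.name: c for c in cases}


# ---------------------------------------------------------------------------
# toy receptor pocket
# ---------------------------------------------------------------------------


def write_toy_pocket(path: str | Path, n_residues: int = 20,
                     radius: float = 9.0) -> Path:
    """Synthetic 20-residue pocket: glycine backbones on two stacked
    rings around the origin, one bound het ligand (LIG) at the center,
    a few waters, and a short second chain for chain-selection tests.
    Coordinates are a deterministic lattice, not real protein geometry."""
    st = gemmi.Structure()
    st.name = "synthetic pocket"
    model = gemmi.Model("1")
    chain_a = gemmi.Chain("A")

    def add_res(chain, name, seqid, het, atoms):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        res.het_flag = "H" if het else "A"
        for aname, elem, (x, y, z) in atoms:
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain.add_residue(res)

    for i in range(n_residues):
        ang = 2 * np.pi * (i % (n_residues // 2)) / (n_residues // 2)
        z0 = -2.0 if i < n_residues // 2 else 2.0
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        add_res(chain_a, "GLY", i + 1, False, [
            ("N", "N", (cx, cy, z0)),
            ("CA", "C", (cx - 0.8, cy + 0.8, z0 + 0.5)),
            ("C", "C", (cx - 1.6, cy, z0)),
            ("O", "O", (cx - 1.6, cy - 1.2, z0)),
        ])
    add_res(chain_a, "LIG", n_residues + 1, True, [
        ("C1", "C", (0.0, 0.0, 0.0)), ("C2", "C", (1.4, 0.0, 0.0)),
        ("C3", "C", (2.1, 1.2, 0.0)), ("N1", "N", (-0.7, 1.2, 0.0)),
        ("O1", "O", (-0.7, -1.2, 0.0)), ("C4", "C", (3.5, 1.2, 0.2)),
    ])
    for j, (wx, wy, wz) in enumerate([(5.0, 5.0, 4.0), (-5.0, 4.0, -4.0)]):
        add_res(chain_a, "HOH", n_residues + 2 + j, True,
                [("O", "O", (wx, wy, wz))])
    model.add_chain(chain_a)
    chain_b = gemmi.Chain("B")
    for i in range(3):
        add_res(chain_b, "ALA", i + 1, False, [
            ("N", "N", (20.0 + i * 3, 0.0, 0.0)),
            ("CA", "C", (21.0 + i * 3, 1.0, 0.0)),
            ("C", "C", (22.0 + i * 3, 0.0, 0.0)),
            ("O", "O", (22.0 + i * 3, -1.2, 0.0)),
        ])
    model.add_chain(chain_b)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path
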