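"""Mining of parent ligands with curated binding-affinity data.

Works against a local relational snapshot in the ChEMBL SQLite dialect
(the same table subset the public ChEMBL dumps use).  The pipeline is

    open_database -> list_target_hierarchy -> fetch_activities
    -> apply_quality_filters -> compute_paffinity -> classify_and_filter
    -> select_diverse_parents

pAffinity is the unified logarithmic affinity: each measurement is
converted to molar and mapped to -log10, and per (ligand, target) the
median of the per-measurement values is reported.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

REQUIRED_TABLES = (
    "target_dictionary", "target_components", "component_class",
    "protein_classification", "assays", "activities",
    "molecule_dictionary", "compound_structures",
)

#: conversion of concentration units to mol/L
UNIT_TO_MOLAR = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "um": 1e-6,
    "nM": 1e-9, "pM": 1e-12, "fM": 1e-15,
}

BINDING_TYPES = ("Ki", "Kd")
AFFINITY_TYPES = ("Ki", "Kd", "IC50", "EC50")


class SchemaError(RuntimeError):
    """Database does not expose the required ChEMBL table subset."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement joined with ligand and assay
    metadata; no deduplication or curation applied."""

    ligand_id: str
    canonical_smiles: str
    target_id: str
    organism: str
    standard_type: str
    standard_value: float | None
    standard_units: str | None
    relation: str | None
    assay_id: str
    assay_type: str
    data_validity_comment: str | None = None


@dataclass(frozen=True)
class PAffinityRecord:
    """Median -log10 molar affinity of one ligand at one target."""

    ligand_id: str
    canonical_smiles: str
    target_id: str
    paffinity: float
    n_measurements: int
    activity_class: str = ""


@dataclass(frozen=True)
class ParentLigand:
    ligand_id: str
    smiles: str
    paffinity: float


@dataclass
class MinerConfig:
    """Curation parameters.

    The quality rules mirror common ChEMBL curation practice: binding
    assays only, exact ('=') affinity relations, concentration units
    convertible to molar, positive values, no data-validity flags, and
    collapse of exact duplicate rows.  Every rule can be switched off.
    """

    mw_range: tuple[float, float] = (100.0, 800.0)
    nha_range: tuple[int, int] = (7, 60)
    paffinity_min: float | None = None
    similarity_threshold: float = 0.5
    class_thresholds: tuple[float, ...] = (6.0, 8.0)
    class_labels: tuple[str, ...] | None = None
    binding_assays_only: bool = True
    exact_relation_only: bool = True
    allow_upper_bound: bool = False        # permissive mode keeps '<' / '<='
    binding_types_only: bool = False       # restrict to Ki/Kd
    reject_validity_flags: bool = True
    collapse_duplicates: bool = True
    fp_radius: int = 2
    fp_bits: int = 2048
    cluster_linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.mw_range[0] >= self.mw_range[1]:
            raise ValueError("mw_range is degenerate")
        if self.nha_range[0] >= self.nha_range[1]:
            raise ValueError("nha_range is degenerate")


class MinerDB:
    """Thin handle over a ChEMBL-dialect SQLite file."""

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"database not found: {path}")
        self.path = path
        self.conn = sqlite3.connect(str(path))
        self.conn.row_factory = sqlite3.Row
        existing = {r[0] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        missing = [t for t in REQUIRED_TABLES if t not in existing]
        if missing:
            raise SchemaError(
                "database is missing required tables: " + ", ".join(missing))
        self.schema_version = self._schema_version()

    def _schema_version(self) -> str:
        try:
            row = self.conn.execute(
                "SELECT name FROM sqlite_master WHERE name='version'"
            ).fetchone()
            if row:
                v = self.conn.execute("SELECT * FROM version").fetchone()
                if v is not None:
                    return str(tuple(v))
        except sqlite3.Error:  # pragma: no cover
            pass
        return "unknown"

    def close(self) -> None:
        self.conn.close()


def open_database(path: str | Path) -> MinerDB:
    """Open a ChEMBL-dialect SQLite snapshot and validate its schema."""
    return MinerDB(path)


def list_target_hierarchy(db: MinerDB) -> dict:
    """Protein class -> subclass -> family -> [(target_id, name, organism)].

    Only targets with at least one activity record appear; every level is
    sorted so the tree is deterministic.  Classification follows the
    protein_classification parent chain (levels 1-3).
    """
    classes = {row["protein_class_id"]: (row["parent_id"], row["pref_name"])
               for row in db.conn.execute(
                   "SELECT protein_class_id, parent_id, pref_name "
                   "FROM protein_classification")}

    def path_names(class_id) -> list[str]:
        names: list[str] = []
        while class_id is not None and class_id in classes:
            parent, name = classes[class_id]
            names.append(name)
            class_id = parent
        return names[::-1]

    rows = db.conn.execute(
        """SELECT DISTINCT td.chembl_id AS target_id, td.pref_name,
                  td.organism, cc.protein_class_id
           FROM target_dictionary td
           JOIN target_components tc ON tc.tid = td.tid
           JOIN component_class cc ON cc.component_id = tc.component_id
           WHERE EXISTS (SELECT 1 FROM assays a JOIN activities act
                         ON act.assay_id = a.assay_id WHERE a.tid = td.tid)
        """)
    tree: dict = {}
    for row in rows:
        names = path_names(row["protein_class_id"])
        l1 = names[0] if names else "Unclassified"
        l2 = names[1] if len(names) > 1 else l1
        l3 = names[2] if len(names) > 2 else l2
        leaf = (row["target_id"], row["pref_name"], row["organism"])
        tree.setdefault(l1, {}).setdefault(l2, {}).setdefault(l3, [])
        if leaf not in tree[l1][l2][l3]:
            tree[l1][l2][l3].append(leaf)
    for l1 in tree:
        for l2 in tree[l1]:
            for l3 in tree[l1][l2]:
                tree[l1][l2][l3].sort()
    return {k1: {k2: dict(sorted(v2.items()))
                 for k2, v2 in sorted(v1.items())}
            for k1, v1 in sorted(tree.items())}


def fetch_activities(db: MinerDB, target_ids: Sequence[str],
                     organisms: Sequence[str] | None = None
                     ) -> list[ActivityRecord]:
    """All raw measurements for the given target accessions, one record
    per activity row.  Unknown target ids yield no rows (logged)."""
    if not target_ids:
        raise ValueError("target_ids must be non-empty")
    known = {r[0] for r in db.conn.execute(
        "SELECT chembl_id FROM target_dictionary")}
    for tid in target_ids:
        if tid not in known:
            logger.warning("unknown target id %s: no records", tid)
    q = """SELECT md.chembl_id AS ligand_id, cs.canonical_smiles,
                  td.chembl_id AS target_id, td.organism,
                  act.standard_type, act.standard_value,
                  act.standard_units, act.standard_relation,
                  a.chembl_id AS assay_id, a.assay_type,
                  act.data_validity_comment
           FROM activities act
           JOIN assays a ON a.assay_id = act.assay_id
           JOIN target_dictionary td ON td.tid = a.tid
           JOIN molecule_dictionary md ON md.molregno = act.molregno
           LEFT JOIN compound_structures cs ON cs.molregno = act.molregno
           WHERE td.chembl_id IN ({ph})""".format(
        ph=",".join("?" * len(target_ids)))
    params = list(target_ids)
    if organisms:
        q += " AND td.organism IN ({})".format(",".join("?" * len(organisms)))
        params += list(organisms)
    q += " ORDER BY act.activity_id"
    return [ActivityRecord(
        ligand_id=r["ligand_id"],
        canonical_smiles=r["canonical_smiles"] or "",
        target_id=r["target_id"], organism=r["organism"],
        standard_type=r["standard_type"] or "other",
        standard_value=r["standard_value"],
        standard_units=r["standard_units"],
        relation=r["standard_relation"],
        assay_id=r["assay_id"], assay_type=r["assay_type"],
        data_validity_comment=r["data_validity_comment"],
    ) for r in db.conn.execute(q, params)]


def _mol_or_none(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles) if smiles else None


def apply_quality_filters(records: Iterable[ActivityRecord],
                          config: MinerConfig | None = None
                          ) -> list[ActivityRecord]:
    """Drop records violating the configured quality rules (each rejection
    logged with the violated rule); idempotent."""
    config = config or MinerConfig()
    kept: list[ActivityRecord] = []
    seen: set[tuple] = set()

    def reject(rec: ActivityRecord, rule: str) -> None:
        logger.info("rejected %s@%s: %s", rec.ligand_id, rec.target_id, rule)

    for rec in records:
        if config.binding_assays_only and rec.assay_type != "B":
            reject(rec, "assay_type != 'B'")
            continue
        allowed = {"="}
        if config.allow_upper_bound:
            allowed |= {"<", "<="}
        if config.exact_relation_only and (rec.relation or "=") not in allowed:
            reject(rec, f"relation {rec.relation!r} not allowed")
            continue
        if rec.standard_value is None or rec.standard_value <= 0:
            reject(rec, "missing or non-positive standard_value")
            continue
        if rec.standard_units not in UNIT_TO_MOLAR:
            reject(rec, f"units {rec.standard_units!r} not molar-convertible")
            continue
        if config.binding_types_only and rec.standard_type not in BINDING_TYPES:
            reject(rec, f"type {rec.standard_type} not in Ki/Kd")
            continue
        if rec.standard_type not in AFFINITY_TYPES:
            reject(rec, f"type {rec.standard_type} not an affinity type")
            continue
        if config.reject_validity_flags and rec.data_validity_comment:
            reject(rec, f"data validity flag: {rec.data_validity_comment}")
            continue
        mol = _mol_or_none(rec.canonical_smiles)
        if mol is None:
            reject(rec, "unparsable SMILES")
            continue
        mw = Descriptors.MolWt(mol)
        if not config.mw_range[0] <= mw <= config.mw_range[1]:
            reject(rec, f"MW {mw:.1f} outside {config.mw_range}")
            continue
        nha = mol.GetNumHeavyAtoms()
        if not config.nha_range[0] <= nha <= config.nha_range[1]:
            reject(rec, f"NHA {nha} outside {config.nha_range}")
            continue
        if config.collapse_duplicates:
            key = (rec.ligand_id, rec.assay_id, rec.standard_type,
                   rec.standard_value, rec.standard_units)
            if key in seen:
                reject(rec, "duplicate (ligand, assay, value) row")
                continue
            seen.add(key)
        kept.append(rec)
    return kept


def paffinity_of(value: float, units: str) -> float:
    """-log10 of an affinity expressed in the given concentration unit."""
    if units not in UNIT_TO_MOLAR:
        raise ValueError(f"units {units!r} not convertible to molar")
    return float(-np.log10(value * UNIT_TO_MOLAR[units]))


def compute_paffinity(records: Iterable[ActivityRecord]
                      ) -> list[PAffinityRecord]:
    """Aggregate measurements into one pAffinity per (ligand, target):
    the median of the per-measurement -log10 molar values."""
    groups: dict[tuple[str, str], list[float]] = {}
    smiles: dict[tuple[str, str], str] = {}
    for rec in records:
        if rec.standard_value is None or rec.standard_units not in UNIT_TO_MOLAR:
            logger.info("excluded %s: non-concentration units", rec.ligand_id)
            continue
        key = (rec.ligand_id, rec.target_id)
        groups.setdefault(key, []).append(
            paffinity_of(rec.standard_value, rec.standard_units))
        smiles.setdefault(key, rec.canonical_smiles)
    return [PAffinityRecord(
        ligand_id=lig, canonical_smiles=smiles[(lig, tgt)], target_id=tgt,
        paffinity=float(np.median(vals)), n_measurements=len(vals),
    ) for (lig, tgt), vals in sorted(groups.items())]


def _class_labels(thresholds: Sequence[float],
                  labels: Sequence[str] | None) -> list[str]:
    if labels is not None:
        if len(labels) != len(thresholds) + 1:
            raise ValueError("need len(thresholds)+1 class labels")
        return list(labels)
    out = [f"<{thresholds[0]:g}"]
    for lo, hi in zip(thresholds, thresholds[1:]):
        out.append(f"[{lo:g},{hi:g})")
    out.append(f">={thresholds[-1]:g}")
    return out


def classify_and_filter(paff_records: Iterable[PAffinityRecord],
                        config: MinerConfig | None = None
                        ) -> list[PAffinityRecord]:
    """Label each record by its threshold bin and drop records below
    ``paffinity_min`` (boundary inclusive: pAffinity >= min is kept)."""
    config = config or MinerConfig()
    thresholds = sorted(config.class_thresholds)
    labels = _class_labels(thresholds, config.class_labels)
    out = []
    for rec in paff_records:
        if (config.paffinity_min is not None
                and rec.paffinity < config.paffinity_min):
            continue
        bin_idx = int(np.searchsorted(thresholds, rec.paffinity, side="right"))
        out.append(replace(rec, activity_class=labels[bin_idx]))
    return out


def _fingerprints(smiles: Sequence[str], radius: int, bits: int):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=bits)
    return [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]


def tanimoto_matrix(smiles: Sequence[str], radius: int = 2,
                    bits: int = 2048) -> np.ndarray:
    """Pairwise Tanimoto similarity on circular fingerprints."""
    fps = _fingerprints(smiles, radius, bits)
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = TanimotoSimilarity(fps[i], fps[j])
    return sim


def select_diverse_parents(paff_records: Sequence[PAffinityRecord],
                           similarity_threshold: float = 0.5,
                           config: MinerConfig | None = None
                           ) -> list[ParentLigand]:
    """Chemically diverse representatives by hierarchical clustering on
    Tanimoto similarity.

    The tree (average linkage on 1 - similarity) is cut at the threshold
    and each cluster is represented by its highest-pAffinity member (ties
    broken by lexicographic ligand id).  A final greedy sweep in
    descending pAffinity order enforces the contract that no two returned
    representatives are more similar than the threshold, which a linkage
    cut alone does not guarantee.
    """
    config = config or MinerConfig()
    records = list(paff_records)
    if not records:
        return []
    if len(records) == 1:
        r = records[0]
        return [ParentLigand(r.ligand_id, r.canonical_smiles, r.paffinity)]
    sim = tanimoto_matrix([r.canonical_smiles for r in records],
                          config.fp_radius, config.fp_bits)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False),
                method=config.cluster_linkage)
    clusters = fcluster(z, t=1.0 - similarity_threshold,
                        criterion="distance")
    reps: list[int] = []
    for cid in sorted(set(clusters)):
        members = [i for i, c in enumerate(clusters) if c == cid]
        members.sort(key=lambda i: (-records[i].paffinity,
                                    records[i].ligand_id))
        reps.append(members[0])
    # greedy enforcement of the pairwise-similarity contract
    reps.sort(key=lambda i: (-records[i].paffinity, records[i].ligand_id))
    accepted: list[int] = []
    for i in reps:
        if all(sim[i, j] <= similarity_threshold for j in accepted):
            accepted.append(i)
    return [ParentLigand(records[i].ligand_id, records[i].canonical_smiles,
                         records[i].paffinity) for i in accepted]


def mine(db: MinerDB, target_ids: Sequence[str],
         organisms: Sequence[str] | None = None,
         config: MinerConfig | None = None) -> list[ParentLigand]:
    """Full mining pipeline: fetch, curate, aggregate, classify/filter,
    and diversity-select parent ligands."""
    config = config or MinerConfig()
    records = fetch_activities(db, target_ids, organisms)
    records = apply_quality_filters(records, config)
    paff = compute_paffinity(records)
    paff = classify_and_filter(paff, config)
    return select_diverse_parents(paff, config.similarity_threshold, config)


def write_parents_smiles(parents: Sequence[ParentLigand],
                         path: str | Path) -> None:
    """SMILES<TAB>ligand_id<TAB>paffinity, one parent per line."""
    with open(path, "w") as fh:
        for p in parents:
            fh.write(f"{p.smiles}\t{p.ligand_id}\t{p.paffinity:.3f}\n")


def read_parents_smiles(path: str | Path) -> list[ParentLigand]:
    parents = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            smi, lid, paff = line.rstrip("\n").split("\t")
            parents.append(ParentLigand(lid, smi, float(paff)))
    return parents
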