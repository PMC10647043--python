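"""Docking orchestration, Pareto pose selection and isomeric-shift
prediction.

The docking engine is pluggable: anything implementing
:class:`DockingEngine` (the PLANTS adapter, or the deterministic mock
engine from :mod:`pswdesign.fixtures`) can drive the pipeline.  Scores
follow the ChemPLP convention — lower is better.

The isomeric-shift predictor converts docking scores to predicted pKi by
proportional scaling against the parent ligand,

    pKi_pred = parent_pAffinity * score / parent_score,

so a variant scoring exactly like its parent is predicted to bind
exactly as well, and a better (more negative) cis score gives a positive
shift delta_pKi = pKi(cis) - pKi(trans).  The predicted fold-change is
FC = 10^|delta_pKi|.  This mapping is a deliberate, documented
reconstruction (see docs/methods.md) and is isolated in
:func:`score_to_pki` so alternatives can be plugged in.
"""

from __future__ import annotations

import logging
import shutil
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .prep import BindingSite, PreparedLigand, Receptor

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.0   # Angstrom, ligand-receptor heavy atoms
DEFAULT_CLASH_CUTOFF = 2.5
DEFAULT_MIN_FOLD = 50.0
DEFAULT_N_POSES = 10


@dataclass
class DockedPose:
    """One scored pose of one prepared ligand variant."""

    variant_id: str
    pose_index: int
    coords: np.ndarray = field(repr=False)
    total_score: float
    score_terms: dict = field(default_factory=dict)
    n_contacts: int = 0
    n_clashes: int = 0
    n_uncontacted: int = 0


@dataclass
class ShiftPrediction:
    """Per-family isomeric-shift prediction.

    ``fold_change`` is the magnitude 10^|median delta_pKi|;
    ``fold_change_display`` carries the reporting convention in which
    cis-ON ligands are shown with negative values.
    """

    family_id: str
    parent_paffinity: float
    parent_score: float
    score_trans: float
    score_cis: float
    delta_score: float
    delta_pki: float
    fold_change: float
    fold_change_display: float
    active_isomer: str          # 'cis' | 'trans' | 'none'
    n_pairs: int
    pair_deltas: list = field(default_factory=list)


@runtime_checkable
class DockingEngine(Protocol):
    """Engine contract: produce up to n_poses scored poses for a ligand."""

    name: str

    def dock_one(self, receptor: Receptor, site: BindingSite,
                 ligand: PreparedLigand, n_poses: int
                 ) -> list[DockedPose]: ...


class EngineNotAvailable(RuntimeError):
    pass


class PlantsEngine:
    """Adapter for the PLANTS docking program (ChemPLP scoring).

    Invokes the external ``plants`` binary with the speed1 search setting
    and 20 ants, writing ligands in the MOL2 dialect the engine consumes.
    """

    name = "plants"

    def __init__(self, binary: str = "plants", search_speed: str = "speed1",
                 aco_ants: int = 20):
        self.binary = binary
        self.search_speed = search_speed
        self.aco_ants = aco_ants
        if shutil.which(binary) is None:
            raise EngineNotAvailable(
                f"docking engine {binary!r} not found on PATH; install "
                "PLANTS or use the mock engine "
                "(pswdesign.fixtures.make_mock_engine)")

    def dock_one(self, receptor, site, ligand, n_poses):  # pragma: no cover
        raise NotImplementedError(
            "PLANTS invocation requires the external binary")


def dock(engine: DockingEngine, receptor: Receptor, site: BindingSite,
         prepared_ligands: Sequence[PreparedLigand],
         n_poses: int = DEFAULT_N_POSES, workers: int = 1
         ) -> list[DockedPose]:
    """Dock every prepared variant; results are sorted by (variant_id,
    pose index) so the output is deterministic for any worker count.
    Per-ligand engine failures are logged and skipped."""
    def run(lig: PreparedLigand) -> list[DockedPose]:
        try:
            return engine.dock_one(receptor, site, lig, n_poses)
        except Exception as exc:
            logger.warning("engine %s failed on %s: %s",
                           getattr(engine, "name", "?"), lig.variant_id, exc)
            return []

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            chunks = list(pool.map(run, prepared_ligands))
    else:
        chunks = [run(lig) for lig in prepared_ligands]
    poses = [p for chunk in chunks for p in chunk]
    poses.sort(key=lambda p: (p.variant_id, p.pose_index))
    return poses


def compute_pose_metrics(coords: np.ndarray, receptor_coords: np.ndarray,
                         contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                         clash_cutoff: float = DEFAULT_CLASH_CUTOFF
                         ) -> tuple[int, int, int]:
    """(n_contacts, n_clashes, n_uncontacted) between ligand and receptor
    heavy atoms.  A contact is a pair within contact_cutoff; a clash is a
    pair closer than clash_cutoff (clashing pairs also count as
    contacts); an uncontacted atom is a ligand heavy atom with no
    receptor atom within contact_cutoff."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        return 0, 0, 0
    if receptor_coords.size == 0:
        return 0, 0, len(coords)
    d = cdist(coords, receptor_coords)
    contacts = d <= contact_cutoff
    n_contacts = int(contacts.sum())
    n_clashes = int((d < clash_cutoff).sum())
    n_uncontacted = int((~contacts.any(axis=1)).sum())
    return n_contacts, n_clashes, n_uncontacted


def annotate_poses(poses: Iterable[DockedPose], receptor: Receptor,
                   contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                   clash_cutoff: float = DEFAULT_CLASH_CUTOFF) -> None:
    for pose in poses:
        (pose.n_contacts, pose.n_clashes,
         pose.n_uncontacted) = compute_pose_metrics(
            pose.coords, receptor.heavy_coords, contact_cutoff, clash_cutoff)


def _dominates(a: DockedPose, b: DockedPose) -> bool:
    """True when a is at least as good as b in all four objectives
    (contacts max; clashes, uncontacted, score min) and better in one."""
    ge = (a.n_contacts >= b.n_contacts and a.n_clashes <= b.n_clashes
          and a.n_uncontacted <= b.n_uncontacted
          and a.total_score <= b.total_score)
    gt = (a.n_contacts > b.n_contacts or a.n_clashes < b.n_clashes
          or a.n_uncontacted < b.n_uncontacted
          or a.total_score < b.total_score)
    return ge and gt


def pareto_best_pose(poses: Sequence[DockedPose]) -> DockedPose:
    """The representative pose: a member of the 4-objective Pareto front
    (max contacts, min clashes, min uncontacted, min score); among front
    members the lowest score wins, remaining ties go to the lowest pose
    index."""
    if not poses:
        raise ValueError("pareto_best_pose requires at least one pose")
    front = [p for p in poses
             if not any(_dominates(q, p) for q in poses if q is not p)]
    return min(front, key=lambda p: (p.total_score, p.pose_index))


def score_to_pki(score: float, parent_score: float,
                 parent_paffinity: float) -> float:
    """Predicted pKi by proportional scaling against the parent ligand
    (see module docstring; the formula is a documented reconstruction)."""
    if parent_score == 0:
        raise ValueError("parent_score must be nonzero")
    return parent_paffinity * (score / parent_score)


def fold_change(delta_pki: float) -> float:
    """FC = 10^|delta_pKi| (magnitude; >= 1)."""
    return float(10.0 ** abs(delta_pki))


def predict_family_shift(family_poses: Sequence[DockedPose],
                         parent_paffinity: float,
                         family_id: str | None = None
                         ) -> ShiftPrediction:
    """Consensus isomeric-shift prediction for one design family.

    ``family_poses`` holds the poses of the parent and of every
    trans/cis variant of one family (variant ids of the form
    ``family|role|label``).  The best pose of each variant is selected
    by Pareto ranking; trans and cis variants are paired by label,
    unpaired variants are dropped; medians across pairs define the
    consensus active isomer.
    """
    groups: dict[tuple[str, str], list[DockedPose]] = {}
    fam = family_id
    for pose in family_poses:
        f, role, label = pose.variant_id.rsplit("|", 2)
        if fam is None:
            fam = f
        groups.setdefault((role, label), []).append(pose)
    best = {key: pareto_best_pose(plist) for key, plist in groups.items()}
    parents = [p for (role, _), p in best.items() if role == "parent"]
    if not parents:
        raise ValueError(f"family {fam}: no parent poses")
    parent_best = min(parents, key=lambda p: p.total_score)
    labels = sorted({lab for (role, lab) in best if role in ("trans", "cis")})
    pairs = []
    for lab in labels:
        t = best.get(("trans", lab))
        c = best.get(("cis", lab))
        if t is None or c is None:
            logger.info("family %s label %s: unpaired variant dropped",
                        fam, lab)
            continue
        dscore = c.total_score - t.total_score
        dpki = (score_to_pki(c.total_score, parent_best.total_score,
                             parent_paffinity)
                - score_to_pki(t.total_score, parent_best.total_score,
                               parent_paffinity))
        pairs.append({"label": lab, "score_trans": t.total_score,
                      "score_cis": c.total_score, "delta_score": dscore,
                      "delta_pki": dpki, "fold_change": fold_change(dpki)})
    if not pairs:
        raise ValueError(f"family {fam}: no complete trans/cis pair")
    med_dpki = float(np.median([p["delta_pki"] for p in pairs]))
    med_dscore = float(np.median([p["delta_score"] for p in pairs]))
    fc = fold_change(med_dpki)
    if med_dpki > 0:
        active, display = "cis", -fc
    elif med_dpki < 0:
        active, display = "trans", fc
    else:
        active, display = "none", fc
    return ShiftPrediction(
        family_id=fam, parent_paffinity=parent_paffinity,
        parent_score=parent_best.total_score,
        score_trans=float(np.median([p["score_trans"] for p in pairs])),
        score_cis=float(np.median([p["score_cis"] for p in pairs])),
        delta_score=med_dscore, delta_pki=med_dpki, fold_change=fc,
        fold_change_display=display, active_isomer=active,
        n_pairs=len(pairs), pair_deltas=pairs)


def apply_shift_filter(predictions: Iterable[ShiftPrediction],
                       min_fold: float | None = DEFAULT_MIN_FOLD
                       ) -> list[ShiftPrediction]:
    """Keep predictions with fold-change >= min_fold (boundary
    inclusive); None disables the filter."""
    preds = list(predictions)
    if min_fold is None:
        return preds
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1 (or None to disable)")
    return [p for p in preds if p.fold_change >= min_fold]


def predictions_to_frame(predictions: Sequence[ShiftPrediction]
                         ) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append({
            "family_id": p.family_id,
            "active_isomer": p.active_isomer,
            "parent_paffinity": p.parent_paffinity,
            "parent_score": p.parent_score,
            "score_trans": p.score_trans,
            "score_cis": p.score_cis,
            "delta_score": p.delta_score,
            "delta_pki": p.delta_pki,
            "fold_change": p.fold_change,
            "fold_change_display": p.fold_change_display,
            "n_pairs": p.n_pairs,
        })
    return pd.DataFrame(rows)


def write_report(predictions: Sequence[ShiftPrediction],
                 path) -> pd.DataFrame:
    df = predictions_to_frame(predictions)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
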