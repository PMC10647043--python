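"""Ligand and receptor preparation for structure-based screening.

Ligands: protonation at physiological pH by rule-based transformations
(basic amines protonated, carboxylic acids deprotonated), tautomer
enumeration (capped), 3D embedding by distance geometry and MMFF94
minimization with a torsion restraint that preserves the declared E/Z
geometry of the azo bond.

Receptors: PDB loading (local file or RCSB fetch), chain selection,
removal of waters/ions/foreign heteroatoms, and definition of the
docking sphere around a bound reference ligand.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD"}
ION_NAMES = {"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "BR", "IOD",
             "SO4", "PO4", "NO3", "ACT", "GOL", "EDO", "PEG"}
BACKBONE = ("N", "CA", "C", "O")

#: basic aliphatic amine, not amide/aniline/azo; protonated at pH 7.4
_BASIC_N = Chem.MolFromSmarts(
    "[NX3;H2,H1,H0;+0;!$(NC=[O,S,N]);!$(N-a);!$(N=*);!$(N-[O,N])]")
_ACID_O = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_AZO = Chem.MolFromSmarts("[a]-[NX2]=[NX2]-[a]")


class StructureError(RuntimeError):
    """Malformed or unusable structure file."""


@dataclass
class PreparedLigand:
    """One protonation/tautomer variant of one isomer, embedded in 3D."""

    family_id: str
    role: str                 # 'parent' | 'trans' | 'cis'
    label: str                # protomer/tautomer label, pairs trans with cis
    smiles: str
    mol: Chem.Mol = field(repr=False)
    formal_charge: int = 0
    energy: float = float("nan")

    @property
    def variant_id(self) -> str:
        return f"{self.family_id}|{self.role}|{self.label}"

    @property
    def heavy_coords(self) -> np.ndarray:
        conf = self.mol.GetConformer()
        idx = [a.GetIdx() for a in self.mol.GetAtoms()
               if a.GetAtomicNum() > 1]
        return np.array([list(conf.GetAtomPosition(i)) for i in idx])


@dataclass
class Receptor:
    """A single prepared protein chain."""

    source: str
    chain_id: str
    structure: gemmi.Structure = field(repr=False)
    heavy_coords: np.ndarray = field(repr=False)
    kept_het_ids: tuple[str, ...] = ()
    hydrogens_added: bool = False
    incomplete_residues: tuple[str, ...] = ()


@dataclass(frozen=True)
class BindingSite:
    """Docking sphere: heavy-atom centroid of the reference ligand plus an
    extra radius beyond its most distal heavy atom."""

    center: tuple[float, float, float]
    radius: float
    reference_ligand_id: str

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        return np.linalg.norm(xyz - np.asarray(self.center),
                              axis=-1) <= self.radius


# ---------------------------------------------------------------------------
# ligand preparation
# ---------------------------------------------------------------------------


def _apply_ph_rules(mol: Chem.Mol) -> Chem.Mol:
    """Rule-based protonation states at pH ~7.4."""
    mol = Chem.RWMol(mol)
    for (idx,) in mol.GetSubstructMatches(_BASIC_N):
        atom = mol.GetAtomWithIdx(idx)
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
    for match in mol.GetSubstructMatches(_ACID_O):
        o = mol.GetAtomWithIdx(match[2])
        o.SetFormalCharge(-1)
        o.SetNumExplicitHs(0)
        o.SetNoImplicit(True)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def _azo_dihedral(mol: Chem.Mol, conf_id: int = -1) -> float | None:
    """C-N=N-C torsion (degrees) of the first aromatic azo bond."""
    matches = mol.GetSubstructMatches(_AZO)
    if not matches:
        return None
    a, n1, n2, b = matches[0]
    from rdkit.Chem import rdMolTransforms
    return rdMolTransforms.GetDihedralDeg(mol.GetConformer(conf_id),
                                          a, n1, n2, b)


def azo_geometry_ok(mol: Chem.Mol, role: str, tol: float = 30.0) -> bool:
    """True when the azo C-N=N-C dihedral matches the declared isomer
    (trans within tol of 180, cis within tol of 0)."""
    dih = _azo_dihedral(mol)
    if dih is None:
        return True
    target = 180.0 if role == "trans" else 0.0
    dev = abs(abs(dih) - target) if role == "trans" else abs(dih)
    return dev <= tol


def _embed_minimize(mol: Chem.Mol, role: str, seed: int,
                    n_attempts: int = 10) -> tuple[Chem.Mol, float] | None:
    """Distance-geometry embedding + MMFF94 minimization; the azo torsion
    is restrained to the declared geometry.  Returns (molH, energy)."""
    molh = Chem.AddHs(mol)
    azo = molh.GetSubstructMatches(_AZO)
    for attempt in range(n_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + attempt
        if AllChem.EmbedMolecule(molh, params) != 0:
            continue
        try:
            props = AllChem.MMFFGetMoleculeProperties(molh)
            if props is None:
                return None
            ff = AllChem.MMFFGetMoleculeForceField(molh, props)
            if azo:
                a, n1, n2, b = azo[0]
                target = 180.0 if role != "cis" else 0.0
                ff.MMFFAddTorsionConstraint(a, n1, n2, b, False,
                                            target - 1.0, target + 1.0, 500.0)
            ff.Initialize()
            e0 = ff.CalcEnergy()
            ff.Minimize(maxIts=2000)
            energy = ff.CalcEnergy()
            if energy > e0 + 1e-6:
                continue
        except Exception:  # pragma: no cover - force-field edge cases
            continue
        if azo and not azo_geometry_ok(molh, role):
            continue
        return molh, float(energy)
    return None


def enumerate_tautomers(mol: Chem.Mol, cap: int = 4) -> list[Chem.Mol]:
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(max(cap, 1))
    res = enumerator.Enumerate(mol)
    tauts = list(res)[:cap] if res else [mol]
    return tauts or [mol]


def prepare_ligand_variants(family_id: str, role: str, smiles: str,
                            ph: float = 7.4, max_tautomers: int = 4,
                            seed: int = 42) -> list[PreparedLigand]:
    """Protonation/tautomer variants of one isomer, each embedded in 3D
    and MMFF94-minimized with the azo E/Z geometry preserved."""
    base = Chem.MolFromSmiles(smiles)
    if base is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    variants: list[PreparedLigand] = []
    seen: set[str] = set()
    for t_idx, taut in enumerate(enumerate_tautomers(base, max_tautomers)):
        # tautomer enumeration can drop stereo on exchangeable bonds; keep
        # only tautomers that preserved the azo geometry annotation
        if base.GetSubstructMatches(_AZO) and role in ("trans", "cis"):
            if "/N=N" not in Chem.MolToSmiles(taut) \
                    and "\\N=N" not in Chem.MolToSmiles(taut):
                if t_idx > 0:
                    continue
                taut = base
        prot = _apply_ph_rules(taut)
        smi = Chem.MolToSmiles(prot)
        if smi in seen:
            continue
        seen.add(smi)
        embedded = _embed_minimize(prot, role, seed)
        if embedded is None:
            logger.warning("embedding failed for %s tautomer %d",
                           family_id, t_idx)
            continue
        molh, energy = embedded
        variants.append(PreparedLigand(
            family_id=family_id, role=role, label=f"t{t_idx}",
            smiles=smi, mol=molh,
            formal_charge=Chem.GetFormalCharge(prot), energy=energy))
    if not variants:
        logger.warning("all variants failed for %s/%s", family_id, role)
    return variants


def prepare_design_family(design, parent_paffinity: float | None = None,
                          seed: int = 42, max_tautomers: int = 4
                          ) -> list[PreparedLigand]:
    """Prepared variants for a whole design family: the parent molecule
    plus the trans and cis isomers of the design."""
    out = prepare_ligand_variants(design.family_id, "parent",
                                  design.parent_smiles, seed=seed,
                                  max_tautomers=max_tautomers)
    out += prepare_ligand_variants(design.family_id, "trans",
                                   design.trans_smiles, seed=seed,
                                   max_tautomers=max_tautomers)
    out += prepare_ligand_variants(design.family_id, "cis",
                                   design.cis_smiles, seed=seed,
                                   max_tautomers=max_tautomers)
    return out


# ---------------------------------------------------------------------------
# receptor preparation
# ---------------------------------------------------------------------------


def load_structure(path: str | Path) -> gemmi.Structure:
    """Parse a local PDB file; malformed files raise
    :class:`StructureError` naming the first offending line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    known = ("ATOM", "HETATM", "HEADER", "TITLE", "REMARK", "MODEL",
             "ENDMDL", "TER", "END", "CRYST1", "SEQRES", "HELIX", "SHEET",
             "CONECT", "MASTER", "EXPDTA", "COMPND", "SOURCE", "SCALE",
             "ORIGX", "DBREF", "ANISOU", "HET", "FORMUL", "LINK", "SSBOND",
             "AUTHOR", "JRNL", "REVDAT", "KEYWDS", "SEQADV", "MODRES",
             "CISPEP", "SITE", "MTRIX")
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(known):
            raise StructureError(f"{path}: unrecognized record at line "
                                 f"{lineno}: {line[:20]!r}")
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise StructureError(
                    f"{path}: bad coordinates at line {lineno}") from None
            n_atoms += 1
    if n_atoms == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def fetch_structure(pdb_id: str, cache_dir: str | Path = ".") -> gemmi.Structure:
    """Download a PDB entry from RCSB (network access required)."""
    if not (len(pdb_id) == 4 and pdb_id[0].isdigit()):
        raise ValueError(f"malformed PDB id: {pdb_id!r}")
    dest = Path(cache_dir) / f"{pdb_id.lower()}.pdb"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                dest.write_bytes(resp.read())
        except Exception as exc:
            raise StructureError(f"could not fetch {pdb_id}: {exc}") from exc
    return load_structure(dest)


def structure_metadata(st: gemmi.Structure) -> dict:
    return {
        "title": st.name,
        "resolution": st.resolution if st.resolution > 0 else None,
        "chains": [ch.name for ch in st[0]],
    }


def _residue_is_water(res: gemmi.Residue) -> bool:
    return res.name in WATER_NAMES


def prepare_receptor(st: gemmi.Structure, chain: str,
                     keep_het_ids: tuple[str, ...] = (),
                     add_hydrogens: bool = False,
                     ph: float = 7.4) -> Receptor:
    """Reduce a structure to one chain: drop waters, ions and foreign
    heteroatoms (except ``keep_het_ids``), strip alternate locations, and
    flag residues with missing backbone atoms.  Deterministic."""
    model = st[0]
    names = [ch.name for ch in model]
    if chain not in names:
        raise ValueError(f"chain {chain!r} not present; available: "
                         + ", ".join(sorted(names)))
    out = gemmi.Structure()
    out.name = st.name
    out.resolution = st.resolution
    new_model = gemmi.Model("1")
    new_chain = gemmi.Chain(chain)
    incomplete: list[str] = []
    for res in model[chain]:
        if _residue_is_water(res):
            continue
        is_het = res.het_flag == "H"
        if is_het and res.name not in keep_het_ids:
            continue
        new_res = gemmi.Residue()
        new_res.name = res.name
        new_res.seqid = res.seqid
        new_res.het_flag = res.het_flag
        seen_names: set[str] = set()
        for atom in res:
            if atom.altloc not in ("", "\x00", "A"):
                continue
            if atom.name in seen_names:
                continue
            seen_names.add(atom.name)
            new_atom = gemmi.Atom()
            new_atom.name = atom.name
            new_atom.element = atom.element
            new_atom.pos = atom.pos
            new_atom.occ = atom.occ
            new_atom.b_iso = atom.b_iso
            new_res.add_atom(new_atom)
        if not is_het and not all(n in seen_names for n in BACKBONE):
            incomplete.append(f"{res.name}{res.seqid.num}")
        new_chain.add_residue(new_res)
    new_model.add_chain(new_chain)
    out.add_model(new_model)
    out.setup_entities()
    if add_hydrogens:
        out = _add_hydrogens_obabel(out, ph)
    coords = _heavy_coords(out, chain)
    return Receptor(source=st.name, chain_id=chain, structure=out,
                    heavy_coords=coords, kept_het_ids=tuple(keep_het_ids),
                    hydrogens_added=add_hydrogens,
                    incomplete_residues=tuple(incomplete))


def _heavy_coords(st: gemmi.Structure, chain: str) -> np.ndarray:
    coords = []
    for res in st[0][chain]:
        for atom in res:
            if atom.element.name != "H":
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.array(coords)


def _add_hydrogens_obabel(st: gemmi.Structure,
                          ph: float) -> gemmi.Structure:
    """Delegate protonation to the openbabel CLI (`obabel -p`)."""
    if shutil.which("obabel") is None:
        raise RuntimeError("obabel not found on PATH; "
                           "run with add_hydrogens=False")
    with tempfile.TemporaryDirectory() as tmp:
        src = Path(tmp) / "in.pdb"
        dst = Path(tmp) / "out.pdb"
        st.write_pdb(str(src))
        subprocess.run(["obabel", str(src), "-O", str(dst), "-p", str(ph)],
                       check=True, capture_output=True)
        return gemmi.read_structure(str(dst))


def get_het_residue(receptor: Receptor, het_id: str) -> gemmi.Residue:
    for res in receptor.structure[0][receptor.chain_id]:
        if res.name == het_id:
            return res
    raise ValueError(f"het group {het_id!r} not found in receptor")


def define_binding_site(receptor_or_coords, reference_ligand,
                        extra_radius: float = 2.0) -> BindingSite:
    """Docking sphere from a bound reference ligand: center at the
    heavy-atom centroid, radius = most distal heavy atom + extra_radius.

    ``reference_ligand`` may be a het-group name (looked up in the
    receptor), a gemmi residue, or an (n, 3) coordinate array.
    """
    if isinstance(reference_ligand, str):
        reference_ligand = get_het_residue(receptor_or_coords,
                                           reference_ligand)
        ref_id = reference_ligand.name
    else:
        ref_id = getattr(reference_ligand, "name", "reference")
    if isinstance(reference_ligand, gemmi.Residue):
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z]
                           for a in reference_ligand
                           if a.element.name != "H"])
    else:
        coords = np.asarray(reference_ligand, dtype=float)
    if coords.size == 0:
        raise ValueError("reference ligand has no heavy atoms")
    center = coords.mean(axis=0)
    radius = float(np.max(np.linalg.norm(coords - center, axis=1))
                   + extra_radius)
    return BindingSite(center=tuple(float(x) for x in center),
                       radius=radius, reference_ligand_id=ref_id)


def write_site(site: BindingSite, path: str | Path) -> None:
    """Small key-value export of the docking sphere."""
    with open(path, "w") as fh:
        cx, cy, cz = site.center
        fh.write(f"center {cx:.3f} {cy:.3f} {cz:.3f}\n")
        fh.write(f"radius {site.radius:.3f}\n")
        fh.write(f"reference {site.reference_ligand_id}\n")


def write_ligands_sdf(ligands, path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    for lig in ligands:
        mol = Chem.Mol(lig.mol)
        mol.SetProp("_Name", lig.variant_id)
        mol.SetProp("family_id", lig.family_id)
        mol.SetProp("isomer", lig.role)
        mol.SetProp("label", lig.label)
        mol.SetProp("energy", f"{lig.energy:.4f}")
        writer.write(mol)
    writer.close()
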