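"""Enumeration of azobenzene photoswitch designs from parent ligands.

Two incorporation strategies are implemented as SMARTS reactions:

* **azologization** — a 0- to 3-atom acyclic linker joining two
  (hetero)aromatic rings is replaced by an azo bond (``-N=N-``).  The
  two-atom, unbranched case is the "typical" azologization (the classic
  stilbene → azobenzene swap); 0-, 1- and 3-atom linkers, optionally
  carrying one-atom branches, are "atypical".  A special atypical family
  replaces a mono- or disubstituted fused 6-6 aromatic bicycle
  (naphthalene-like) with an azobenzene, remapping the substituents onto
  the two phenyl rings.
* **azoextension** — a phenyldiazene group (``-N=N-C6H5``) is appended at
  every free aromatic C-H position ("typical"), or replaces a small
  (1-3 heavy atom) substituent ("atypical").

Every enumerated product is emitted as a *flat* constitution first; the
E (trans) / Z (cis) pair is generated afterwards by assigning geometry to
the newly created azo bond only, so parents that already contain azo
groups keep their original stereochemistry.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdFMCS

logger = logging.getLogger(__name__)

CATEGORIES = (
    "typical_azologization",
    "atypical_azologization",
    "naphthalene_azologization",
    "typical_azoextension",
    "atypical_azoextension",
)

AZOLOGIZATION_CATEGORIES = frozenset(CATEGORIES[:3])

#: aromatic-C azo motif; symmetric, so raw match counts are doubled
_AZO_MOTIF = Chem.MolFromSmarts("[a]-[NX2]=[NX2]-[a]")

# Acyclic linker atoms eligible for replacement (C, N, O, S; aliphatic,
# not in a ring).  "D2" = unbranched chain atom, "D3" = one branch.
_L2 = "[#6,#7,#8,#16;A;!R;D2:{m}]"
_L3 = "[#6,#7,#8,#16;A;!R;D3:{m}](~[*;D1:{b}])"

_PHENYLDIAZENE = "-N=N-c1ccccc1"


class RuleError(ValueError):
    """Invalid rule-set request (unknown category, bad mode)."""


@dataclass(frozen=True)
class TransformationRule:
    """A named SMARTS reaction converting a parent into an azo design.

    ``heavy_atom_delta`` is the expected change in heavy-atom count of the
    product relative to the parent and is asserted during enumeration.
    """

    name: str
    category: str
    reaction: str
    params: dict = field(default_factory=dict, compare=False)
    heavy_atom_delta: int | None = field(default=None, compare=False)

    def to_reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.reaction)
        if rxn is None:
            raise RuleError(f"rule {self.name}: reaction SMARTS does not parse")
        return rxn


@dataclass
class PSWDesign:
    """One parent → photoswitchable-product transformation.

    ``trans_smiles``/``cis_smiles`` are empty until
    :func:`enumerate_ez_isomers` has run; ``provenance`` accumulates the
    (rule, family) pairs merged by deduplication.
    """

    parent_id: str
    parent_smiles: str
    rule_name: str
    product_smiles_flat: str
    family_id: str
    trans_smiles: str = ""
    cis_smiles: str = ""
    provenance: list[str] = field(default_factory=list)
    mol: Chem.Mol | None = field(default=None, repr=False)
    azo_atoms: tuple[int, int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [self.rule_name]


@dataclass(frozen=True)
class DescriptorRecord:
    """Constitution-level physicochemical descriptors of one design."""

    family_id: str
    logp: float
    tpsa: float
    mol_weight: float
    fraction_csp3: float
    heavy_atoms: int


# ---------------------------------------------------------------------------
# rule construction
# ---------------------------------------------------------------------------


def _linker_rule(name: str, n_atoms: int, branches: Sequence[bool],
                 category: str) -> TransformationRule:
    """Azologization rule replacing an ``n_atoms`` linker (branch flags per
    linker atom) between two aromatic carbons by N=N."""
    parts = ["[c:1]"]
    m = 2
    b = 50
    for i in range(n_atoms):
        if branches[i]:
            parts.append(_L3.format(m=m, b=b))
            b += 1
        else:
            parts.append(_L2.format(m=m))
        m += 1
    parts.append(f"[c:{m}]")
    reactant = "~".join(parts)
    product = f"[c:1]-N=N-[c:{m}]"
    # linker atoms + branches vanish, two N appear
    delta = 2 - n_atoms - sum(branches)
    return TransformationRule(
        name=name, category=category, reaction=f"{reactant}>>{product}",
        params={"linker_atoms": n_atoms, "branches": list(branches)},
        heavy_atom_delta=delta,
    )


def _typical_azologization_rules() -> list[TransformationRule]:
    return [_linker_rule("Azolog_2atom", 2, (False, False),
                         "typical_azologization")]


def _atypical_azologization_rules() -> list[TransformationRule]:
    rules = [
        TransformationRule(
            name="Azolog_0atom", category="atypical_azologization",
            reaction="[c:1]-!@[c:2]>>[c:1]-N=N-[c:2]",
            params={"linker_atoms": 0}, heavy_atom_delta=2,
        ),
        _linker_rule("Azolog_1atom", 1, (False,), "atypical_azologization"),
        _linker_rule("Azolog_1atom_branched", 1, (True,),
                     "atypical_azologization"),
    ]
    for flags in itertools.product((False, True), repeat=3):
        tag = "".join("b" if f else "u" for f in flags)
        rules.append(_linker_rule(f"Azolog_3atom_{tag}", 3, flags,
                                  "atypical_azologization"))
    return rules


# Fused 6-6 aromatic bicycle written as a 10-atom chain with ring closures
# 1 (atoms 1-10) and 2 (atoms 4-9); chain atoms 4 and 9 are the fusion
# positions.  Standard naphthalene numbering of the remaining chain atoms:
_CHAIN_TO_NAPH = {3: 1, 2: 2, 1: 3, 10: 4, 8: 5, 7: 6, 6: 7, 5: 8}
# Azobenzene target offsets (position relative to the azo-bearing ipso
# carbon, 2=ortho .. 5=meta') for the two orientations of each ring: the
# ring is laid onto a phenyl with one of its two fusion atoms becoming the
# ipso carbon.
_ORIENT = {
    "ring1": ({3: 2, 2: 3, 1: 4, 10: 5}, {10: 2, 1: 3, 2: 4, 3: 5}),
    "ring2": ({5: 2, 6: 3, 7: 4, 8: 5}, {8: 2, 7: 3, 6: 4, 5: 5}),
}
_RING1 = (1, 2, 3, 10)


def _naphthalene_pattern(subs: dict[int, int]) -> str:
    """Reactant SMARTS for the bicycle with mapped substituents at the
    given chain positions; all other non-fusion positions unsubstituted."""
    def atom(i: int) -> str:
        if i in (4, 9):
            return f"[a;D3:{i}]"
        if i in subs:
            return f"[a;D3:{i}](-!@[*:{subs[i]}])"
        return f"[a;D2:{i}]"

    a = {i: atom(i) for i in range(1, 11)}
    return (f"{a[1]}1:{a[2]}:{a[3]}:{a[4]}2:{a[5]}:{a[6]}:{a[7]}:"
            f"{a[8]}:{a[9]}:2:{a[10]}:1")


def _phenyl(subs: dict[int, int], azo_branch: str = "",
            ring_idx: int = 8) -> str:
    """Product-template phenyl written from the ipso carbon; ``subs`` maps
    ring offset (2..6) to the atom-map label re-attached there."""
    out = f"c{ring_idx}" + (f"({azo_branch})" if azo_branch else "")
    for pos in range(2, 7):
        out += "c"
        if pos in subs:
            out += f"(-[*:{subs[pos]}])"
    return out + str(ring_idx)


def _naphthalene_rules(mode: str) -> list[TransformationRule]:
    if mode not in ("mono", "di", "both"):
        raise RuleError(f"naphthalene_mode must be mono|di|both, got {mode!r}")
    rules: list[TransformationRule] = []

    def add(name: str, subs: dict[int, int], subs_a: dict[int, int],
            subs_b: dict[int, int], n_subs: int) -> None:
        reactant = _naphthalene_pattern(subs)
        product = _phenyl(subs_a, ring_idx=8,
                          azo_branch="-N=N-" + _phenyl(subs_b, ring_idx=9))
        rules.append(TransformationRule(
            name=name, category="naphthalene_azologization",
            reaction=f"{reactant}>>{product}",
            params={"n_substituents": n_subs}, heavy_atom_delta=4,
        ))

    if mode in ("mono", "both"):
        # one substituent; chain 3 (alpha, naphthalene C1) and chain 2
        # (beta, C2) cover all positions by symmetry
        for chain in (3, 2):
            naph = _CHAIN_TO_NAPH[chain]
            for orient in _ORIENT["ring1"]:
                off = orient[chain]
                add(f"Naphtho_{naph}_ABz_{off}a", {chain: 20},
                    {off: 20}, {}, 1)
    if mode in ("di", "both"):
        # the 10 substitution patterns of a fused 6-6 bicycle, as
        # (chain, chain) pairs in standard numbering order
        pairs = [(3, 2), (3, 1), (3, 10), (3, 8), (3, 7), (3, 6), (3, 5),
                 (2, 1), (2, 7), (2, 6)]
        for c1, c2 in pairs:
            n1, n2 = _CHAIN_TO_NAPH[c1], _CHAIN_TO_NAPH[c2]
            same_ring = c2 in _RING1
            if same_ring:
                combos = [(o, o) for o in _ORIENT["ring1"]]
            else:
                combos = list(itertools.product(_ORIENT["ring1"],
                                                _ORIENT["ring2"]))
            for o1, o2 in combos:
                t1, t2 = o1[c1], o2[c2]
                if same_ring:
                    suffix = f"{t1}a{t2}a"
                    subs_a, subs_b = {t1: 20, t2: 21}, {}
                else:
                    suffix = f"{t1}a{t2}b"
                    subs_a, subs_b = {t1: 20}, {t2: 21}
                add(f"Naphtho_{n1}_{n2}_ABz_{suffix}",
                    {c1: 20, c2: 21}, subs_a, subs_b, 2)
    return rules


def _typical_azoextension_rules() -> list[TransformationRule]:
    return [TransformationRule(
        name="Azoext_CH", category="typical_azoextension",
        reaction=f"[cH:1]>>[c:1]{_PHENYLDIAZENE}",
        params={"replaced_atoms": 0}, heavy_atom_delta=8,
    )]


def _atypical_azoextension_rules(max_replaced: int) -> list[TransformationRule]:
    if max_replaced not in (1, 2, 3):
        raise RuleError("max_replaced_substituent must be 1, 2 or 3")
    specs = [("Azoext_repl1", "[c:1]-!@[*;D1:2]", 1)]
    if max_replaced >= 2:
        specs.append(("Azoext_repl2", "[c:1]-!@[*;!R;D2:2]~[*;D1:3]", 2))
    if max_replaced >= 3:
        specs.append(("Azoext_repl3",
                      "[c:1]-!@[*;!R;D2:2]~[*;!R;D2:3]~[*;D1:4]", 3))
        specs.append(("Azoext_repl3_branched",
                      "[c:1]-!@[*;!R;D3:2](~[*;D1:3])~[*;D1:4]", 3))
    return [TransformationRule(
        name=name, category="atypical_azoextension",
        reaction=f"{smarts}>>[c:1]{_PHENYLDIAZENE}",
        params={"replaced_atoms": n}, heavy_atom_delta=8 - n,
    ) for name, smarts, n in specs]


def build_rule_set(categories: Iterable[str] = CATEGORIES,
                   naphthalene_mode: str = "both",
                   max_replaced_substituent: int = 1,
                   ) -> list[TransformationRule]:
    """Build the deterministic, named transformation-rule list for the
    requested categories.

    Parameters
    ----------
    categories
        Subset of :data:`CATEGORIES`.
    naphthalene_mode
        ``mono``, ``di`` or ``both`` — which substitution counts of the
        fused-bicycle replacement family to include.
    max_replaced_substituent
        Largest substituent (heavy atoms, 1-3) that atypical azoextension
        may displace.
    """
    categories = list(categories)
    if not categories:
        raise RuleError("categories must be non-empty")
    for cat in categories:
        if cat not in CATEGORIES:
            raise RuleError(f"unknown category {cat!r}")
    rules: list[TransformationRule] = []
    if "typical_azologization" in categories:
        rules += _typical_azologization_rules()
    if "atypical_azologization" in categories:
        rules += _atypical_azologization_rules()
    if "naphthalene_azologization" in categories:
        rules += _naphthalene_rules(naphthalene_mode)
    if "typical_azoextension" in categories:
        rules += _typical_azoextension_rules()
    if "atypical_azoextension" in categories:
        rules += _atypical_azoextension_rules(max_replaced_substituent)
    for rule in rules:  # every reaction must parse up front
        rule.to_reaction()
    return rules


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def count_azo_motifs(mol: Chem.Mol) -> int:
    """Number of aromatic-C-N=N-C-aromatic motifs (one per azo bond)."""
    return len(mol.GetSubstructMatches(_AZO_MOTIF))


def _new_azo_bond(product: Chem.Mol) -> tuple[int, int] | None:
    """Locate the azo bond created by the reaction: the N=N between atoms
    that did not come from the reactant (no ``react_atom_idx``)."""
    for bond in product.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if (bond.GetBondType() == Chem.BondType.DOUBLE
                and a.GetAtomicNum() == 7 and b.GetAtomicNum() == 7
                and not a.HasProp("react_atom_idx")
                and not b.HasProp("react_atom_idx")):
            return a.GetIdx(), b.GetIdx()
    return None


def _apply_rule(parent_mol: Chem.Mol, rule: TransformationRule
                ) -> list[tuple[str, Chem.Mol, tuple[int, int]]]:
    """Run one rule exhaustively; returns (flat canonical SMILES, product
    mol, new azo bond atoms) per distinct product."""
    rxn = rule.to_reaction()
    out: list[tuple[str, Chem.Mol, tuple[int, int]]] = []
    seen: set[str] = set()
    parent_nha = parent_mol.GetNumHeavyAtoms()
    for (product,) in rxn.RunReactants((parent_mol,)):
        try:
            Chem.SanitizeMol(product)
        except Exception:  # pragma: no cover - exotic chemistry
            continue
        azo = _new_azo_bond(product)
        if azo is None:
            continue
        if (rule.heavy_atom_delta is not None
                and product.GetNumHeavyAtoms() - parent_nha
                != rule.heavy_atom_delta):
            logger.warning("rule %s: heavy-atom delta mismatch, skipping",
                           rule.name)
            continue
        smi = Chem.MolToSmiles(product)
        if smi in seen:
            continue
        seen.add(smi)
        out.append((smi, product, azo))
    return out


def _designs_from_rules(parent_id: str, parent_smiles: str,
                        parent_mol: Chem.Mol,
                        rules: Iterable[TransformationRule]
                        ) -> list[PSWDesign]:
    designs = []
    for rule in rules:
        for site, (smi, mol, azo) in enumerate(_apply_rule(parent_mol, rule)):
            designs.append(PSWDesign(
                parent_id=parent_id, parent_smiles=parent_smiles,
                rule_name=rule.name, product_smiles_flat=smi,
                family_id=f"{parent_id}|{rule.name}|{site}",
                mol=mol, azo_atoms=azo,
            ))
    return designs


def _parse_parent(parent_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(parent_smiles)
    if mol is None:
        raise ValueError(f"parent SMILES does not parse: {parent_smiles!r}")
    return mol


def run_azologization(parent_id: str, parent_smiles: str,
                      rules: Sequence[TransformationRule]) -> list[PSWDesign]:
    """Apply azologization rules (typical/atypical/naphthalene) at every
    matching site of the parent.  Returns flat designs (no E/Z yet)."""
    mol = _parse_parent(parent_smiles)
    azo_rules = [r for r in rules if r.category in AZOLOGIZATION_CATEGORIES]
    return _designs_from_rules(parent_id, parent_smiles, mol, azo_rules)


def run_naphthalene_azologization(parent_id: str, parent_smiles: str,
                                  mode: str = "both") -> list[PSWDesign]:
    """Replace a mono-/disubstituted fused 6-6 aromatic bicycle with an
    azobenzene, remapping substituents onto both ring orientations."""
    mol = _parse_parent(parent_smiles)
    return _designs_from_rules(parent_id, parent_smiles, mol,
                               _naphthalene_rules(mode))


def run_azoextension(parent_id: str, parent_smiles: str,
                     rules: Sequence[TransformationRule] | None = None,
                     max_replaced_substituent: int = 1) -> list[PSWDesign]:
    """Append a phenyldiazene at every free aromatic C-H (typical) and in
    place of every small substituent (atypical)."""
    mol = _parse_parent(parent_smiles)
    if rules is None:
        rules = (_typical_azoextension_rules()
                 + _atypical_azoextension_rules(max_replaced_substituent))
    ext = [r for r in rules if r.category.endswith("azoextension")]
    return _designs_from_rules(parent_id, parent_smiles, mol, ext)


def enumerate_ez_isomers(design: PSWDesign) -> tuple[str, str] | None:
    """Assign E (trans) and Z (cis) geometry to the newly created azo bond
    only; returns the pair of isomeric SMILES, or ``None`` (and leaves the
    design unmodified) when the azo bond sits in a ring too small (< 9)
    for Z/E isomerism."""
    if design.mol is None or design.azo_atoms is None:
        raise ValueError(f"design {design.family_id} has no tracked azo bond")
    mol = Chem.Mol(design.mol)
    i, j = design.azo_atoms
    bond = mol.GetBondBetweenAtoms(i, j)
    ring_info = mol.GetRingInfo()
    if ring_info.NumBondRings(bond.GetIdx()):
        if min(len(r) for r in ring_info.BondRings()
               if bond.GetIdx() in r) < 9:
            logger.warning("design %s: azo bond in small ring, dropped",
                           design.family_id)
            return None
    ni = mol.GetAtomWithIdx(i)
    nj = mol.GetAtomWithIdx(j)
    ci = min(a.GetIdx() for a in ni.GetNeighbors() if a.GetIdx() != j)
    cj = min(a.GetIdx() for a in nj.GetNeighbors() if a.GetIdx() != i)
    bond.SetStereoAtoms(ci, cj)
    smiles = {}
    for label, stereo in (("trans", Chem.BondStereo.STEREOE),
                          ("cis", Chem.BondStereo.STEREOZ)):
        bond.SetStereo(stereo)
        Chem.SetDoubleBondNeighborDirections(mol)
        smiles[label] = Chem.MolToSmiles(mol)
    design.trans_smiles = smiles["trans"]
    design.cis_smiles = smiles["cis"]
    return smiles["trans"], smiles["cis"]


def deduplicate_designs(designs: Sequence[PSWDesign]) -> list[PSWDesign]:
    """Collapse designs with the same flat canonical product SMILES; the
    first-seen design keeps its identity, merged provenance recorded."""
    out: dict[str, PSWDesign] = {}
    for d in designs:
        kept = out.get(d.product_smiles_flat)
        if kept is None:
            out[d.product_smiles_flat] = d
        else:
            for p in d.provenance:
                if p not in kept.provenance:
                    kept.provenance.append(p)
    return list(out.values())


def compute_descriptors(design: PSWDesign) -> DescriptorRecord:
    """Constitution-level descriptors (identical for trans/cis)."""
    mol = Chem.MolFromSmiles(design.product_smiles_flat)
    if mol is None:
        raise ValueError(
            f"design {design.family_id}: product SMILES does not parse")
    return DescriptorRecord(
        family_id=design.family_id,
        logp=Descriptors.MolLogP(mol),
        tpsa=Descriptors.TPSA(mol),
        mol_weight=Descriptors.MolWt(mol),
        fraction_csp3=Descriptors.FractionCSP3(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
    )


def map_parent_atoms(design: PSWDesign, min_fragment: int = 3
                     ) -> dict[int, int]:
    """Parent → product atom correspondence (unmapped parent atoms are the
    transformed region).

    Common substructures are extracted iteratively — already-mapped atoms
    are masked and the search repeated — so that disconnected conserved
    fragments (e.g. the two phenyls of a bibenzyl parent flanking the
    replaced linker) are all captured, not just the largest one.
    """
    parent = Chem.RWMol(Chem.MolFromSmiles(design.parent_smiles))
    product = Chem.RWMol(Chem.MolFromSmiles(design.product_smiles_flat))
    mapping: dict[int, int] = {}
    for _ in range(8):
        res = rdFMCS.FindMCS([parent, product], timeout=10,
                             bondCompare=rdFMCS.BondCompare.CompareAny)
        if res.canceled or res.numAtoms < min_fragment:
            break
        query = Chem.MolFromSmarts(res.smartsString)
        pm = parent.GetSubstructMatch(query)
        qm = product.GetSubstructMatch(query)
        if not pm or not qm:
            break
        mapping.update(zip(pm, qm))
        # mask matched atoms with sentinels that cannot match anything
        for idx in pm:
            parent.GetAtomWithIdx(idx).SetAtomicNum(54)
        for idx in qm:
            product.GetAtomWithIdx(idx).SetAtomicNum(86)
    return mapping


def enumerate_designs(parent_id: str, parent_smiles: str,
                      rules: Sequence[TransformationRule]) -> list[PSWDesign]:
    """Full enumeration for one parent: apply every rule exhaustively,
    deduplicate by flat constitution, then generate the trans/cis pair."""
    mol = _parse_parent(parent_smiles)
    designs = _designs_from_rules(parent_id, parent_smiles, mol, rules)
    designs = deduplicate_designs(designs)
    kept = []
    for d in designs:
        if enumerate_ez_isomers(d) is not None:
            kept.append(d)
    return kept
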