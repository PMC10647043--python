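"""Transformation-rule enumeration: golden products, bookkeeping
invariants, E/Z handling and deduplication."""

import pytest
from rdkit import Chem

from pswdesign import reactor


def canon(smiles: str) -> str:
    return Chem.CanonSmiles(smiles)


def enumerate_category(case, category, naphthalene_mode="both",
                       max_replaced=1):
    rules = reactor.build_rule_set([category], naphthalene_mode,
                                   max_replaced)
    return reactor.enumerate_designs(case.name, case.smiles, rules)


class TestRuleSet:
    def test_all_reactions_parse_and_products_contain_azo(self, all_rules):
        for rule in all_rules:
            rxn = rule.to_reaction()
            prod = rxn.GetProductTemplate(0)
            symbols = [a.GetSymbol() for a in prod.GetAtoms()]
            assert symbols.count("N") >= 2, rule.name

    def test_rule_list_is_deterministic(self):
        a = [r.name for r in reactor.build_rule_set()]
        b = [r.name for r in reactor.build_rule_set()]
        assert a == b

    def test_unknown_category_rejected(self):
        with pytest.raises(reactor.RuleError):
            reactor.build_rule_set(["sulfur_switch"])
        with pytest.raises(reactor.RuleError):
            reactor.build_rule_set([])

    def test_naphthalene_mode_validated(self):
        with pytest.raises(reactor.RuleError):
            reactor.build_rule_set(["naphthalene_azologization"],
                                   naphthalene_mode="tri")

    def test_typical_rule_matches_two_atom_linker(self, all_rules):
        rule = next(r for r in all_rules if r.category ==
                    "typical_azologization")
        rxn = rule.to_reaction()
        bibenzyl = Chem.MolFromSmiles("C(c1ccccc1)Cc1ccccc1")
        assert rxn.RunReactants((bibenzyl,))
        # branched two-atom linkers are not "typical"
        branched = Chem.MolFromSmiles("CC(c1ccccc1)Cc1ccccc1")
        products = rxn.RunReactants((branched,))
        assert not products

    def test_atypical_includes_ring_ring_single_bond_rule(self, all_rules):
        names = [r.name for r in all_rules
                 if r.category == "atypical_azologization"]
        assert "Azolog_0atom" in names


class TestGoldenProducts:
    """Every toy-catalog case must reproduce its hand-derived product
    set exactly."""

    def test_expected_product_sets(self, toy_catalog):
        for case in toy_catalog.values():
            for category, expected in case.expected.items():
                designs = enumerate_category(case, category)
                got = {canon(d.product_smiles_flat) for d in designs}
                assert got == {canon(s) for s in expected}, case.name

    def test_expected_unique_counts(self, toy_catalog):
        for case in toy_catalog.values():
            for category, n in case.expected_counts.items():
                designs = enumerate_category(case, category)
                assert len(designs) == n, (case.name, category)

    def test_unsubstituted_naphthalene_yields_nothing(self):
        designs = reactor.run_naphthalene_azologization(
            "naph", "c1ccc2ccccc2c1", "both")
        assert designs == []

    def test_disubstituted_includes_para_para_product(self):
        designs = reactor.run_naphthalene_azologization(
            "dmn", "Cc1ccc2cc(C)ccc2c1", "di")
        got = {canon(d.product_smiles_flat)
               for d in reactor.deduplicate_designs(designs)}
        assert canon("Cc1ccc(N=Nc2ccc(C)cc2)cc1") in got

    def test_fluorine_replacement_azoextension(self):
        designs = reactor.run_azoextension("fb", "Fc1ccccc1",
                                           max_replaced_substituent=1)
        got = {canon(d.product_smiles_flat) for d in designs}
        assert canon("c1ccc(N=Nc2ccccc2)cc1") in got

    def test_larger_substituent_replacement_requires_flag(self):
        # an ethyl group (2 heavy atoms) is only displaced at max >= 2
        at_1 = reactor.run_azoextension("eb", "CCc1ccccc1",
                                        max_replaced_substituent=1)
        at_2 = reactor.run_azoextension("eb", "CCc1ccccc1",
                                        max_replaced_substituent=2)
        azb = canon("c1ccc(N=Nc2ccccc2)cc1")
        assert azb not in {canon(d.product_smiles_flat) for d in at_1}
        assert azb in {canon(d.product_smiles_flat) for d in at_2}


class TestInvariants:
    def test_heavy_atom_bookkeeping(self, toy_catalog, all_rules):
        by_name = {r.name: r for r in all_rules}
        for case in toy_catalog.values():
            designs = (reactor.run_azologization(case.name, case.smiles,
                                                 all_rules)
                       + reactor.run_azoextension(case.name, case.smiles,
                                                  all_rules))
            parent_nha = Chem.MolFromSmiles(case.smiles).GetNumHeavyAtoms()
            for d in designs:
                delta = by_name[d.rule_name].heavy_atom_delta
                product = Chem.MolFromSmiles(d.product_smiles_flat)
                assert product.GetNumHeavyAtoms() == parent_nha + delta

    def test_azo_motif_count_increases_by_one(self, toy_catalog, all_rules):
        for case in toy_catalog.values():
            parent = Chem.MolFromSmiles(case.smiles)
            n0 = reactor.count_azo_motifs(parent)
            for d in reactor.enumerate_designs(case.name, case.smiles,
                                               all_rules):
                product = Chem.MolFromSmiles(d.product_smiles_flat)
                assert reactor.count_azo_motifs(product) == n0 + 1

    def test_trans_cis_constitution_identity(self, toy_catalog, all_rules):
        def strip(smi):
            mol = Chem.MolFromSmiles(smi)
            Chem.RemoveStereochemistry(mol)
            return Chem.MolToSmiles(mol)

        for case in toy_catalog.values():
            for d in reactor.enumerate_designs(case.name, case.smiles,
                                               all_rules):
                assert d.trans_smiles != d.cis_smiles
                assert strip(d.trans_smiles) == strip(d.cis_smiles)

    def test_enumeration_is_atom_order_independent(self, all_rules):
        smi = "CC(C)NCC(O)COc1cccc2ccccc12"  # propranolol
        mol = Chem.MolFromSmiles(smi)
        order = list(range(mol.GetNumAtoms()))[::-1]
        permuted = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order),
                                    canonical=False)
        ref = {d.product_smiles_flat
               for d in reactor.enumerate_designs("p", smi, all_rules)}
        out = {d.product_smiles_flat
               for d in reactor.enumerate_designs("p", permuted, all_rules)}
        assert ref == out


class TestEZAndDedup:
    def test_flat_azobenzene_gives_distinct_isomeric_pair(self, all_rules):
        d = reactor.enumerate_designs(
            "bb", "C(c1ccccc1)Cc1ccccc1",
            [r for r in all_rules if r.name == "Azolog_2atom"])[0]
        assert "/N=N/" in d.trans_smiles
        assert "/N=N\\" in d.cis_smiles

    def test_existing_azo_bond_is_untouched(self, all_rules):
        parent = "C(Cc1ccccc1)c1ccc(/N=N/c2ccccc2)cc1"
        d = reactor.enumerate_designs(
            "p", parent,
            [r for r in all_rules if r.name == "Azolog_2atom"])[0]
        # the pre-existing bond stays E in both isomers: exactly one
        # Z-marked azo bond may appear, and only in the cis product
        assert d.trans_smiles.count("/N=N\\") == 0
        assert d.cis_smiles.count("/N=N\\") == 1

    def test_dedup_collapses_symmetric_azoextension(self):
        designs = reactor.run_azoextension("bz", "c1ccccc1")
        assert len(designs) == 1  # all six positions are equivalent

    def test_dedup_is_idempotent_and_monotone(self, all_rules):
        designs = reactor.run_azologization(
            "dmn", "Cc1ccc2cc(C)ccc2c1", all_rules)
        once = reactor.deduplicate_designs(designs)
        twice = reactor.deduplicate_designs(once)
        assert len(once) <= len(designs)
        assert [d.product_smiles_flat for d in once] == \
               [d.product_smiles_flat for d in twice]

    def test_rule_collision_merges_provenance(self):
        # identical 2,6-substituents: the 3a4b and 4a3b orientation rules
        # produce the same compound, which must merge into one design
        designs = reactor.run_naphthalene_azologization(
            "dmn", "Cc1ccc2cc(C)ccc2c1", "di")
        merged = [d for d in reactor.deduplicate_designs(designs)
                  if len(d.provenance) == 2]
        assert merged, "expected a two-rule provenance merge"


class TestDescriptorsAndMapping:
    def test_azobenzene_molecular_weight(self, all_rules):
        d = reactor.enumerate_designs(
            "bz", "c1ccccc1",
            [r for r in all_rules if r.category == "typical_azoextension"])[0]
        rec = reactor.compute_descriptors(d)
        assert rec.mol_weight == pytest.approx(182.2, abs=0.1)
        assert rec.heavy_atoms == 14

    def test_saturated_fragment_fraction_sp3(self):
        d = reactor.PSWDesign("x", "C1CCCCC1", "manual", "C1CCCCC1", "x|m|0")
        rec = reactor.compute_descriptors(d)
        assert rec.fraction_csp3 == 1.0

    def test_descriptors_identical_for_trans_and_cis(self, all_rules):
        from dataclasses import replace
        d = reactor.enumerate_designs(
            "tol", "Cc1ccccc1",
            [r for r in all_rules if r.category == "typical_azoextension"])[0]
        rec_t = reactor.compute_descriptors(
            replace_smiles(d, d.trans_smiles))
        rec_c = reactor.compute_descriptors(
            replace_smiles(d, d.cis_smiles))
        assert (rec_t.logp, rec_t.tpsa, rec_t.mol_weight) == \
               (rec_c.logp, rec_c.tpsa, rec_c.mol_weight)

    def test_azoextension_maps_whole_parent(self, all_rules):
        d = reactor.enumerate_designs(
            "tol", "Cc1ccccc1",
            [r for r in all_rules if r.category == "typical_azoextension"])[0]
        mapping = reactor.map_parent_atoms(d)
        assert len(mapping) == 7  # every parent heavy atom is conserved

    def test_azologization_maps_phenyls_not_linker(self, all_rules):
        d = reactor.enumerate_designs(
            "bb", "C(c1ccccc1)Cc1ccccc1",
            [r for r in all_rules if r.name == "Azolog_2atom"])[0]
        mapping = reactor.map_parent_atoms(d)
        parent = Chem.MolFromSmiles(d.parent_smiles)
        unmapped = [a.GetIdx() for a in parent.GetAtoms()
                    if a.GetIdx() not in mapping]
        # exactly the two linker carbons are lost
        assert len(mapping) == 12
        assert all(not parent.GetAtomWithIdx(i).GetIsAromatic()
                   for i in unmapped)


def replace_smiles(design, smiles):
    from dataclasses import replace
    return replace(design, product_smiles_flat=smiles)
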