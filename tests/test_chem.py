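"""Scaffold chemistry: linear assembly, module-local tailoring, type II
chains and tailoring."""

import random

import pytest
from rdkit import Chem

from helpers import make_cluster, make_domain

from bgcforge.chem_scaffold import (
    Scaffold,
    apply_reductive_loop,
    apply_type2_tailoring,
    build_linear_scaffold,
    build_type2_chain,
    heterocyclize,
    ScaffoldError,
)
from bgcforge.errors import MonomerLibraryError
from bgcforge.modules_arch import BioModule


def _module(substrate, families=(), mtype="adenylation", subtype=None):
    domains = [
        make_domain("x", "condensation", functional_subtype=subtype)
        if mtype == "adenylation"
        else make_domain("x", "ketosynthase")
    ]
    domains += [make_domain("x", f) for f in families]
    domains += [make_domain("x", "thiolation")]
    return BioModule(type=mtype, domains=domains, orf_ids=["x"],
                     substrate=substrate)


def _starter(substrate):
    return BioModule(
        type="acyl_adenylating_ligase",
        domains=[make_domain("x", "acyl_adenylating")],
        orf_ids=["x"],
        substrate=substrate,
    )


def canon(smiles):
    return Chem.CanonSmiles(smiles)


class TestLinearScaffold:
    def test_two_glycine_modules_give_glycylglycine(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("glycine")], monomers
        )
        assert canon(scaffold.smiles) == canon("NCC(=O)NCC(=O)O")

    def test_acetate_starter_plus_malonyl_gives_acetoacetic_acid(self, monomers):
        scaffold = build_linear_scaffold(
            [_starter("acetate"),
             _module("malonate", mtype="acyltransferase")],
            monomers,
        )
        assert canon(scaffold.smiles) == canon("CC(=O)CC(=O)O")

    def test_empty_permutation_is_an_error(self, monomers):
        with pytest.raises(ScaffoldError):
            build_linear_scaffold([], monomers)

    def test_unknown_substrate_errors_naming_the_substrate(self, monomers):
        with pytest.raises(MonomerLibraryError, match="unobtainium"):
            build_linear_scaffold([_module("unobtainium")], monomers)

    def test_hydroxy_acid_module_forms_an_ester_bond(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("lactate")], monomers
        )
        assert canon(scaffold.smiles) == canon("NCC(=O)OC(C)C(=O)O")

    def test_residue_map_covers_all_backbone_atoms(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("alanine"), _module("serine")],
            monomers,
        )
        rmap = scaffold.residue_map
        assert set(rmap) == {0, 1, 2}
        assert sum(len(v) for v in rmap.values()) == scaffold.mol.GetNumAtoms()

    def test_heavy_atoms_balance_for_random_amino_acid_sequences(self, monomers):
        rng = random.Random(11)
        names = ["glycine", "alanine", "serine", "valine", "leucine",
                 "threonine", "phenylalanine"]
        for _ in range(10):
            seq = [rng.choice(names) for _ in range(rng.randrange(2, 6))]
            scaffold = build_linear_scaffold(
                [_module(n) for n in seq], monomers
            )
            monomer_atoms = sum(
                Chem.MolFromSmiles(
                    monomers.get(n).smiles
                ).GetNumHeavyAtoms()
                for n in seq
            )
            # one water-equivalent oxygen lost per amide condensation
            assert scaffold.mol.GetNumHeavyAtoms() == monomer_atoms - (
                len(seq) - 1
            )

    def test_n_methyltransferase_methylates_the_amide_nitrogen(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"),
             _module("glycine", families=("methyltransferase_N",))],
            monomers,
        )
        assert canon(scaffold.smiles) == canon("NCC(=O)N(C)CC(=O)O")


class TestReductiveLoop:
    @pytest.mark.parametrize(
        "families,expected",
        [
            ((), "CC(=O)CC(=O)O"),
            (("ketoreductase",), "CC(O)CC(=O)O"),
            (("ketoreductase", "dehydratase"), "CC=CC(=O)O"),
            (
                ("ketoreductase", "dehydratase", "enoylreductase"),
                "CCCC(=O)O",
            ),
        ],
    )
    def test_loop_states(self, monomers, families, expected):
        scaffold = build_linear_scaffold(
            [_starter("acetate"),
             _module("malonate", families=families, mtype="acyltransferase")],
            monomers,
        )
        assert canon(scaffold.smiles) == canon(expected)

    def test_dh_without_kr_left_beta_keto_with_warning(self, monomers, caplog):
        scaffold = build_linear_scaffold(
            [_starter("acetate"),
             _module("malonate", families=("dehydratase",),
                     mtype="acyltransferase")],
            monomers,
        )
        assert canon(scaffold.smiles) == canon("CC(=O)CC(=O)O")

    def test_loop_states_mutually_exclusive_per_module(self, monomers):
        # applying the loop twice must not double-edit
        module = _module("malonate", families=("ketoreductase",),
                         mtype="acyltransferase")
        scaffold = build_linear_scaffold(
            [_starter("acetate"), module], monomers
        )
        once = canon(scaffold.smiles)
        apply_reductive_loop(module, scaffold)
        assert canon(scaffold.smiles) == once


class TestHeterocyclization:
    def test_cysteine_gives_thiazoline(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"),
             _module("cysteine", subtype="heterocyclization")],
            monomers,
        )
        assert canon(scaffold.smiles) == canon("NCC1=NC(C(=O)O)CS1")

    def test_nitroreductase_oxidizes_to_thiazole(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"),
             _module("cysteine", subtype="heterocyclization")],
            monomers,
            cluster_families=frozenset({"nitroreductase"}),
        )
        assert canon(scaffold.smiles) == canon("NCc1nc(C(=O)O)cs1")

    def test_serine_gives_oxazoline(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"),
             _module("serine", subtype="heterocyclization")],
            monomers,
        )
        assert canon(scaffold.smiles) == canon("NCC1=NC(C(=O)O)CO1")

    def test_non_cys_ser_residue_condenses_normally(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"),
             _module("alanine", subtype="heterocyclization")],
            monomers,
        )
        assert canon(scaffold.smiles) == canon("NCC(=O)NC(C)C(=O)O")


class TestType2:
    def _cluster(self, extensions=9, extra=(), starter_annotations=None):
        rows = [[make_domain("x", "KS_alpha")],
                [make_domain(
                    "x", "chain_length_factor",
                    annotations={"extensions": extensions,
                                 "clf_pattern": "anthracycline"},
                )]]
        for fam, ann in extra:
            rows.append([make_domain("x", fam, annotations=dict(ann or {}))])
        return make_cluster(rows)

    def test_nine_extensions_with_acetate_starter_gives_c20_chain(self, monomers):
        chain = build_type2_chain(self._cluster(9), monomers)
        carbons = sum(
            1 for a in chain.scaffold.mol.GetAtoms() if a.GetSymbol() == "C"
        )
        assert carbons == 20
        assert chain.chain_carbons == 20

    @pytest.mark.parametrize("extensions", range(3, 16))
    def test_chain_length_formula_exact(self, monomers, extensions):
        chain = build_type2_chain(self._cluster(extensions), monomers)
        carbons = sum(
            1 for a in chain.scaffold.mol.GetAtoms() if a.GetSymbol() == "C"
        )
        assert carbons == 2 * extensions + 2  # acetate starter contributes C2

    def test_missing_clf_annotation_is_an_error(self, monomers):
        cluster = make_cluster(
            [[make_domain("x", "KS_alpha")],
             [make_domain("x", "chain_length_factor")]]
        )
        with pytest.raises(ScaffoldError):
            build_type2_chain(cluster, monomers)

    def test_benzoate_starter_requires_phenylalanine_ammonia_lyase(self, monomers):
        gated = self._cluster(
            6, extra=[("priming_AT", {"substrate": "benzoate"})]
        )
        chain = build_type2_chain(gated, monomers)
        assert chain.starter.name == "acetate"  # PAL absent: fallback
        allowed = self._cluster(
            6,
            extra=[("priming_AT", {"substrate": "benzoate"}),
                   ("phenylalanine_ammonia_lyase", None)],
        )
        chain = build_type2_chain(allowed, monomers)
        assert chain.starter.name == "benzoate"

    def test_c9_ketoreductase_reduces_only_carbon_nine(self, monomers):
        cluster = self._cluster(9, extra=[("KR_C9", None)])
        chain = build_type2_chain(cluster, monomers)
        scaffolds = apply_type2_tailoring(chain, cluster)
        assert len(scaffolds) == 1
        mol = scaffolds[0].mol
        c9 = scaffolds[0].atom(chain.carbon_numbering[9])
        assert any(
            n.GetSymbol() == "O"
            and mol.GetBondBetweenAtoms(c9.GetIdx(), n.GetIdx()).GetBondType()
            == Chem.BondType.SINGLE
            for n in c9.GetNeighbors()
        )
        # every other odd chain carbon is still a ketone
        ketones = 0
        for num, uid in chain.carbon_numbering.items():
            atom = scaffolds[0].atom(uid)
            if atom is None or num % 2 == 0 or num == 9 or num == 1:
                continue
            if any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(atom).GetSymbol() == "O"
                for b in atom.GetBonds()
            ):
                ketones += 1
        assert ketones == 8

    def test_c2_aminotransferase_then_mt_gives_nn_dimethylation(self, monomers):
        cluster = self._cluster(
            6, extra=[("aminotransferase_C2", None), ("MT_C2", None)]
        )
        chain = build_type2_chain(cluster, monomers)
        scaffold = apply_type2_tailoring(chain, cluster)[0]
        c2 = scaffold.atom(chain.carbon_numbering[2])
        nitrogen = next(
            n for n in c2.GetNeighbors() if n.GetSymbol() == "N"
        )
        methyls = [
            n for n in nitrogen.GetNeighbors()
            if n.GetSymbol() == "C" and n.GetDegree() == 1
        ]
        assert len(methyls) == 2

    def test_cyclase_clade_closes_its_ring_pair(self, monomers):
        cluster = self._cluster(9, extra=[("cyclase_clade_I", None)])
        chain = build_type2_chain(cluster, monomers)
        scaffold = apply_type2_tailoring(chain, cluster)[0]
        c7 = scaffold.atom(chain.carbon_numbering[7])
        c12 = scaffold.atom(chain.carbon_numbering[12])
        assert scaffold.mol.GetBondBetweenAtoms(c7.GetIdx(), c12.GetIdx())

    def test_unknown_cyclase_clade_leaves_chain_uncyclized(self, monomers, caplog):
        cluster = self._cluster(9, extra=[("cyclase_clade_VII", None)])
        # clade VII pattern needs C16; truncate the chain so it is absent
        short = self._cluster(5, extra=[("cyclase_clade_VII", None)])
        chain = build_type2_chain(short, monomers)
        scaffold = apply_type2_tailoring(chain, short)[0]
        assert scaffold.mol.GetRingInfo().NumRings() == 0


class TestSmilesValidity:
    def test_every_emitted_smiles_recanonicalizes_to_itself(self, monomers):
        rng = random.Random(5)
        names = ["glycine", "serine", "cysteine", "threonine", "tyrosine",
                 "valine", "lysine", "aspartate"]
        for _ in range(15):
            seq = [rng.choice(names) for _ in range(rng.randrange(1, 5))]
            scaffold = build_linear_scaffold([_module(n) for n in seq], monomers)
            smi = scaffold.smiles
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None
            assert Chem.MolToSmiles(mol) == canon(smi)
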