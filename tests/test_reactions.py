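"""Tailoring reactions: site detection, graph-edit execution,
macrocyclization enumeration."""

import pytest
from rdkit import Chem

from helpers import make_cluster, make_domain

from bgcforge.chem_scaffold import build_linear_scaffold
from bgcforge.modules_arch import BioModule
from bgcforge.reactions import (
    ReactionPlan,
    enumerate_macrocyclizations,
    execute_cyclization,
    execute_reaction,
    find_substrate_sites,
    free_hydroxyls,
)
from bgcforge.refdata import reaction_registry


def _module(substrate, subtype=None):
    domains = [make_domain("x", "condensation", functional_subtype=subtype),
               make_domain("x", "adenylation"),
               make_domain("x", "thiolation")]
    return BioModule(type="adenylation", domains=domains, orf_ids=["x"],
                     substrate=substrate)


def _starter(substrate):
    return BioModule(
        type="starter_condensation",
        domains=[make_domain("x", "condensation",
                             functional_subtype="starter_condensation")],
        orf_ids=["x"], substrate=substrate,
    )


REACTIONS = {r.name: r for r in reaction_registry()}


@pytest.fixture
def seryl_scaffold(monomers):
    """Ser-Thr-Ser-Ala peptide with an acylated N-terminus: three free
    hydroxyls (all far enough from the carboxyl to cyclize), no free amine."""
    return build_linear_scaffold(
        [_starter("isovalerate"), _module("serine"), _module("threonine"),
         _module("serine"), _module("alanine")],
        monomers,
    )


class TestSiteDetection:
    def test_three_free_hydroxyls_give_three_glycosylation_sites(
        self, seryl_scaffold
    ):
        sites = find_substrate_sites(
            REACTIONS["O-glycosylation"], seryl_scaffold
        )
        assert len(sites) == 3
        assert all(s[0] == "O" for s in sites)

    def test_phenols_and_carboxyls_are_not_free_hydroxyls(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("tyrosine"), _module("aspartate")], monomers
        )
        assert free_hydroxyls(scaffold) == []

    def test_sulfotransferase_on_hydroxyl_free_scaffold_finds_no_sites(
        self, monomers
    ):
        scaffold = build_linear_scaffold([_module("alanine")], monomers)
        assert find_substrate_sites(REACTIONS["sulfation"], scaffold) == []

    def test_site_detection_is_pure(self, seryl_scaffold):
        r = REACTIONS["O-glycosylation"]
        assert find_substrate_sites(r, seryl_scaffold) == find_substrate_sites(
            r, seryl_scaffold
        )

    def test_chlorinase_falls_back_down_ranked_classes_and_halts(
        self, monomers
    ):
        scaffold = build_linear_scaffold(
            [_module("tryptophan"), _module("threonine")], monomers
        )
        dom = make_domain(
            "x", "chlorinase",
            annotations={
                "ranked_refs": [
                    ("r1", 90.0, {"substrate_class": "tyrosine_phenylglycine"}),
                    ("r2", 80.0, {"substrate_class": "tryptophan"}),
                    ("r3", 70.0, {"substrate_class": "threonine"}),
                ]
            },
        )
        sites = find_substrate_sites(
            REACTIONS["chlorination"], scaffold, domain=dom
        )
        # no Tyr: falls to the tryptophan class; never reaches threonine
        assert len(sites) == 1
        assert scaffold.residues[sites[0][1]].name == "tryptophan"

    def test_formyltransferase_targets_n_terminus_and_ornithine_side_chain(
        self, monomers
    ):
        scaffold = build_linear_scaffold(
            [_module("ornithine"), _module("glycine")], monomers
        )
        sites = find_substrate_sites(REACTIONS["N-formylation"], scaffold)
        assert len(sites) == 2


class TestExecution:
    def test_glucosylation_forms_o_glycosidic_bond_and_counts(
        self, seryl_scaffold, monomers
    ):
        site = find_substrate_sites(
            REACTIONS["O-glycosylation"], seryl_scaffold
        )[0]
        plan = ReactionPlan(REACTIONS["O-glycosylation"], site,
                            extras={"sugar": monomers.get("glucose")})
        out = execute_reaction(plan, seryl_scaffold)
        assert out is not None
        assert out.reaction_count == seryl_scaffold.reaction_count + 1
        assert out.mol.GetNumAtoms() > seryl_scaffold.mol.GetNumAtoms()

    def test_reaction_at_consumed_site_fails_without_partial_edit(
        self, seryl_scaffold, monomers
    ):
        site = find_substrate_sites(
            REACTIONS["O-glycosylation"], seryl_scaffold
        )[0]
        cyclized = execute_cyclization(("macrolactone", site[1]), seryl_scaffold)
        assert cyclized is not None
        plan = ReactionPlan(REACTIONS["O-glycosylation"], site,
                            extras={"sugar": monomers.get("glucose")})
        assert execute_reaction(plan, cyclized) is None

    def test_chlorination_adds_chlorine_to_the_residue(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("tyrosine")], monomers
        )
        dom = make_domain(
            "x", "chlorinase",
            annotations={"substrate_class": "tyrosine_phenylglycine"},
        )
        sites = find_substrate_sites(
            REACTIONS["chlorination"], scaffold, domain=dom
        )
        out = execute_reaction(
            ReactionPlan(REACTIONS["chlorination"], sites[0], dom), scaffold
        )
        assert out is not None
        assert any(a.GetSymbol() == "Cl" for a in out.mol.GetAtoms())

    def test_oxidative_p450_crosslink_forms_biaryl_ether(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("tyrosine"), _module("alanine"),
             _module("4-hydroxyphenylglycine")],
            monomers,
        )
        dom = make_domain("x", "glycopeptide_P450", functional_subtype="OxyA")
        sites = find_substrate_sites(
            REACTIONS["glycopeptide_crosslink"], scaffold, domain=dom
        )
        assert sites == [("pair", 1, 3, "ether")]
        out = execute_reaction(
            ReactionPlan(REACTIONS["glycopeptide_crosslink"], sites[0], dom),
            scaffold,
        )
        assert out is not None
        assert (
            out.mol.GetRingInfo().NumRings()
            > scaffold.mol.GetRingInfo().NumRings()
        )

    def test_isopenicillin_n_synthase_bicyclizes_cys_val(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("2-aminoadipate"), _module("cysteine"), _module("valine")],
            monomers,
        )
        sites = find_substrate_sites(
            REACTIONS["beta_lactam_formation"], scaffold
        )
        assert sites == [("res2", 1, 2)]
        out = execute_reaction(
            ReactionPlan(REACTIONS["beta_lactam_formation"], sites[0]), scaffold
        )
        assert out is not None
        rings = [len(r) for r in out.mol.GetRingInfo().AtomRings()]
        assert sorted(rings) == [4, 5]  # beta-lactam + thiazolidine
        # ring expansion applies only after the synthase has fired
        exp_sites = find_substrate_sites(REACTIONS["ring_expansion"], out)
        assert exp_sites == [("penam",)]
        cephem = execute_reaction(
            ReactionPlan(REACTIONS["ring_expansion"], exp_sites[0]), out
        )
        assert cephem is not None
        assert sorted(
            len(r) for r in cephem.mol.GetRingInfo().AtomRings()
        ) == [4, 6]

    def test_ring_expansion_without_penam_finds_no_site(self, seryl_scaffold):
        assert find_substrate_sites(
            REACTIONS["ring_expansion"], seryl_scaffold
        ) == []

    def test_valence_validity_over_random_plans(self, seryl_scaffold, monomers):
        import random

        rng = random.Random(2)
        hydroxyl_reactions = [
            REACTIONS[n]
            for n in ("sulfation", "carbamoylation", "phosphorylation")
        ]
        for _ in range(10):
            scaffold = seryl_scaffold
            for _ in range(rng.randrange(1, 4)):
                r = rng.choice(hydroxyl_reactions)
                sites = find_substrate_sites(r, scaffold)
                if not sites:
                    break
                out = execute_reaction(
                    ReactionPlan(r, rng.choice(sites)), scaffold
                )
                if out is None:
                    continue
                scaffold = out
                assert Chem.MolFromSmiles(scaffold.smiles) is not None


class TestMacrocyclization:
    def test_three_hydroxyls_give_three_lactones_plus_linear(
        self, seryl_scaffold
    ):
        patterns = enumerate_macrocyclizations(seryl_scaffold)
        kinds = [p[0] for p in patterns]
        assert kinds.count("macrolactone") == 3
        assert kinds.count("linear") == 1
        assert len(patterns) == 4

    def test_terminal_reductase_gives_exactly_aldehyde_and_imine(
        self, monomers
    ):
        cluster = make_cluster(
            [["condensation", "adenylation", "thiolation",
              "reductase_terminal"]],
            classify=False,
        )
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("serine")], monomers
        )
        patterns = enumerate_macrocyclizations(scaffold, cluster)
        assert patterns == [("linear_aldehyde",), ("cyclic_imine",)]
        for p in patterns:
            assert execute_cyclization(p, scaffold) is not None

    def test_nucleophile_free_scaffold_gives_linear_only(self, monomers):
        scaffold = build_linear_scaffold(
            [_starter("acetate"), _module("alanine")], monomers
        )
        assert enumerate_macrocyclizations(scaffold) == [("linear",)]

    def test_free_n_terminus_offers_a_macrolactam(self, monomers):
        scaffold = build_linear_scaffold(
            [_module("glycine"), _module("alanine"), _module("valine")],
            monomers,
        )
        kinds = [p[0] for p in enumerate_macrocyclizations(scaffold)]
        assert "macrolactam" in kinds

    def test_macrolactonization_consumes_the_terminal_carboxyl(
        self, seryl_scaffold
    ):
        pattern = enumerate_macrocyclizations(seryl_scaffold)[0]
        out = execute_cyclization(pattern, seryl_scaffold)
        assert out is not None
        assert (
            out.mol.GetRingInfo().NumRings()
            == seryl_scaffold.mol.GetRingInfo().NumRings() + 1
        )
        # cyclizing again at the same carboxyl must fail
        again = enumerate_macrocyclizations(seryl_scaffold)[1]
        assert execute_cyclization(again, out) is None
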