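"""Module identification, adenylation activity rules, artificial ORFs,
and ORF permutation generation."""

import itertools
import math

import pytest

from helpers import make_cluster, make_domain

from bgcforge.annotate import Domain
from bgcforge.modules_arch import (
    BioModule,
    ModularOrf,
    active_module_sequence,
    assign_adenylation_activity,
    build_modular_orfs,
    build_trans_at_orfs,
    generate_orf_permutations,
    identify_modules,
    insert_trans_a_modules,
    permutation_is_plausible,
)


def _adomain(substrate):
    return make_domain("x", "adenylation", substrates=[(substrate, 40.0)])


class TestIdentifyModules:
    def test_c_a_t_is_one_adenylation_module(self):
        cluster = make_cluster(
            [["condensation", _adomain("serine"), "thiolation"]]
        )
        modules = identify_modules(cluster)
        assert [m.type for m in modules] == ["adenylation"]
        assert modules[0].substrate == "serine"

    def test_c_t_didomain_is_a_trans_a_insertion_module(self):
        cluster = make_cluster(
            [["condensation", _adomain("serine"), "thiolation",
              "condensation", "thiolation"]]
        )
        modules = identify_modules(cluster)
        assert [m.type for m in modules] == ["adenylation", "trans_a_insertion"]

    def test_all_at_orf_flags_candidate_trans_acting_ats(self):
        cluster = make_cluster(
            [["ketosynthase", "thiolation"], ["acyltransferase"]],
            classify=False,
        )
        identify_modules(cluster)
        at = next(d for d in cluster.domains if d.family == "acyltransferase")
        assert at.annotations.get("trans_at_candidate")

    def test_ks_at_t_is_an_acyltransferase_module(self):
        cluster = make_cluster(
            [["ketosynthase", "acyltransferase", "ketoreductase", "thiolation"]],
            classify=False,
        )
        modules = identify_modules(cluster)
        assert [m.type for m in modules] == ["acyltransferase"]
        assert modules[0].substrate == "malonate"
        assert modules[0].reductive_loop == {"ketoreductase"}

    def test_ks_span_without_at_is_a_trans_at_insertion(self):
        cluster = make_cluster(
            [["ketosynthase", "ketoreductase", "thiolation"]], classify=False
        )
        modules = identify_modules(cluster)
        assert [m.type for m in modules] == ["trans_at_insertion"]
        assert modules[0].substrate == "malonate"

    def test_starter_condensation_emits_its_own_module(self):
        starter = make_domain(
            "x", "condensation",
            functional_subtype="starter_condensation",
            annotations={"substrate": "isovalerate"},
        )
        cluster = make_cluster(
            [[starter, _adomain("serine"), "thiolation"]]
        )
        modules = identify_modules(cluster)
        assert [m.type for m in modules] == [
            "starter_condensation", "adenylation"
        ]
        assert modules[0].substrate == "isovalerate"
        assert modules[0].initiates

    def test_type2_cluster_emits_a_type2_unit(self):
        cluster = make_cluster([["KS_alpha"], ["chain_length_factor"]])
        modules = identify_modules(cluster)
        assert [m.type for m in modules] == ["type2_unit"]


class TestAdenylationActivity:
    def test_lone_adenylation_domain_on_own_orf_inactive(self):
        cluster = make_cluster([[_adomain("alanine")]], classify=False)
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        assert len(modules) == 1 and not modules[0].active

    def test_a_t_didomain_acts_in_trans_when_cluster_has_c_t_didomain(self):
        cluster = make_cluster(
            [
                ["condensation", _adomain("glycine"), "thiolation",
                 "condensation", "thiolation"],
                [_adomain("alanine"), "thiolation"],
            ],
            classify=False,
        )
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        didomain = next(m for m in modules if "alanine" == m.substrate)
        assert didomain.type == "trans_a" and didomain.active

    def test_a_t_didomain_initiates_without_a_c_t_didomain(self):
        cluster = make_cluster(
            [
                ["condensation", _adomain("glycine"), "thiolation"],
                [_adomain("alanine"), "thiolation"],
            ],
            classify=False,
        )
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        didomain = next(m for m in modules if m.substrate == "alanine")
        assert didomain.type == "initiating_adenylation" and didomain.active

    def test_orf_terminal_c_a_didomain_active(self):
        cluster = make_cluster(
            [["condensation", _adomain("valine")]], classify=False
        )
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        assert modules and modules[0].active
        assert modules[0].extras.get("orf_terminal_ca")

    def test_multiple_acyl_adenylating_modules_share_one_initiator_slot(self):
        cluster = make_cluster(
            [
                [make_domain("x", "acyl_adenylating",
                             substrates=[("acetate", 30.0)])],
                [make_domain("x", "acyl_adenylating",
                             substrates=[("benzoate", 30.0)])],
                ["condensation", _adomain("glycine"), "thiolation"],
            ],
            classify=False,
        )
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        als = [m for m in modules if m.type == "acyl_adenylating_ligase"]
        assert len(als) == 2
        assert all(m.extras.get("initiator_pool") for m in als)
        orfs = build_modular_orfs(cluster, modules)
        seq = active_module_sequence(orfs)
        assert sum(1 for m in seq if m.type == "acyl_adenylating_ligase") == 1


class TestTransAT:
    def test_split_module_joined_into_artificial_orf(self, bundle):
        cluster = bundle.cluster_for("transat")
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        orfs = build_modular_orfs(cluster, modules)
        joined = build_trans_at_orfs(orfs)
        artificial = [o for o in joined if len(o.source_orf_ids) > 1]
        assert len(artificial) == 1
        first = artificial[0].modules[0]
        assert first.type == "trans_at_insertion"
        assert [d.family for d in first.domains] == [
            "ketosynthase", "ketoreductase", "thiolation"
        ]

    def test_monomer_capacity_conserved_by_joining(self, bundle):
        cluster = bundle.cluster_for("transat")
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        orfs = build_modular_orfs(cluster, modules)

        def capacity(orf_list):
            return sum(
                1
                for o in orf_list
                for m in o.modules
                if not m.extras.get("carrier_fragment")
            )

        before = capacity(orfs)
        joined = build_trans_at_orfs(orfs)
        assert capacity(joined) == before

    def test_no_split_modules_returns_input_unchanged(self):
        cluster = make_cluster(
            [["ketosynthase", "acyltransferase", "thiolation"]],
            classify=False,
        )
        orfs = build_modular_orfs(cluster, identify_modules(cluster))
        assert build_trans_at_orfs(list(orfs)) == orfs

    def test_all_trans_acting_ats_assigned_malonate(self, bundle):
        cluster = bundle.cluster_for("transat")
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        insertions = [m for m in modules if m.type == "trans_at_insertion"
                      and not m.extras.get("carrier_fragment")]
        assert insertions
        assert all(m.substrate == "malonate" for m in insertions)


class TestTransA:
    def _orfs(self, n_trans_a, n_sites):
        cluster_rows = []
        row = []
        for _ in range(n_sites):
            row += ["condensation", "thiolation"]
        cluster_rows.append(["condensation", _adomain("glycine"), "thiolation"]
                            + row)
        for i in range(n_trans_a):
            cluster_rows.append(
                [_adomain(["alanine", "serine"][i % 2]), "thiolation"]
            )
        cluster = make_cluster(cluster_rows, classify=False)
        modules = assign_adenylation_activity(cluster, identify_modules(cluster))
        return build_modular_orfs(cluster, modules)

    def test_one_module_two_sites_gives_two_variants(self):
        variants = insert_trans_a_modules(self._orfs(1, 2))
        assert len(variants) == 2

    def test_two_modules_two_sites_enumerates_injective_assignments(self):
        variants = insert_trans_a_modules(self._orfs(2, 2))
        # oracle: injective assignments of 2 distinguishable modules to 2 sites
        assert len(variants) == math.perm(2, 2)

    def test_no_insertion_modules_is_a_no_op(self):
        cluster = make_cluster(
            [["condensation", _adomain("glycine"), "thiolation"]],
            classify=False,
        )
        orfs = build_modular_orfs(cluster, identify_modules(cluster))
        assert insert_trans_a_modules(orfs) == [orfs]

    def test_spliced_module_carries_donor_substrate(self):
        variants = insert_trans_a_modules(self._orfs(1, 1))
        assert len(variants) == 1
        filled = [
            m
            for o in variants[0]
            for m in o.modules
            if m.extras.get("trans_filled")
        ]
        assert len(filled) == 1 and filled[0].substrate == "alanine"
        donors = [
            m
            for o in variants[0]
            for m in o.modules
            if m.extras.get("spliced_away")
        ]
        assert len(donors) == 1 and not donors[0].active


def _mod_orf(orf_id, initiates=False, terminates=False, frame=("+", 0),
             start=0):
    domains = [make_domain(orf_id, "condensation")]
    mtype = "starter_condensation" if initiates else "adenylation"
    if terminates:
        domains = domains + [make_domain(orf_id, "thioesterase")]
    module = BioModule(type=mtype, domains=domains, orf_ids=[orf_id],
                       substrate="glycine")
    return ModularOrf(id=orf_id, source_orf_ids=[orf_id], modules=[module],
                      frame_key=frame, genomic_start=start)


def _oracle_count(orfs):
    return sum(
        1
        for p in itertools.permutations(orfs)
        if (not any(o.initiates for o in orfs) or p[0].initiates)
        and (not any(o.terminates for o in orfs) or p[-1].terminates)
    )


class TestOrfPermutations:
    def test_same_frame_constrained_order_gives_single_permutation(self):
        orfs = [
            _mod_orf("a", initiates=True, start=1),
            _mod_orf("b", start=1000),
            _mod_orf("c", terminates=True, start=2000),
        ]
        perms = generate_orf_permutations(orfs)
        assert len(perms) == 1
        assert [o.id for o in perms[0]] == ["a", "b", "c"]

    def test_mixed_frames_enumerate_constrained_orderings(self):
        orfs = [
            _mod_orf("a", initiates=True, frame=("+", 0), start=1),
            _mod_orf("b", frame=("-", 1), start=1000),
            _mod_orf("c", frame=("+", 2), start=2000),
            _mod_orf("d", terminates=True, frame=("+", 0), start=3000),
        ]
        perms = generate_orf_permutations(orfs)
        assert len(perms) == 2  # 2! orderings of the free middle pair
        for p in perms:
            assert p[0].id == "a" and p[-1].id == "d"

    def test_eight_unconstrained_orfs_sample_500_permutations(self):
        orfs = [
            _mod_orf(f"o{i}", frame=("+", i % 3), start=i * 1000)
            for i in range(8)
        ]
        perms = generate_orf_permutations(orfs)
        assert len(perms) == 500
        keys = {tuple(o.id for o in p) for p in perms}
        assert len(keys) == 500  # all distinct

    def test_sampling_reproducible_under_fixed_seed(self):
        orfs = [
            _mod_orf(f"o{i}", frame=("+", i % 3), start=i * 1000)
            for i in range(8)
        ]
        a = [[o.id for o in p] for p in generate_orf_permutations(orfs, seed=0)]
        b = [[o.id for o in p] for p in generate_orf_permutations(orfs, seed=0)]
        c = [[o.id for o in p] for p in generate_orf_permutations(orfs, seed=1)]
        assert a == b
        assert a != c

    def test_every_returned_permutation_satisfies_constraints(self):
        orfs = [
            _mod_orf("a", initiates=True, frame=("+", 0)),
            _mod_orf("b", frame=("-", 1), start=500),
            _mod_orf("c", terminates=True, frame=("+", 1), start=900),
            _mod_orf("d", frame=("+", 2), start=1200),
        ]
        for p in generate_orf_permutations(orfs):
            assert permutation_is_plausible(p)
            assert p[0].initiates and p[-1].terminates

    @pytest.mark.parametrize("n,n_init,n_term", [
        (3, 1, 1), (4, 0, 1), (5, 2, 0), (6, 1, 2), (6, 0, 0),
    ])
    def test_enumeration_matches_bruteforce_oracle_up_to_six_orfs(
        self, n, n_init, n_term
    ):
        orfs = []
        for i in range(n):
            orfs.append(
                _mod_orf(
                    f"o{i}",
                    initiates=i < n_init,
                    terminates=n_init <= i < n_init + n_term,
                    frame=("+", i % 3),
                    start=i * 1000,
                )
            )
        perms = generate_orf_permutations(orfs, cap_threshold=10**9)
        assert len(perms) == _oracle_count(orfs)
        assert len({tuple(o.id for o in p) for p in perms}) == len(perms)

    def test_contradictory_constraints_fall_back_to_genomic_order(self):
        both = _mod_orf("a", initiates=True, terminates=True, frame=("+", 0))
        other = _mod_orf("b", frame=("-", 1), start=1000)
        # the only initiator is also the only terminator: with two ORFs no
        # ordering can satisfy both constraints
        perms = generate_orf_permutations([both, other])
        assert len(perms) == 1
        assert [o.id for o in perms[0]] == ["a", "b"]
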