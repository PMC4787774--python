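"""Domain annotation: search backend, table backend, refinement, substrates."""

import pytest

from helpers import make_domain, make_orf

from bgcforge.annotate import (
    Domain,
    ReferenceRecord,
    annotate_domains,
    apply_prerequisite_rules,
    predict_substrates,
    read_annotation_table,
    refine_by_alignment,
    resolve_overlaps,
    write_annotation_table,
)
from bgcforge.errors import ConfigurationError


class TestSearchBackend:
    def test_fixture_consensus_recovers_its_domain_above_cutoff(self, bundle):
        key = "adenylation:serine"
        protein = "M" + "GSTA" + bundle.consensus[key] + "PLK"
        orf = make_orf("o1", protein=protein)
        hits = annotate_domains([orf], bundle.models)
        families = {d.family for d in hits}
        assert "adenylation" in families
        hit = next(d for d in hits if d.family == "adenylation")
        model = next(m for m in bundle.models if m.name == key)
        assert hit.score >= model.bitscore_cutoff
        assert hit.top_substrate == "serine"

    def test_unrelated_sequence_yields_no_hits(self, bundle):
        orf = make_orf("o1", protein="M" + "PG" * 150)
        assert annotate_domains([orf], bundle.models) == []

    def test_empty_model_library_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            annotate_domains([make_orf("o1")], [])

    def test_overlapping_same_family_hits_resolve_to_best_score(self):
        a = make_domain("o1", "condensation", 10, 70, score=80.0)
        b = make_domain("o1", "condensation", 40, 100, score=60.0)
        c = make_domain("o1", "thiolation", 40, 100, score=30.0)
        kept = resolve_overlaps([a, b, c])
        assert a in kept and c in kept and b not in kept


class TestAnnotationTable:
    def test_round_trip_preserves_every_field(self, tmp_path):
        domains = [
            make_domain(
                "o1",
                "chlorinase",
                5,
                64,
                score=42.5,
                functional_subtype=None,
                substrates=[("tyrosine", 30.0), ("tryptophan", 20.0)],
                annotations={"substrate_class": "tyrosine_phenylglycine"},
            ),
            make_domain("o2", "thiolation", 1, 60),
        ]
        path = tmp_path / "ann.tsv"
        write_annotation_table(domains, str(path))
        back = read_annotation_table(str(path))
        assert len(back) == 2
        assert back[0].family == "chlorinase"
        assert back[0].substrates == [("tyrosine", 30.0), ("tryptophan", 20.0)]
        assert back[0].annotations["substrate_class"] == "tyrosine_phenylglycine"
        assert back[1].functional_subtype is None

    def test_table_matches_embedded_fixture_layout(self, bundle, tmp_path):
        from bgcforge.fixtures import generate_annotation_table

        genome = bundle.genomes["flagship"]
        path = tmp_path / "t.tsv"
        truth = generate_annotation_table(genome, str(path))
        back = read_annotation_table(str(path))
        assert [(d.orf_id, d.family, d.start_aa, d.end_aa) for d in back] == [
            (d.orf_id, d.family, d.start_aa, d.end_aa) for d in truth
        ]


class TestRefinement:
    def _domain(self, seq):
        return make_domain("o1", "condensation", sequence=seq)

    def test_best_reference_annotation_copied(self, bundle):
        seq = bundle.consensus["condensation:starter"]
        db = [
            ReferenceRecord(
                "ref_starter", seq,
                {"functional_subtype": "starter_condensation"},
            ),
            ReferenceRecord(
                "ref_lcl", bundle.consensus["condensation:lcl"],
                {"functional_subtype": None},
            ),
        ]
        refined = refine_by_alignment(self._domain(seq), db)
        assert refined.functional_subtype == "starter_condensation"
        assert [r[0] for r in refined.annotations["ranked_refs"]][0] == (
            "ref_starter"
        )

    def test_clf_extension_annotation_copied(self):
        dom = make_domain(
            "o1", "chain_length_factor", sequence="MKLVNNNQRSTW" * 5
        )
        db = [ReferenceRecord("clf9", dom.sequence, {"extensions": 9})]
        refined = refine_by_alignment(dom, db)
        assert refined.annotations["extensions"] == 9

    def test_equal_scores_break_to_lexicographically_first_id(self):
        seq = "MKLVNNNQRSTW" * 5
        dom = make_domain("o1", "ketosynthase", sequence=seq)
        db = [
            ReferenceRecord("zzz", seq, {"functional_subtype": "late"}),
            ReferenceRecord("aaa", seq, {"functional_subtype": "early"}),
        ]
        refined = refine_by_alignment(dom, db)
        assert refined.functional_subtype == "early"

    def test_empty_reference_db_returns_domain_unchanged(self, caplog):
        dom = self._domain("MKLV" * 20)
        refined = refine_by_alignment(dom, [])
        assert refined is dom

    def test_unrefined_family_rejected(self):
        with pytest.raises(ConfigurationError):
            refine_by_alignment(make_domain("o1", "thiolation"), [])


class TestSubstratePrediction:
    def test_proline_fixture_profile_ranks_proline_first(self, bundle):
        seq = bundle.consensus["adenylation:proline"]
        dom = make_domain("o1", "adenylation", sequence=seq)
        ranked = predict_substrates(dom, bundle.substrate_profiles)
        assert ranked[0][0] == "proline"
        assert all(
            ranked[i][1] >= ranked[i + 1][1] for i in range(len(ranked) - 1)
        )

    def test_acyl_adenylating_scored_only_against_acyl_profiles(self, bundle):
        # the fixture library has no acyl_adenylating profiles registered,
        # so scoring one must not silently fall back to amino-acid profiles
        dom = make_domain(
            "o1", "acyl_adenylating",
            sequence=bundle.consensus["adenylation:proline"],
        )
        with pytest.raises(ConfigurationError):
            predict_substrates(dom, bundle.substrate_profiles)

    def test_non_substrate_family_rejected(self, bundle):
        with pytest.raises(ConfigurationError):
            predict_substrates(
                make_domain("o1", "thiolation"), bundle.substrate_profiles
            )


class TestPrerequisiteRules:
    def _adomain(self, subs):
        return make_domain("o1", "adenylation", substrates=list(subs))

    def test_methoxymalonate_demoted_without_both_prerequisites(self):
        dom = self._adomain(
            [("methoxymalonate", 50.0), ("malonate", 40.0), ("alanine", 30.0)]
        )
        out = apply_prerequisite_rules([dom], {"acyl_CoA_dehydrogenase"})
        assert [s[0] for s in out[0].substrates] == [
            "malonate", "methoxymalonate", "alanine"
        ]

    def test_methoxymalonate_retained_with_both_prerequisites(self):
        dom = self._adomain([("methoxymalonate", 50.0), ("malonate", 40.0)])
        out = apply_prerequisite_rules(
            [dom], {"acyl_CoA_dehydrogenase", "hydroxyacyl_CoA_dehydrogenase"}
        )
        assert out[0].substrates[0][0] == "methoxymalonate"

    def test_ungated_top_substrate_unchanged(self):
        dom = self._adomain([("alanine", 50.0), ("glycine", 40.0)])
        out = apply_prerequisite_rules([dom], set())
        assert out[0].substrates == dom.substrates

    def test_demotion_reorders_but_never_removes(self):
        subs = [
            ("capreomycidine", 50.0),
            ("3-hydroxypipecolate", 45.0),
            ("serine", 40.0),
        ]
        dom = self._adomain(subs)
        out = apply_prerequisite_rules([dom], set())
        assert sorted(out[0].substrates) == sorted(subs)
        assert out[0].substrates[0][0] == "serine"
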