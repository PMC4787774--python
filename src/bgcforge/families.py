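"""Registry of biosynthetic, tailoring, sugar, and resistance domain families.

Family names are the vocabulary shared by the annotation backend, the
cluster-calling rules, module architecture inference, and the tailoring
reaction registry. Resistance families are recognized by the
``resistance_`` prefix and are flagged only (never interpreted).
"""

from __future__ import annotations

# --- thiotemplated (NRPS / type I PKS) core domains ---
THIOTEMPLATED_FAMILIES = frozenset(
    {
        "condensation",
        "ketosynthase",
        "adenylation",
        "acyl_adenylating",
        "prolyl_AMP_ligase",
        "acyltransferase",
        "thiolation",
        "thioesterase",
        "ketoreductase",
        "dehydratase",
        "enoylreductase",
        "methyltransferase_N",
        "methyltransferase_O",
        "methyltransferase_C",
        "nitroreductase",
        "reductase_terminal",
        "PPTase",
    }
)

#: Domains that form scaffold bonds; these seed the greedy cluster algorithm.
BOND_FORMING_FAMILIES = frozenset(
    {"condensation", "ketosynthase", "KS_alpha", "enediyne_KS"}
)

#: Domains that select and activate a monomer.
SUBSTRATE_ACTIVATING_FAMILIES = frozenset(
    {"adenylation", "acyl_adenylating", "acyltransferase", "prolyl_AMP_ligase"}
)

# --- type II PKS domains ---
CYCLASE_CLADES = (
    "cyclase_clade_I",
    "cyclase_clade_II",
    "cyclase_clade_III",
    "cyclase_clade_IV",
    "cyclase_clade_Va",
    "cyclase_clade_Vb",
    "cyclase_clade_VIa",
    "cyclase_clade_VIb",
    "cyclase_clade_VII",
    "cyclase_clade_VIIIa",
    "cyclase_clade_VIIIb",
    "cyclase_clade_IX",
)

TYPE2_KR_FAMILIES = ("KR_C9", "KR_C11", "KR_C15", "KR_C17", "KR_C19")

TYPE2_MT_FAMILIES = (
    "MT_C6",
    "MT_C8",
    "MT_C10",
    "MT_C2",
    "MT_O_carboxy",
    "MT_O_C11_cladeA",
    "MT_O_C11_cladeB",
)

TYPE2_OXYGENASE_FAMILIES = (
    "anthrone_oxygenase",
    "quinone_forming_oxygenase",
    "baeyer_villiger_monooxygenase",
    "favorskiiase",
)

TYPE2_FAMILIES = frozenset(
    {
        "KS_alpha",
        "chain_length_factor",
        "priming_AT",
        "KSIII",
        "ACP",
        "aminotransferase_C2",
        "c_glycosyltransferase",
        "phenylalanine_ammonia_lyase",
        "amidotransferase",
    }
    | set(CYCLASE_CLADES)
    | set(TYPE2_KR_FAMILIES)
    | set(TYPE2_MT_FAMILIES)
    | set(TYPE2_OXYGENASE_FAMILIES)
)

# --- tailoring domains ---
TAILORING_FAMILIES = frozenset(
    {
        "glycosyltransferase",
        "chlorinase",
        "sulfotransferase",
        "carbamoyltransferase",
        "phosphotransferase",
        "formyltransferase",
        "glycopeptide_P450",
        "tryptophan_dioxygenase",
        "proline_dehydrogenase",
        "isopenicillin_N_synthase",
        "isopenicillin_N_acyltransferase",
        "deacetoxycephalosporin_C_synthase",
    }
)

# --- prerequisite domains gating rare-substrate predictions ---
PREREQUISITE_FAMILIES = frozenset(
    {
        "acyl_CoA_dehydrogenase",
        "hydroxyacyl_CoA_dehydrogenase",
        "arginine_hydroxylase",
        "capreomycidine_synthase",
        "diaminopropionate_synthase",
        "cyclodeaminase",
        "pipecolate_hydroxylase",
        "aryl_formamidase",
    }
)

#: Rare substrates demoted unless every listed family is present in the cluster.
SUBSTRATE_PREREQUISITES: dict[str, frozenset[str]] = {
    "methoxymalonate": frozenset(
        {"acyl_CoA_dehydrogenase", "hydroxyacyl_CoA_dehydrogenase"}
    ),
    "capreomycidine": frozenset({"arginine_hydroxylase", "capreomycidine_synthase"}),
    "diaminopropionate": frozenset({"diaminopropionate_synthase"}),
    "3-hydroxypipecolate": frozenset({"cyclodeaminase", "pipecolate_hydroxylase"}),
    "3-hydroxyanthranilate": frozenset(
        {"tryptophan_dioxygenase", "aryl_formamidase"}
    ),
}

# --- deoxysugar biosynthesis gene families (glycogenetic code vocabulary) ---
DEOXYSUGAR_GENE_FAMILIES = frozenset(
    {
        "sugar_46_dehydratase",
        "sugar_23_dehydratase",
        "sugar_34_isomerase",
        "sugar_3_ketoreductase",
        "sugar_4_ketoreductase",
        "sugar_35_epimerase",
        "sugar_5_epimerase",
        "sugar_3_aminotransferase",
        "sugar_4_aminotransferase",
        "sugar_3_C_methyltransferase",
        "sugar_5_C_methyltransferase",
        "sugar_N_methyltransferase",
        "sugar_NN_dimethyltransferase",
        "sugar_4_O_methyltransferase",
        "sugar_3_O_carbamoyltransferase",
        "sugar_4_oxidase",
        "sugar_26_dideoxygenase",
        "sugar_UDP_dehydrogenase",
        "sugar_UDP_decarboxylase",
        "sugar_4_acetyltransferase",
        "sugar_tautomerase",
    }
)

# --- fungal iterative type I / enediyne markers ---
OTHER_FAMILIES = frozenset({"product_template", "enediyne_KS"})

ALL_FAMILIES = (
    THIOTEMPLATED_FAMILIES
    | TYPE2_FAMILIES
    | TAILORING_FAMILIES
    | PREREQUISITE_FAMILIES
    | DEOXYSUGAR_GENE_FAMILIES
    | OTHER_FAMILIES
)


def is_resistance_family(family: str) -> bool:
    return family.startswith("resistance_")


def is_registered_family(family: str) -> bool:
    return family in ALL_FAMILIES or is_resistance_family(family)


def is_bond_forming(family: str) -> bool:
    return family in BOND_FORMING_FAMILIES


def is_substrate_activating(family: str) -> bool:
    return family in SUBSTRATE_ACTIVATING_FAMILIES
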