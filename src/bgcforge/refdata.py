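"""Reference data: monomer structures, glycogenetic code, tailoring-reaction
registry, and type II cyclase ring-pattern table.

Monomer SMILES carry two labelled attachment points as atom maps: map 1 is
the head (the amine nitrogen of an amino acid, the ester oxygen of a hydroxy
acid, the alpha carbon of a ketide extender, the anomeric carbon of a
sugar); map 2 is the tail carboxyl/acyl carbon. Starters have no head.
Stereochemistry is not modelled anywhere: all structures are achiral.

The cyclase clade -> ring-pattern table encodes ring-closure bond lists as
carbon-number pairs on the linear poly-beta-ketothioester (C1 = thioester
carbonyl); the pairs shipped here are provisional (the authoritative
topologies live in the cyclase phylogeny literature, not in this package).
"""

from __future__ import annotations

from dataclasses import dataclass

from bgcforge.errors import MonomerLibraryError

# ---------------------------------------------------------------------------
# Monomer library
# ---------------------------------------------------------------------------

MONOMER_CLASSES = (
    "alpha_amino_acid",
    "ketide",
    "acyl_starter",
    "aryl_starter",
    "alpha_keto_acid",
    "alpha_hydroxy_acid",
    "sugar",
)


@dataclass(frozen=True)
class MonomerRecord:
    name: str
    smiles: str
    monomer_class: str


_AA = "alpha_amino_acid"

_MONOMERS = [
    # proteinogenic amino acids
    ("alanine", "[NH2:1]C(C)[C:2](=O)O", _AA),
    ("arginine", "[NH2:1]C(CCCNC(=N)N)[C:2](=O)O", _AA),
    ("asparagine", "[NH2:1]C(CC(N)=O)[C:2](=O)O", _AA),
    ("aspartate", "[NH2:1]C(CC(O)=O)[C:2](=O)O", _AA),
    ("cysteine", "[NH2:1]C(CS)[C:2](=O)O", _AA),
    ("glutamate", "[NH2:1]C(CCC(O)=O)[C:2](=O)O", _AA),
    ("glutamine", "[NH2:1]C(CCC(N)=O)[C:2](=O)O", _AA),
    ("glycine", "[NH2:1]C[C:2](=O)O", _AA),
    ("histidine", "[NH2:1]C(Cc1c[nH]cn1)[C:2](=O)O", _AA),
    ("isoleucine", "[NH2:1]C(C(C)CC)[C:2](=O)O", _AA),
    ("leucine", "[NH2:1]C(CC(C)C)[C:2](=O)O", _AA),
    ("lysine", "[NH2:1]C(CCCCN)[C:2](=O)O", _AA),
    ("methionine", "[NH2:1]C(CCSC)[C:2](=O)O", _AA),
    ("phenylalanine", "[NH2:1]C(Cc1ccccc1)[C:2](=O)O", _AA),
    ("proline", "[NH:1]1CCCC1[C:2](=O)O", _AA),
    ("serine", "[NH2:1]C(CO)[C:2](=O)O", _AA),
    ("threonine", "[NH2:1]C(C(C)O)[C:2](=O)O", _AA),
    ("tryptophan", "[NH2:1]C(Cc1c[nH]c2ccccc12)[C:2](=O)O", _AA),
    ("tyrosine", "[NH2:1]C(Cc1ccc(O)cc1)[C:2](=O)O", _AA),
    ("valine", "[NH2:1]C(C(C)C)[C:2](=O)O", _AA),
    # nonproteinogenic amino acids
    ("ornithine", "[NH2:1]C(CCCN)[C:2](=O)O", _AA),
    ("N-hydroxyornithine", "[NH2:1]C(CCCNO)[C:2](=O)O", _AA),
    ("2-aminoadipate", "[NH2:1]C(CCCC(O)=O)[C:2](=O)O", _AA),
    ("beta-hydroxytyrosine", "[NH2:1]C(C(O)c1ccc(O)cc1)[C:2](=O)O", _AA),
    ("4-hydroxyphenylglycine", "[NH2:1]C(c1ccc(O)cc1)[C:2](=O)O", _AA),
    ("3,5-dihydroxyphenylglycine", "[NH2:1]C(c1cc(O)cc(O)c1)[C:2](=O)O", _AA),
    ("pipecolate", "[NH:1]1CCCCC1[C:2](=O)O", _AA),
    ("3-hydroxypipecolate", "[NH:1]1CCCC(O)C1[C:2](=O)O", _AA),
    ("piperazate", "[NH:1]1[NH]CCCC1[C:2](=O)O", _AA),
    ("dehydroaminobutyrate", "[NH2:1]C(=CC)[C:2](=O)O", _AA),
    ("beta-methylglutamate", "[NH2:1]C(C(C)CC(O)=O)[C:2](=O)O", _AA),
    ("beta-hydroxyleucine", "[NH2:1]C(C(O)C(C)C)[C:2](=O)O", _AA),
    ("beta-methylphenylalanine", "[NH2:1]C(C(C)c1ccccc1)[C:2](=O)O", _AA),
    ("beta-hydroxyphenylalanine", "[NH2:1]C(C(O)c1ccccc1)[C:2](=O)O", _AA),
    ("beta-hydroxyasparagine", "[NH2:1]C(C(O)C(N)=O)[C:2](=O)O", _AA),
    ("beta-hydroxyaspartate", "[NH2:1]C(C(O)C(O)=O)[C:2](=O)O", _AA),
    ("capreomycidine", "[NH2:1]C(C1CNC(=N)N1)[C:2](=O)O", _AA),
    ("diaminopropionate", "[NH2:1]C(CN)[C:2](=O)O", _AA),
    ("kynurenine", "[NH2:1]C(CC(=O)c1ccccc1N)[C:2](=O)O", _AA),
    # ketide extender units (acyltransferase substrates)
    ("malonate", "[CH2:1][C:2](=O)O", "ketide"),
    ("methylmalonate", "[CH:1](C)[C:2](=O)O", "ketide"),
    ("ethylmalonate", "[CH:1](CC)[C:2](=O)O", "ketide"),
    ("methoxymalonate", "[CH:1](OC)[C:2](=O)O", "ketide"),
    ("hydroxymalonate", "[CH:1](O)[C:2](=O)O", "ketide"),
    # acyl starter units
    ("acetate", "C[C:2](=O)O", "acyl_starter"),
    ("propionate", "CC[C:2](=O)O", "acyl_starter"),
    ("butyrate", "CCC[C:2](=O)O", "acyl_starter"),
    ("isobutyrate", "CC(C)[C:2](=O)O", "acyl_starter"),
    ("2-methylbutyrate", "CCC(C)[C:2](=O)O", "acyl_starter"),
    ("isovalerate", "CC(C)C[C:2](=O)O", "acyl_starter"),
    ("hexanoate", "CCCCC[C:2](=O)O", "acyl_starter"),
    ("octanoate", "CCCCCCC[C:2](=O)O", "acyl_starter"),
    ("decanoate", "CCCCCCCCC[C:2](=O)O", "acyl_starter"),
    ("hexadienoate", "CC=CC=C[C:2](=O)O", "acyl_starter"),
    ("malonamate", "NC(=O)C[C:2](=O)O", "acyl_starter"),
    # aryl starter units
    ("benzoate", "[C:2](=O)(O)c1ccccc1", "aryl_starter"),
    ("2,3-dihydroxybenzoate", "[C:2](=O)(O)c1cccc(O)c1O", "aryl_starter"),
    ("3-amino-5-hydroxybenzoate", "[C:2](=O)(O)c1cc(N)cc(O)c1", "aryl_starter"),
    ("3-hydroxypicolinate", "[C:2](=O)(O)c1ncccc1O", "aryl_starter"),
    (
        "3-formamido-2-hydroxybenzoate",
        "[C:2](=O)(O)c1cccc(NC=O)c1O",
        "aryl_starter",
    ),
    ("3-hydroxyanthranilate", "[C:2](=O)(O)c1cccc(O)c1N", "aryl_starter"),
    ("quinoxaline-2-carboxylate", "[C:2](=O)(O)c1cnc2ccccc2n1", "aryl_starter"),
    # alpha-hydroxy / alpha-keto acids (depsipeptide units; keto acids are
    # carried in their reduced, ester-forming hydroxy form)
    ("lactate", "[OH:1]C(C)[C:2](=O)O", "alpha_hydroxy_acid"),
    ("2-hydroxyisovalerate", "[OH:1]C(C(C)C)[C:2](=O)O", "alpha_hydroxy_acid"),
    ("2-hydroxyisocaproate", "[OH:1]C(CC(C)C)[C:2](=O)O", "alpha_hydroxy_acid"),
    ("2-ketoisovalerate", "[OH:1]C(C(C)C)[C:2](=O)O", "alpha_keto_acid"),
    # hexose sugars
    ("glucose", "[CH:1]1OC(CO)C(O)C(O)C1O", "sugar"),
    ("mannose", "[CH:1]1OC(CO)C(O)C(O)C1O", "sugar"),
    ("gulose", "[CH:1]1OC(CO)C(O)C(O)C1O", "sugar"),
    ("N-acetylglucosamine", "[CH:1]1OC(CO)C(O)C(O)C1NC(C)=O", "sugar"),
    # deoxysugars (fixture subset of the 63-entry code)
    ("olivose", "[CH:1]1CC(O)C(O)C(C)O1", "sugar"),
    ("digitoxose", "[CH:1]1CC(O)C(O)C(C)O1", "sugar"),
    ("oleandrose", "[CH:1]1CC(OC)C(O)C(C)O1", "sugar"),
    ("rhamnose", "[CH:1]1OC(C)C(O)C(O)C1O", "sugar"),
    ("desosamine", "[CH:1]1C(O)C(N(C)C)CC(C)O1", "sugar"),
    ("mycaminose", "[CH:1]1C(O)C(N(C)C)C(O)C(C)O1", "sugar"),
    ("mycarose", "[CH:1]1CC(C)(O)C(O)C(C)O1", "sugar"),
    ("forosamine", "[CH:1]1CCC(N(C)C)C(C)O1", "sugar"),
    ("amicetose", "[CH:1]1CCC(O)C(C)O1", "sugar"),
    ("xylose", "[CH:1]1OCC(O)C(O)C1O", "sugar"),
]


class MonomerLibrary:
    """Name -> :class:`MonomerRecord` lookup; unknown names error loudly."""

    def __init__(self, records=None):
        self._records = {
            r.name: r
            for r in (
                records
                if records is not None
                else (MonomerRecord(n, s, c) for n, s, c in _MONOMERS)
            )
        }

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def names(self):
        return sorted(self._records)

    def get(self, name: str) -> MonomerRecord:
        try:
            return self._records[name]
        except KeyError:
            raise MonomerLibraryError(
                f"no structure in the monomer library for substrate "
                f"'{name}'"
            ) from None


def default_monomer_library() -> MonomerLibrary:
    return MonomerLibrary()


# ---------------------------------------------------------------------------
# Glycogenetic code (fixture subset; the full code covers 63 deoxysugars)
# ---------------------------------------------------------------------------

GLYCO_CODE: dict[str, frozenset] = {
    "olivose": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_3_ketoreductase",
            "sugar_4_ketoreductase",
        }
    ),
    "digitoxose": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_3_ketoreductase",
            "sugar_35_epimerase",
        }
    ),
    "oleandrose": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_3_ketoreductase",
            "sugar_4_ketoreductase",
            "sugar_4_O_methyltransferase",
        }
    ),
    "rhamnose": frozenset(
        {"sugar_46_dehydratase", "sugar_35_epimerase", "sugar_4_ketoreductase"}
    ),
    "desosamine": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_3_aminotransferase",
            "sugar_NN_dimethyltransferase",
        }
    ),
    "mycaminose": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_34_isomerase",
            "sugar_3_aminotransferase",
            "sugar_NN_dimethyltransferase",
            "sugar_4_ketoreductase",
        }
    ),
    "mycarose": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_3_C_methyltransferase",
            "sugar_4_ketoreductase",
        }
    ),
    "forosamine": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_26_dideoxygenase",
            "sugar_4_aminotransferase",
            "sugar_NN_dimethyltransferase",
        }
    ),
    "amicetose": frozenset(
        {
            "sugar_46_dehydratase",
            "sugar_23_dehydratase",
            "sugar_26_dideoxygenase",
            "sugar_4_ketoreductase",
        }
    ),
    "xylose": frozenset({"sugar_UDP_dehydrogenase", "sugar_UDP_decarboxylase"}),
}


def write_glyco_code_tsv(code: dict, path: str) -> None:
    with open(path, "w") as fh:
        for sugar in sorted(code):
            fh.write(f"{sugar}\t{','.join(sorted(code[sugar]))}\n")


def read_glyco_code_tsv(path: str) -> dict[str, frozenset]:
    code = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sugar, genes = line.split("\t")
            code[sugar] = frozenset(genes.split(","))
    return code


# ---------------------------------------------------------------------------
# Chlorinase substrate classes (ranked fallback vocabulary)
# ---------------------------------------------------------------------------

#: substrate class -> residue/monomer names bearing chlorination sites
CHLORINASE_CLASSES: dict[str, frozenset] = {
    "tyrosine_phenylglycine": frozenset(
        {
            "tyrosine",
            "beta-hydroxytyrosine",
            "4-hydroxyphenylglycine",
            "3,5-dihydroxyphenylglycine",
        }
    ),
    "tryptophan": frozenset({"tryptophan"}),
    "histidine": frozenset({"histidine"}),
    "aromatic_starter": frozenset(
        {
            "benzoate",
            "2,3-dihydroxybenzoate",
            "3-amino-5-hydroxybenzoate",
            "3-hydroxyanthranilate",
        }
    ),
    "threonine": frozenset({"threonine"}),
    "branched_chain": frozenset({"valine", "leucine", "isoleucine"}),
}

# ---------------------------------------------------------------------------
# Type II PKS reference tables
# ---------------------------------------------------------------------------

#: priming-AT starter units and their gating domains
TYPE2_STARTERS = (
    "propionate",
    "butyrate",
    "isobutyrate",
    "2-methylbutyrate",
    "hexadienoate",
    "benzoate",
    "malonamate",
)

TYPE2_STARTER_GATES: dict[str, str] = {
    "benzoate": "phenylalanine_ammonia_lyase",
    "malonamate": "amidotransferase",
}

#: cyclase clade -> ring-closure carbon pairs (provisional topology table);
#: in each (a, b) pair the odd-numbered carbon is the attacked carbonyl
CYCLASE_RING_PATTERNS: dict[str, tuple] = {
    "cyclase_clade_I": ((7, 12),),
    "cyclase_clade_II": ((5, 14),),
    "cyclase_clade_III": ((7, 12), (5, 14)),
    "cyclase_clade_IV": ((9, 14),),
    "cyclase_clade_Va": ((3, 16),),
    "cyclase_clade_Vb": ((5, 18),),
    "cyclase_clade_VIa": ((7, 12), (5, 14), (3, 16)),
    # clade VIb is polyphyletic: resolved through the CLF annotation
    "cyclase_clade_VIb:anthracycline": ((7, 12), (5, 14), (3, 16)),
    "cyclase_clade_VIb:tetracycline": ((9, 14), (7, 16), (5, 18)),
    "cyclase_clade_VII": ((9, 14), (7, 16)),
    "cyclase_clade_VIIIa": ((3, 8),),
    "cyclase_clade_VIIIb": ((5, 10),),
    "cyclase_clade_IX": ((7, 12),),
}

#: type II ketoreductase family -> reduced carbon number
TYPE2_KR_CARBON = {"KR_C9": 9, "KR_C11": 11, "KR_C15": 15, "KR_C17": 17, "KR_C19": 19}

#: type II C-methyltransferase family -> methylated carbon number
TYPE2_CMT_CARBON = {"MT_C6": 6, "MT_C8": 8, "MT_C10": 10}


# ---------------------------------------------------------------------------
# Tailoring-reaction registry
# ---------------------------------------------------------------------------

#: nominal registry size (slots beyond the concretely described reactions are
#: provisional placeholders; the authoritative list is external)
REACTION_REGISTRY_SIZE = 54

#: (name, trigger family[:subtype], site_rule, graph_edit)
REACTION_REGISTRY: tuple = (
    ("O-glycosylation", "glycosyltransferase", "free_hydroxyl", "glycosylate"),
    ("sulfation", "sulfotransferase", "free_hydroxyl", "sulfate"),
    ("carbamoylation", "carbamoyltransferase", "free_hydroxyl", "carbamoylate"),
    ("phosphorylation", "phosphotransferase", "free_hydroxyl", "phosphorylate"),
    ("chlorination", "chlorinase", "chlorinase_ranked", "chlorinate"),
    ("glycopeptide_crosslink", "glycopeptide_P450", "p450_positions", "crosslink"),
    (
        "beta_lactam_formation",
        "isopenicillin_N_synthase",
        "cys_val_diresidue",
        "penam",
    ),
    (
        "penam_side_chain_exchange",
        "isopenicillin_N_acyltransferase",
        "aminoadipate_residue",
        "phenylacetyl_exchange",
    ),
    (
        "ring_expansion",
        "deacetoxycephalosporin_C_synthase",
        "penam_core",
        "cephem",
    ),
    ("N-formylation", "formyltransferase", "formylation_nitrogens", "formylate"),
    (
        "kynurenine_formation",
        "tryptophan_dioxygenase",
        "tryptophan_residue",
        "kynurenine",
    ),
    ("pyrrole_formation", "proline_dehydrogenase", "terminal_proline", "pyrrole"),
    ("C-glycosylation", "c_glycosyltransferase", "aromatic_alpha_carbon", "c_glycosylate"),
)


@dataclass(frozen=True)
class TailoringReaction:
    name: str
    trigger: str
    site_rule: str
    graph_edit: str


def reaction_registry() -> list[TailoringReaction]:
    return [TailoringReaction(*row) for row in REACTION_REGISTRY]


def write_reaction_registry_tsv(path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\ttrigger\tsite_rule\tgraph_edit\n")
        for row in REACTION_REGISTRY:
            fh.write("\t".join(row) + "\n")
        # provisional slots up to the nominal registry size
        for i in range(len(REACTION_REGISTRY), REACTION_REGISTRY_SIZE):
            fh.write(f"provisional_{i + 1}\t-\tnone\tnone\n")
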