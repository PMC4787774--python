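"""Synthetic reference data and test genomes.

Everything the pipeline consumes — domain search profiles, substrate
profiles, monomer structures, the glycogenetic code, the reaction registry,
compound and cluster databases, and annotated test genomes — is generated
here deterministically from a seed, so every stage is testable without
downloads. Fixture profiles are tiny (built from 8 mutated copies of a
60-residue synthetic consensus each); their adequacy for real genomes is
explicitly not claimed. Ground-truth domain layouts are embedded as CDS
features in the GenBank fixtures and can be exported as precomputed
annotation tables, giving a backend-free test path equivalent to the
profile-search path.

The flagship genome encodes a hypothetical NRPS cluster with an acyl
starter, five amino-acid modules (one heterocyclizing cysteine), three free
scaffold hydroxyls, one chlorinase, one deoxysugar glycosyltransferase with
a two-sugar-ambiguous gene complement — yielding 2 sugar candidates x 3
attachment sites x (3 macrolactones + linear acid) x 1 chlorination site =
24 combinatorial plans. Additional genomes cover trans-AT split modules,
trans-adenylation didomains, a type II PKS with an annotated chain length
factor, a terminal-reductase cluster, and a resistance-flanked pair of
clusters.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from bgcforge.annotate import (
    Domain,
    DomainModel,
    SubstrateProfileLibrary,
    write_annotation_table,
)
from bgcforge.cluster import Cluster, build_clusters, classify_and_filter
from bgcforge.derep import ArtificialDerepOrf, CompoundRecord
from bgcforge.refdata import (
    GLYCO_CODE,
    MonomerLibrary,
    reaction_registry,
    write_glyco_code_tsv,
    write_reaction_registry_tsv,
)
from bgcforge.seqio import Contig, find_orfs

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CONSENSUS_LENGTH = 60
FIXTURE_CUTOFF = 25.0

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "TCT", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTT",
}


@dataclass
class DomainSpec:
    """Ground-truth domain on a fixture ORF: a model key plus metadata."""

    key: str
    family: str
    functional_subtype: Optional[str] = None
    substrates: tuple = ()
    annotations: dict = field(default_factory=dict)


@dataclass
class OrfSpec:
    name: str
    domains: list
    gap_before: int = 300  # filler nucleotides before the gene (multiple of 3)


@dataclass
class FixtureGenome:
    name: str
    contig: Contig
    orf_specs: list
    layout: list = field(default_factory=list)  # (OrfSpec, start, end, aa spans)

    def fasta(self) -> str:
        return f">{self.contig.id}\n{self.contig.sequence}\n"

    def record(self) -> SeqRecord:
        rec = SeqRecord(
            Seq(self.contig.sequence),
            id=self.contig.id,
            name=self.contig.id[:16],
            description=f"synthetic fixture genome {self.name}",
        )
        rec.annotations["molecule_type"] = "DNA"
        for spec, start, end, spans in self.layout:
            feature = SeqFeature(
                FeatureLocation(start - 1, end, strand=1),
                type="CDS",
                qualifiers={
                    "locus_tag": [spec.name],
                    "note": [
                        "ground_truth="
                        + json.dumps(
                            [
                                {
                                    "family": d.family,
                                    "subtype": d.functional_subtype,
                                    "start_aa": s,
                                    "end_aa": e,
                                }
                                for d, (s, e) in zip(spec.domains, spans)
                            ]
                        )
                    ],
                },
            )
            rec.features.append(feature)
        return rec

    def ground_truth_domains(self) -> list[Domain]:
        """Embedded domain layout with ORF ids as the ORF caller assigns them."""
        orfs = find_orfs(self.contig)
        by_coords = {(o.start, o.end, o.strand): o for o in orfs}
        domains: list[Domain] = []
        for spec, start, end, spans in self.layout:
            orf = by_coords.get((start, end, "+"))
            if orf is None:
                raise AssertionError(
                    f"fixture ORF {spec.name} not recovered by the ORF caller"
                )
            for d, (s, e) in zip(spec.domains, spans):
                domains.append(
                    Domain(
                        orf_id=orf.id,
                        family=d.family,
                        start_aa=s,
                        end_aa=e,
                        score=50.0,
                        substrates=[tuple(x) for x in d.substrates],
                        functional_subtype=d.functional_subtype,
                        annotations=dict(d.annotations),
                        sequence=orf.protein[s - 1 : e],
                    )
                )
        return domains


@dataclass
class FixtureBundle:
    seed: int
    consensus: dict
    models: list
    substrate_profiles: SubstrateProfileLibrary
    monomers: MonomerLibrary
    glyco_code: dict
    reactions: list
    compound_db: list
    cluster_db: list
    anchors: dict
    genomes: dict

    def cluster_for(self, genome_name: str, index: int = 0) -> Cluster:
        """Build the (classified) cluster object for a fixture genome from
        its embedded ground truth."""
        genome = self.genomes[genome_name]
        orfs = find_orfs(genome.contig)
        domains = genome.ground_truth_domains()
        clusters = build_clusters(domains, orfs)
        return classify_and_filter(clusters[index])


# ---------------------------------------------------------------------------
# genome layouts
# ---------------------------------------------------------------------------


def _flagship_specs() -> list[OrfSpec]:
    thio = DomainSpec("thiolation", "thiolation")
    lcl = DomainSpec("condensation:lcl", "condensation")

    def adenyl(substrate):
        return DomainSpec(
            f"adenylation:{substrate}",
            "adenylation",
            substrates=((substrate, 40.0),),
        )

    return [
        OrfSpec(
            "nrpsA",
            [
                DomainSpec(
                    "condensation:starter",
                    "condensation",
                    functional_subtype="starter_condensation",
                    annotations={"substrate": "isovalerate"},
                ),
                adenyl("serine"),
                thio,
                lcl,
                adenyl("threonine"),
                thio,
            ],
        ),
        OrfSpec(
            "nrpsB",
            [
                DomainSpec(
                    "condensation:het",
                    "condensation",
                    functional_subtype="heterocyclization",
                ),
                adenyl("cysteine"),
                thio,
                lcl,
                adenyl("serine"),
                thio,
                lcl,
                adenyl("tyrosine"),
                thio,
                DomainSpec("thioesterase", "thioesterase"),
            ],
        ),
        OrfSpec(
            "halA",
            [
                DomainSpec(
                    "chlorinase",
                    "chlorinase",
                    annotations={"substrate_class": "tyrosine_phenylglycine"},
                )
            ],
        ),
        OrfSpec("gtfA", [DomainSpec("glycosyltransferase", "glycosyltransferase")]),
        OrfSpec("sugA", [DomainSpec("sugar_46_dehydratase", "sugar_46_dehydratase")]),
        OrfSpec("sugB", [DomainSpec("sugar_23_dehydratase", "sugar_23_dehydratase")]),
        OrfSpec("sugC", [DomainSpec("sugar_3_ketoreductase", "sugar_3_ketoreductase")]),
        OrfSpec("sugD", [DomainSpec("sugar_4_ketoreductase", "sugar_4_ketoreductase")]),
        OrfSpec("sugE", [DomainSpec("sugar_35_epimerase", "sugar_35_epimerase")]),
    ]


def _transat_specs() -> list[OrfSpec]:
    return [
        OrfSpec(
            "pksA",
            [
                DomainSpec("ketosynthase:ks", "ketosynthase"),
                DomainSpec("ketoreductase", "ketoreductase"),
            ],
        ),
        OrfSpec(
            "pksB",
            [
                DomainSpec("thiolation", "thiolation"),
                DomainSpec("ketosynthase:ks", "ketosynthase"),
                DomainSpec("thioesterase", "thioesterase"),
            ],
        ),
        OrfSpec(
            "transAT",
            [
                DomainSpec(
                    "acyltransferase:malonate",
                    "acyltransferase",
                    substrates=(("malonate", 40.0),),
                )
            ],
        ),
    ]


def _transa_specs() -> list[OrfSpec]:
    return [
        OrfSpec(
            "nrpsA",
            [
                DomainSpec("condensation:lcl", "condensation"),
                DomainSpec(
                    "adenylation:glycine",
                    "adenylation",
                    substrates=(("glycine", 40.0),),
                ),
                DomainSpec("thiolation", "thiolation"),
                DomainSpec("condensation:lcl", "condensation"),
                DomainSpec("thiolation", "thiolation"),
            ],
        ),
        OrfSpec(
            "standaloneA",
            [
                DomainSpec(
                    "adenylation:alanine",
                    "adenylation",
                    substrates=(("alanine", 40.0),),
                ),
                DomainSpec("thiolation", "thiolation"),
            ],
        ),
    ]


def _type2_specs() -> list[OrfSpec]:
    return [
        OrfSpec("ksA", [DomainSpec("KS_alpha", "KS_alpha")]),
        OrfSpec(
            "clfA",
            [
                DomainSpec(
                    "chain_length_factor",
                    "chain_length_factor",
                    annotations={"extensions": 9, "clf_pattern": "anthracycline"},
                )
            ],
        ),
        OrfSpec("acpA", [DomainSpec("ACP", "ACP")]),
        OrfSpec("cycA", [DomainSpec("cyclase_clade_I", "cyclase_clade_I")]),
        OrfSpec("krA", [DomainSpec("KR_C9", "KR_C9")]),
        OrfSpec("gtfT", [DomainSpec("glycosyltransferase", "glycosyltransferase")]),
        OrfSpec("sugA", [DomainSpec("sugar_46_dehydratase", "sugar_46_dehydratase")]),
        OrfSpec("sugB", [DomainSpec("sugar_23_dehydratase", "sugar_23_dehydratase")]),
        OrfSpec("sugC", [DomainSpec("sugar_3_ketoreductase", "sugar_3_ketoreductase")]),
        OrfSpec("sugD", [DomainSpec("sugar_4_ketoreductase", "sugar_4_ketoreductase")]),
    ]


def _reductase_specs() -> list[OrfSpec]:
    return [
        OrfSpec(
            "nrpsR",
            [
                DomainSpec("condensation:lcl", "condensation"),
                DomainSpec(
                    "adenylation:glycine",
                    "adenylation",
                    substrates=(("glycine", 40.0),),
                ),
                DomainSpec("thiolation", "thiolation"),
                DomainSpec("condensation:lcl", "condensation"),
                DomainSpec(
                    "adenylation:serine",
                    "adenylation",
                    substrates=(("serine", 40.0),),
                ),
                DomainSpec("thiolation", "thiolation"),
                DomainSpec("reductase_terminal", "reductase_terminal"),
            ],
        ),
    ]


def _resist_specs() -> list[OrfSpec]:
    return [
        OrfSpec(
            "nrpsX",
            [
                DomainSpec("condensation:lcl", "condensation"),
                DomainSpec(
                    "adenylation:alanine",
                    "adenylation",
                    substrates=(("alanine", 40.0),),
                ),
                DomainSpec("thiolation", "thiolation"),
            ],
        ),
        OrfSpec(
            "blaR",
            [DomainSpec("resistance_beta_lactamase", "resistance_beta_lactamase")],
            gap_before=5001,
        ),
        OrfSpec(
            "nrpsY",
            [
                DomainSpec("condensation:lcl", "condensation"),
                DomainSpec(
                    "adenylation:glycine",
                    "adenylation",
                    substrates=(("glycine", 40.0),),
                ),
                DomainSpec("thiolation", "thiolation"),
            ],
            gap_before=22002,
        ),
    ]


_GENOME_SPECS = {
    "flagship": _flagship_specs,
    "transat": _transat_specs,
    "transa": _transa_specs,
    "type2": _type2_specs,
    "reductase": _reductase_specs,
    "resist": _resist_specs,
}


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------


def _consensus_for(key: str, consensus: dict, rng: random.Random) -> str:
    if key not in consensus:
        consensus[key] = "".join(
            rng.choice(AA_ALPHABET) for _ in range(CONSENSUS_LENGTH)
        )
    return consensus[key]


def _pad(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA_ALPHABET) for _ in range(n))


def _build_protein(spec: OrfSpec, consensus: dict, rng: random.Random):
    """Protein with embedded domain consensi; returns (protein, aa spans)."""
    parts = ["M" + _pad(rng, 4)]
    spans = []
    pos = len(parts[0])
    for d in spec.domains:
        seq = _consensus_for(d.key, consensus, rng)
        spans.append((pos + 1, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
        linker = _pad(rng, 3)
        parts.append(linker)
        pos += len(linker)
    return "".join(parts), spans


def _gene_nt(protein: str) -> str:
    return "ATG" + "".join(_CODON[a] for a in protein[1:]) + "TAA"


def _filler(n: int, rng: random.Random) -> str:
    # A/C-only filler: contains no start or stop codon on the forward strand
    return "".join(rng.choice("AC") for _ in range(n))


def _build_genome(
    name: str, specs: list, consensus: dict, rng: random.Random
) -> FixtureGenome:
    parts: list[str] = []
    layout = []
    pos = 0
    for spec in specs:
        gap = spec.gap_before - (spec.gap_before % 3)
        parts.append(_filler(gap, rng))
        pos += gap
        protein, spans = _build_protein(spec, consensus, rng)
        gene = _gene_nt(protein)
        layout.append((spec, pos + 1, pos + len(gene), spans))
        parts.append(gene)
        pos += len(gene)
    parts.append(_filler(300, rng))
    contig = Contig(id=f"{name}_contig1", sequence="".join(parts))
    return FixtureGenome(name=name, contig=contig, orf_specs=specs, layout=layout)


# ---------------------------------------------------------------------------
# search profiles
# ---------------------------------------------------------------------------


def _build_profiles(consensus: dict, rng: random.Random):
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmms = {}
    for key in sorted(consensus):
        seqs = []
        for i in range(8):
            chars = list(consensus[key])
            for _ in range(3):
                p = rng.randrange(len(chars))
                chars[p] = rng.choice(AA_ALPHABET)
            seqs.append(
                pyhmmer.easel.TextSequence(
                    name=f"{key}|{i}".encode(), sequence="".join(chars)
                )
            )
        msa = pyhmmer.easel.TextMSA(
            name=key.encode().replace(b":", b"_"), sequences=seqs
        )
        hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
        hmms[key] = hmm
    return hmms


def _collect_domain_specs(genomes: dict) -> dict:
    """Distinct DomainSpec metadata per model key across all genomes."""
    by_key: dict[str, DomainSpec] = {}
    for genome in genomes.values():
        for spec in genome.orf_specs:
            for d in spec.domains:
                by_key.setdefault(d.key, d)
    return by_key


_COMPOUND_SMILES = [
    ("cpd1", "glycylglycine", "NCC(=O)NCC(=O)O"),
    ("cpd2", "acetoacetate", "CC(=O)CC(=O)O"),
    ("cpd3", "salicylate", "O=C(O)c1ccccc1O"),
    ("cpd4", "tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("cpd5", "tripeptide_SGS", "NC(CO)C(=O)NCC(=O)NC(CO)C(=O)O"),
    ("cpd6", "benzamide", "NC(=O)c1ccccc1"),
    ("cpd7", "caffeate", "O=C(O)C=Cc1ccc(O)c(O)c1"),
    ("cpd8", "diketopiperazine", "O=C1CNC(=O)CN1"),
    ("cpd9", "pantothenate", "CC(C)(CO)C(O)C(=O)NCCC(=O)O"),
    ("cpd10", "citrate", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("cpd11", "shikimate", "OC1CC(C(=O)O)=CC(O)C1O"),
    ("cpd12", "phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("cpd13", "chlorotyrosine", "NC(Cc1ccc(O)c(Cl)c1)C(=O)O"),
    ("cpd14", "rhamnoside", "CC1OC(OC)C(O)C(O)C1O"),
    ("cpd15", "naphthoquinone", "O=C1C=CC(=O)c2ccccc21"),
    ("cpd16", "thiazole_acid", "O=C(O)c1cscn1"),
    ("cpd17", "valerolactone", "O=C1CCCCO1"),
    ("cpd18", "orsellinate", "Cc1cc(O)cc(O)c1C(=O)O"),
    ("cpd19", "anthranilate", "Nc1ccccc1C(=O)O"),
    ("cpd20", "pyrrole_carboxylate", "O=C(O)c1ccc[nH]1"),
    ("cpd21", "triketide", "CC(=O)CC(=O)CC(=O)O"),
    ("cpd22", "macrolactone_model", "CC1CCCCCC(=O)O1"),
]


def generate_bundle(seed: int = 0, out_dir: Optional[str] = None) -> FixtureBundle:
    """Generate the full self-consistent fixture bundle (seed-deterministic).

    When ``out_dir`` is given, genomes (GenBank + FASTA), annotation tables,
    and the reference tables are written there as plain-text files.
    """
    rng = random.Random(seed)
    consensus: dict[str, str] = {}
    genomes = {
        name: _build_genome(name, make_specs(), consensus, rng)
        for name, make_specs in sorted(_GENOME_SPECS.items())
    }
    spec_by_key = _collect_domain_specs(genomes)
    hmms = _build_profiles(consensus, rng)
    models = [
        DomainModel(
            name=key,
            family=spec_by_key[key].family,
            profile=hmms[key],
            bitscore_cutoff=FIXTURE_CUTOFF,
            functional_subtype=spec_by_key[key].functional_subtype,
            annotations=dict(spec_by_key[key].annotations),
            substrates=tuple(spec_by_key[key].substrates),
        )
        for key in sorted(spec_by_key)
    ]
    # substrate-specific profiles: one per (family, substrate) model key,
    # sharing the model's consensus so ranks are recoverable by search
    substrate_profiles: dict[str, dict] = {}
    for key, spec in sorted(spec_by_key.items()):
        if ":" not in key:
            continue
        family = spec.family
        if family not in ("adenylation", "acyl_adenylating", "acyltransferase"):
            continue
        substrate = key.split(":", 1)[1]
        if spec.substrates:
            substrate = spec.substrates[0][0]
        substrate_profiles.setdefault(family, {})[substrate] = hmms[key]
    # an extra proline profile exercises substrate ranking beyond the genomes
    proline_key = "adenylation:proline"
    _consensus_for(proline_key, consensus, rng)
    extra = _build_profiles({proline_key: consensus[proline_key]}, rng)
    substrate_profiles.setdefault("adenylation", {})["proline"] = extra[
        proline_key
    ]

    anchors = {}
    for key in sorted(consensus):
        family = spec_by_key[key].family if key in spec_by_key else "adenylation"
        anchors.setdefault(family, consensus[key])

    compound_db = [CompoundRecord(*row) for row in _COMPOUND_SMILES]

    cluster_db = [
        ArtificialDerepOrf(
            cluster_id=f"ref_cluster{i + 1}",
            sequence="".join(
                rng.choice(AA_ALPHABET) for _ in range(rng.randrange(200, 320))
            ),
        )
        for i in range(5)
    ]

    bundle = FixtureBundle(
        seed=seed,
        consensus=consensus,
        models=models,
        substrate_profiles=SubstrateProfileLibrary(substrate_profiles),
        monomers=MonomerLibrary(),
        glyco_code=dict(GLYCO_CODE),
        reactions=reaction_registry(),
        compound_db=compound_db,
        cluster_db=cluster_db,
        anchors=anchors,
        genomes=genomes,
    )
    # include the flagship cluster's own artificial ORF so pipeline-level
    # genetic dereplication has a recoverable reference
    from bgcforge.derep import make_artificial_orf

    flagship = bundle.cluster_for("flagship")
    ref = make_artificial_orf(flagship, anchors)
    bundle.cluster_db.append(
        ArtificialDerepOrf(cluster_id="ref_flagship", sequence=ref.sequence)
    )
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def generate_annotation_table(
    genome: FixtureGenome, path: Optional[str] = None
) -> list[Domain]:
    """Precomputed-annotation TSV matching the genome's embedded layout."""
    domains = genome.ground_truth_domains()
    if path is not None:
        write_annotation_table(domains, path)
    return domains


def _write_bundle(bundle: FixtureBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name, genome in sorted(bundle.genomes.items()):
        with open(os.path.join(out_dir, f"{name}.fasta"), "w") as fh:
            fh.write(genome.fasta())
        SeqIO.write(
            genome.record(), os.path.join(out_dir, f"{name}.gbk"), "genbank"
        )
        generate_annotation_table(
            genome, os.path.join(out_dir, f"{name}.annotation.tsv")
        )
    write_glyco_code_tsv(
        bundle.glyco_code, os.path.join(out_dir, "glyco_code.tsv")
    )
    write_reaction_registry_tsv(os.path.join(out_dir, "reactions.tsv"))
    with open(os.path.join(out_dir, "compounds.tsv"), "w") as fh:
        for c in bundle.compound_db:
            fh.write(f"{c.id}\t{c.name}\t{c.smiles}\n")
    with open(os.path.join(out_dir, "cluster_db.fasta"), "w") as fh:
        for ref in bundle.cluster_db:
            fh.write(f">{ref.cluster_id}\n{ref.sequence}\n")
    meta = {
        "seed": bundle.seed,
        "clusters": [ref.cluster_id for ref in bundle.cluster_db],
    }
    with open(os.path.join(out_dir, "cluster_db.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
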