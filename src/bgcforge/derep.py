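"""Genetic and chemical dereplication.

Genetic dereplication follows a multilocus-sequence-typing-style scheme:
bond-forming domains are grouped by family in a fixed (alphabetical)
registry order, sorted within each family by their alignment bitscore to a
per-family anchor domain as a proxy for genetic distance, and concatenated
into one artificial open reading frame. The query artificial ORF is locally
aligned to each database entry; the total alignment score is divided by the
number of residues aligned, and hits covering less than 25% of the query are
discarded.

Chemical dereplication computes 1024-bit circular fingerprints of diameter 6
(ECFP6, and FCFP6 with feature invariants) for every scaffold and compound
and ranks compound matches by descending ECFP6 Tanimoto coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

from bgcforge.annotate import protein_aligner
from bgcforge.cluster import Cluster
from bgcforge.errors import InputError
from bgcforge.families import is_bond_forming

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.25
FINGERPRINT_BITS = 1024
FINGERPRINT_RADIUS = 3  # diameter 6


@dataclass
class ArtificialDerepOrf:
    """Concatenated bond-forming domain sequences of one cluster."""

    cluster_id: str
    sequence: str
    domain_order: list = field(default_factory=list)
    segments: list = field(default_factory=list)  # (family, domain_id, seq)


@dataclass
class DerepHit:
    reference_cluster_id: str
    score: float  # alignment score / residues aligned
    coverage: float  # fraction of the query aligned
    orf_identity: float


def make_artificial_orf(
    cluster: Cluster, anchors: Optional[dict] = None
) -> ArtificialDerepOrf:
    """Build the query artificial ORF for genetic dereplication.

    ``anchors`` maps family -> anchor amino-acid sequence; within a family
    domains are ordered by descending anchor alignment score (ties by locus
    order). Families appear in alphabetical registry order.
    """
    bond = [d for d in cluster.domains if is_bond_forming(d.family)]
    if not bond:
        raise InputError(
            f"cluster {cluster.id} has no bond-forming domains; cannot "
            "dereplicate genetically"
        )
    anchors = anchors or {}
    aligner = protein_aligner()
    orf_order = {oid: i for i, oid in enumerate(cluster.orf_ids)}

    def anchor_score(domain) -> float:
        anchor = anchors.get(domain.family)
        if not anchor or not domain.sequence:
            return 0.0
        try:
            return float(aligner.score(domain.sequence, anchor))
        except (ValueError, IndexError):
            return 0.0

    keyed = []
    for j, d in enumerate(bond):
        keyed.append(
            (
                d.family,
                -anchor_score(d),
                orf_order.get(d.orf_id, 0),
                d.start_aa,
                j,
                d,
            )
        )
    keyed.sort(key=lambda t: t[:4])
    order = []
    segments = []
    for fam, _neg, _loc, _st, j, d in keyed:
        dom_id = f"{d.orf_id}:{fam}:{d.start_aa}"
        order.append((fam, dom_id))
        segments.append((fam, dom_id, d.sequence))
    return ArtificialDerepOrf(
        cluster_id=cluster.id,
        sequence="".join(seq for _f, _i, seq in segments),
        domain_order=order,
        segments=segments,
    )


def _alignment_stats(alignment, query: str, target: str):
    """(aligned query residues, identical residues) over aligned blocks."""
    aligned = 0
    identical = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        aligned += qe - qs
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            if query[qi] == target[ti]:
                identical += 1
    return aligned, identical


def dereplicate_genetic(
    query: ArtificialDerepOrf,
    db: Sequence[ArtificialDerepOrf],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[DerepHit]:
    """Rank database clusters by normalized artificial-ORF alignment score.

    Score is total alignment score divided by residues aligned; hits whose
    alignment covers less than ``min_coverage`` of the query are dropped.
    ``orf_identity`` is the alignment-length-weighted mean identity of
    per-domain best alignments.
    """
    if not db:
        return []
    aligner = protein_aligner()
    hits: list[DerepHit] = []
    for ref in db:
        try:
            alignment = aligner.align(query.sequence, ref.sequence)[0]
        except (ValueError, IndexError):
            continue
        aligned, _ident = _alignment_stats(
            alignment, query.sequence, ref.sequence
        )
        if aligned == 0:
            continue
        coverage = aligned / len(query.sequence)
        if coverage < min_coverage:
            continue
        score = float(alignment.score) / aligned
        total_len = 0
        weighted_ident = 0.0
        for _fam, _id, seq in query.segments:
            if not seq:
                continue
            try:
                seg_aln = aligner.align(seq, ref.sequence)[0]
            except (ValueError, IndexError):
                continue
            seg_aligned, seg_ident = _alignment_stats(seg_aln, seq, ref.sequence)
            if seg_aligned:
                total_len += seg_aligned
                weighted_ident += seg_ident
        orf_identity = (
            100.0 * weighted_ident / total_len if total_len else 0.0
        )
        hits.append(
            DerepHit(
                reference_cluster_id=ref.cluster_id,
                score=score,
                coverage=coverage,
                orf_identity=orf_identity,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.reference_cluster_id))
    return hits


# ---------------------------------------------------------------------------
# chemical dereplication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    smiles: str


def read_compound_db(path: str) -> list[CompoundRecord]:
    """TSV compound database: id, name, SMILES."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, name, smiles = line.split("\t")[:3]
            out.append(CompoundRecord(cid, name, smiles))
    return out


@dataclass
class SimilarityHit:
    scaffold_index: int
    compound_id: str
    compound_name: str
    ecfp6_tanimoto: float
    fcfp6_tanimoto: float


def fingerprints(mol):
    """(ECFP6, FCFP6) 1024-bit fingerprints for a molecule."""
    ecfp = AllChem.GetMorganFingerprintAsBitVect(
        mol, FINGERPRINT_RADIUS, nBits=FINGERPRINT_BITS
    )
    fcfp = AllChem.GetMorganFingerprintAsBitVect(
        mol, FINGERPRINT_RADIUS, nBits=FINGERPRINT_BITS, useFeatures=True
    )
    return ecfp, fcfp


def dereplicate_chemical(
    library,
    compounds: Sequence[CompoundRecord],
    top_k: int = 10,
) -> list[SimilarityHit]:
    """Tanimoto-rank library scaffolds against the compound database.

    Every (scaffold, compound) pair is scored on both fingerprints; results
    are sorted by descending ECFP6 Tanimoto (ties broken by compound id and
    scaffold index) and truncated to ``top_k``. Unparseable compound SMILES
    are skipped with a warning.
    """
    scaffold_fps = []
    for i, scaffold in enumerate(library.scaffolds):
        scaffold_fps.append((i, fingerprints(scaffold.mol)))
    hits: list[SimilarityHit] = []
    for comp in compounds:
        mol = Chem.MolFromSmiles(comp.smiles)
        if mol is None:
            logger.warning(
                "unparseable compound SMILES for %s; skipped", comp.id
            )
            continue
        cfps = fingerprints(mol)
        for i, sfps in scaffold_fps:
            hits.append(
                SimilarityHit(
                    scaffold_index=i,
                    compound_id=comp.id,
                    compound_name=comp.name,
                    ecfp6_tanimoto=DataStructs.TanimotoSimilarity(
                        sfps[0], cfps[0]
                    ),
                    fcfp6_tanimoto=DataStructs.TanimotoSimilarity(
                        sfps[1], cfps[1]
                    ),
                )
            )
    hits.sort(
        key=lambda h: (-h.ecfp6_tanimoto, h.compound_id, h.scaffold_index)
    )
    return hits[:top_k]
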