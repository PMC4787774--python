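"""Domain detection and substrate prediction.

Two interchangeable backends provide domain calls:

* a profile-HMM search (pyhmmer) over a library of
  :class:`DomainModel` objects carrying per-model bitscore cutoffs, or
* a precomputed annotation table (tab-separated, one domain per row) that
  replaces the search stage entirely.

Condensation, ketosynthase, chlorination, glycosyltransferase, priming
acyltransferase, and chain length factor calls are refined against curated
reference collections by local protein alignment, copying the annotation of
the best-scoring reference (functional subtype, substrate, chain length, or
cyclization pattern) onto the domain. Adenylation, acyl-adenylating, and
acyltransferase domains are scored against substrate-specific profiles to
rank their putative monomers, and rare substrates are demoted unless their
prerequisite biosynthesis domains are present in the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from bgcforge.errors import ConfigurationError
from bgcforge.families import SUBSTRATE_PREREQUISITES, is_registered_family
from bgcforge.seqio import Orf

logger = logging.getLogger(__name__)

#: Families whose calls are refined against curated reference collections.
REFINED_FAMILIES = frozenset(
    {
        "condensation",
        "ketosynthase",
        "chlorinase",
        "glycosyltransferase",
        "priming_AT",
        "chain_length_factor",
    }
)

#: Families carrying ranked substrate predictions.
SUBSTRATE_PREDICTED_FAMILIES = frozenset(
    {"adenylation", "acyl_adenylating", "acyltransferase"}
)

ANNOTATION_TABLE_COLUMNS = (
    "orf_id",
    "family",
    "start_aa",
    "end_aa",
    "score",
    "functional_subtype",
    "substrates",
    "annotations",
)


@dataclass
class DomainModel:
    """A named search profile with a bitscore cutoff.

    ``profile`` is an opaque backend object (a ``pyhmmer.plan7.HMM`` for the
    HMM backend). ``functional_subtype`` and ``annotations`` are defaults
    stamped onto every hit of this model (e.g. a glycopeptide P450 clade, an
    enediyne KS ring class).
    """

    name: str
    family: str
    profile: object = None
    bitscore_cutoff: float = 10.0
    functional_subtype: Optional[str] = None
    annotations: dict = field(default_factory=dict)
    substrates: tuple = ()  # default ranked substrates stamped onto hits

    def __post_init__(self):
        if not is_registered_family(self.family):
            raise ConfigurationError(f"unregistered domain family: {self.family}")


@dataclass
class Domain:
    """A located domain call on an ORF.

    ``substrates`` is an ordered (descending-score) list of
    ``(substrate_name, score)`` pairs; ``annotations`` carries
    alignment-refined payloads (e.g. ``extensions`` for a chain length
    factor, ``substrate_classes`` for a chlorinase, ``ring_pattern`` for a
    cyclase); ``sequence`` is the matched amino-acid subsequence when known.
    """

    orf_id: str
    family: str
    start_aa: int
    end_aa: int
    score: float
    substrates: list = field(default_factory=list)
    functional_subtype: Optional[str] = None
    annotations: dict = field(default_factory=dict)
    sequence: str = ""

    @property
    def top_substrate(self) -> Optional[str]:
        return self.substrates[0][0] if self.substrates else None


@dataclass(frozen=True)
class ReferenceRecord:
    """An annotated sequence in a curated refinement collection."""

    id: str
    sequence: str
    payload: dict


def protein_aligner() -> PairwiseAligner:
    """Local protein aligner (BLOSUM62, affine gaps) used for refinement,
    anchor ordering, and genetic dereplication."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


# ---------------------------------------------------------------------------
# HMM search backend
# ---------------------------------------------------------------------------


def annotate_domains(
    orfs: Sequence[Orf], models: Sequence[DomainModel]
) -> list[Domain]:
    """Search every ORF against the model library; return hits above cutoff.

    Overlapping hits of the same family on the same ORF are resolved to the
    best-scoring one. Output order is (orf input order, start_aa).
    """
    import pyhmmer

    if not models:
        raise ConfigurationError("empty domain model library")
    for m in models:
        if m.profile is None:
            raise ConfigurationError(
                f"model {m.name} has no search profile; use the annotation "
                "table backend instead"
            )
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(
            name=str(i).encode(), sequence=orf.protein
        ).digitize(alphabet)
        for i, orf in enumerate(orfs)
    ]
    hits_out: list[Domain] = []
    for model in models:
        for tophits in pyhmmer.hmmsearch([model.profile], seqs, T=0.0, domT=0.0):
            for hit in tophits:
                name = hit.name
                if isinstance(name, bytes):
                    name = name.decode()
                orf = orfs[int(name)]
                for dom in hit.domains:
                    if dom.score < model.bitscore_cutoff:
                        continue
                    start = dom.env_from
                    end = dom.env_to
                    hits_out.append(
                        Domain(
                            orf_id=orf.id,
                            family=model.family,
                            start_aa=start,
                            end_aa=end,
                            score=float(dom.score),
                            substrates=[tuple(s) for s in model.substrates],
                            functional_subtype=model.functional_subtype,
                            annotations=dict(model.annotations),
                            sequence=orf.protein[start - 1 : end],
                        )
                    )
    hits_out = resolve_overlaps(hits_out)
    order = {orf.id: i for i, orf in enumerate(orfs)}
    hits_out.sort(key=lambda d: (order.get(d.orf_id, 0), d.start_aa, d.family))
    return hits_out


def resolve_overlaps(domains: Iterable[Domain]) -> list[Domain]:
    """Among same-family, same-ORF overlapping spans, keep the best score."""
    kept: list[Domain] = []
    for dom in sorted(domains, key=lambda d: -d.score):
        clash = any(
            k.orf_id == dom.orf_id
            and k.family == dom.family
            and not (dom.end_aa < k.start_aa or dom.start_aa > k.end_aa)
            for k in kept
        )
        if not clash:
            kept.append(dom)
    return kept


# ---------------------------------------------------------------------------
# Annotation table backend (primary test interface)
# ---------------------------------------------------------------------------


def _format_substrates(subs) -> str:
    return ";".join(f"{name}:{score:g}" for name, score in subs)


def _parse_substrates(text: str):
    if not text:
        return []
    out = []
    for item in text.split(";"):
        name, _, score = item.rpartition(":")
        out.append((name, float(score)))
    return out


def _format_annotations(ann: dict) -> str:
    parts = []
    for key in sorted(ann):
        value = ann[key]
        if isinstance(value, (list, tuple)):
            value = ",".join(str(v) for v in value)
        parts.append(f"{key}={value}")
    return ";".join(parts)


def _parse_annotations(text: str) -> dict:
    ann: dict = {}
    if not text:
        return ann
    for part in text.split(";"):
        key, _, value = part.partition("=")
        if "," in value:
            ann[key] = value.split(",")
        else:
            try:
                ann[key] = int(value)
            except ValueError:
                ann[key] = value
    return ann


def write_annotation_table(domains: Sequence[Domain], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_TABLE_COLUMNS) + "\n")
        for d in domains:
            fh.write(
                "\t".join(
                    [
                        d.orf_id,
                        d.family,
                        str(d.start_aa),
                        str(d.end_aa),
                        f"{d.score:g}",
                        d.functional_subtype or "",
                        _format_substrates(d.substrates),
                        _format_annotations(d.annotations),
                    ]
                )
                + "\n"
            )


def read_annotation_table(path: str) -> list[Domain]:
    """Parse the tab-separated precomputed annotation table."""
    domains: list[Domain] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != list(ANNOTATION_TABLE_COLUMNS[:5]):
            raise ConfigurationError(f"{path}: not an annotation table")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            cols += [""] * (len(ANNOTATION_TABLE_COLUMNS) - len(cols))
            domains.append(
                Domain(
                    orf_id=cols[0],
                    family=cols[1],
                    start_aa=int(cols[2]),
                    end_aa=int(cols[3]),
                    score=float(cols[4]),
                    functional_subtype=cols[5] or None,
                    substrates=_parse_substrates(cols[6]),
                    annotations=_parse_annotations(cols[7]),
                )
            )
    return domains


# ---------------------------------------------------------------------------
# Alignment refinement
# ---------------------------------------------------------------------------


def refine_by_alignment(
    domain: Domain, reference_db: Sequence[ReferenceRecord]
) -> Domain:
    """Copy the annotation payload of the best-aligning reference onto the
    domain; retain the full ranked reference list for fallback logic.

    Ties on alignment score break to the lexicographically first reference
    id. An empty reference collection logs a warning and returns the domain
    unchanged.
    """
    if domain.family not in REFINED_FAMILIES:
        raise ConfigurationError(
            f"family {domain.family} is not alignment-refined"
        )
    if not reference_db:
        logger.warning(
            "empty reference collection for %s; domain left unannotated",
            domain.family,
        )
        return domain
    aligner = protein_aligner()
    ranked = []
    for ref in reference_db:
        try:
            score = float(aligner.score(domain.sequence, ref.sequence))
        except (ValueError, IndexError):
            score = 0.0
        ranked.append((score, ref.id, ref))
    ranked.sort(key=lambda t: (-t[0], t[1]))
    best = ranked[0][2]
    new = replace(domain)
    new.annotations = dict(domain.annotations)
    new.annotations.update(best.payload)
    new.annotations["ranked_refs"] = [
        (ref.id, score, dict(ref.payload)) for score, _id, ref in ranked
    ]
    if "functional_subtype" in best.payload:
        new.functional_subtype = best.payload["functional_subtype"]
    if "substrate" in best.payload:
        new.substrates = [(best.payload["substrate"], ranked[0][0])]
    return new


# ---------------------------------------------------------------------------
# Substrate prediction
# ---------------------------------------------------------------------------


@dataclass
class SubstrateProfileLibrary:
    """Substrate-specific profiles grouped by the family they apply to.

    ``profiles[family]`` maps substrate name -> pyhmmer HMM. Acyl-adenylating
    domains are scored only against the acyl-adenylating profile set, never
    the amino-acid set (and vice versa).
    """

    profiles: dict

    def for_family(self, family: str) -> dict:
        return self.profiles.get(family, {})


def predict_substrates(
    domain: Domain, library: SubstrateProfileLibrary
) -> list[tuple[str, float]]:
    """Rank a substrate-activating domain's putative monomers.

    Returns ``(substrate, score)`` pairs, descending score, alphabetical on
    ties; the top entry is the point prediction.
    """
    import pyhmmer

    if domain.family not in SUBSTRATE_PREDICTED_FAMILIES:
        raise ConfigurationError(
            f"family {domain.family} has no substrate profiles"
        )
    profiles = library.for_family(domain.family)
    if not profiles:
        raise ConfigurationError(
            f"no substrate profiles registered for family {domain.family}"
        )
    alphabet = pyhmmer.easel.Alphabet.amino()
    seq = pyhmmer.easel.TextSequence(
        name=b"query", sequence=domain.sequence
    ).digitize(alphabet)
    scored = []
    for name in sorted(profiles):
        hmm = profiles[name]
        best = 0.0
        for tophits in pyhmmer.hmmsearch([hmm], [seq], T=0.0, domT=0.0):
            for hit in tophits:
                best = max(best, float(hit.score))
        if best > 0.0:
            scored.append((name, best))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def apply_prerequisite_rules(
    domains: Sequence[Domain], cluster_families: set[str]
) -> list[Domain]:
    """Demote gated rare substrates whose prerequisite domains are absent.

    A gated substrate is moved below the next-ranked ungated substrate; it is
    never removed from the ranked list. Substrate score values are untouched
    (rank order is the prediction).
    """
    out = []
    for domain in domains:
        subs = list(domain.substrates)
        reordered: list = []
        deferred: list = []
        for sub in subs:
            prereq = SUBSTRATE_PREREQUISITES.get(sub[0])
            if prereq is not None and not prereq <= cluster_families:
                deferred.append(sub)
            else:
                reordered.append(sub)
                reordered.extend(deferred)
                deferred = []
        reordered.extend(deferred)
        if reordered != subs:
            domain = replace(domain, substrates=reordered)
        out.append(domain)
    return out
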