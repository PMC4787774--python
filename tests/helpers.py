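"""Factories for hand-built ORFs, domains, and clusters used across tests."""

from __future__ import annotations

from bgcforge.annotate import Domain
from bgcforge.cluster import Cluster, classify_and_filter
from bgcforge.seqio import Orf

PROTEIN = "M" + "ADEKLNQRSTVWY" * 60  # generic long protein


def make_orf(
    orf_id: str,
    start: int = 1,
    length_nt: int = 2400,
    strand: str = "+",
    frame: int = 1,
    contig_id: str = "ctg1",
    protein: str | None = None,
) -> Orf:
    prot = protein if protein is not None else PROTEIN[: length_nt // 3 - 1]
    return Orf(
        id=orf_id,
        contig_id=contig_id,
        start=start,
        end=start + length_nt - 1,
        strand=strand,
        frame=frame,
        protein=prot,
    )


def make_domain(
    orf_id: str,
    family: str,
    start_aa: int = 1,
    end_aa: int = 60,
    score: float = 50.0,
    **kwargs,
) -> Domain:
    return Domain(
        orf_id=orf_id,
        family=family,
        start_aa=start_aa,
        end_aa=end_aa,
        score=score,
        **kwargs,
    )


def make_cluster(
    orf_families: list,
    gap: int = 1000,
    classify: bool = True,
    frames=None,
) -> Cluster:
    """Cluster with one ORF per entry; each entry is a list of either family
    names or prebuilt Domain objects (orf_id filled in)."""
    orfs = []
    domains = []
    pos = 1
    for i, fams in enumerate(orf_families):
        oid = f"orf{i + 1}"
        strand, frame = ("+", 1)
        if frames is not None:
            strand, frame = frames[i]
        length = 90 + 210 * max(1, len(fams))
        orf = make_orf(oid, start=pos, length_nt=length * 3, strand=strand,
                       frame=frame)
        orfs.append(orf)
        pos += length * 3 + gap
        aa = 5
        for item in fams:
            if isinstance(item, Domain):
                item.orf_id = oid
                if item.start_aa == 1 and item.end_aa == 60:
                    item.start_aa, item.end_aa = aa, aa + 59
                domains.append(item)
            else:
                domains.append(make_domain(oid, item, start_aa=aa, end_aa=aa + 59))
            aa += 70
    cluster = Cluster(
        id="test_cluster", contig_id="ctg1", orfs=orfs, domains=domains
    )
    return classify_and_filter(cluster) if classify else cluster
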