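"""Greedy-window cluster identification and family retention rules.

Clusters are seeded on bond-forming domains (condensation / ketosynthase
types) and expanded iteratively: any ORF carrying detected domains within
``window`` base pairs (default 20 kb) of the current cluster boundary joins
the cluster, and iteration stops once no bond-forming domain lies within the
window of either end. Resistance-family ORFs inside the window are attached
but never extend the boundary. Clusters never span contigs.

Retention rules per family:

* thiotemplated (NRPS / type I PKS / hybrid): at least one
  substrate-activating (A, AL, AT) domain and one bond-forming (C, KS)
  domain;
* type II PKS: both a ketosynthase alpha and a chain length factor;
* enediyne: a C-terminal phosphopantetheinyl transferase and a 9- or
  10-membered enediyne ketosynthase;
* fungal iterative type I: a product template domain and a ketosynthase
  (identified, but no structure is predicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from bgcforge.annotate import Domain
from bgcforge.families import (
    is_bond_forming,
    is_resistance_family,
)
from bgcforge.seqio import Orf

DEFAULT_WINDOW_BP = 20000

#: Bond-forming families satisfying the thiotemplated retention rule.
_THIO_BOND = {"condensation", "ketosynthase"}
#: Substrate-activating families satisfying the thiotemplated retention rule.
_THIO_ACTIVATING = {"adenylation", "acyl_adenylating", "acyltransferase"}


@dataclass
class Cluster:
    id: str
    contig_id: str
    orfs: list[Orf]
    domains: list[Domain]
    families: set = field(default_factory=set)
    retained: bool = False
    structure_capable: bool = False
    window: int = DEFAULT_WINDOW_BP

    @property
    def orf_ids(self) -> list[str]:
        return [o.id for o in self.orfs]

    @property
    def domain_families(self) -> set:
        return {d.family for d in self.domains}

    @property
    def start(self) -> int:
        return min(o.start for o in self.orfs)

    @property
    def end(self) -> int:
        return max(o.end for o in self.orfs)

    def domains_on(self, orf_id: str) -> list[Domain]:
        return sorted(
            (d for d in self.domains if d.orf_id == orf_id),
            key=lambda d: d.start_aa,
        )

    def domains_of_family(self, *families: str) -> list[Domain]:
        return [d for d in self.domains if d.family in families]


def _orf_distance(a: Orf, b: Orf) -> int:
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0


def build_clusters(
    domains: Sequence[Domain],
    orfs: Sequence[Orf],
    window: int = DEFAULT_WINDOW_BP,
) -> list[Cluster]:
    """Group domain-bearing ORFs into clusters with the greedy window rule."""
    by_orf: dict[str, list[Domain]] = {}
    for d in domains:
        by_orf.setdefault(d.orf_id, []).append(d)
    orf_by_id = {o.id: o for o in orfs}
    bearing = [orf_by_id[i] for i in orf_by_id if i in by_orf]
    bearing.sort(key=lambda o: (o.contig_id, o.start, o.end))

    def has_bond(orf: Orf) -> bool:
        return any(is_bond_forming(d.family) for d in by_orf[orf.id])

    def resistance_only(orf: Orf) -> bool:
        return all(is_resistance_family(d.family) for d in by_orf[orf.id])

    visited: set[str] = set()
    clusters: list[Cluster] = []
    for seed in bearing:
        if seed.id in visited or not has_bond(seed):
            continue
        members = {seed.id}
        while True:
            core = [
                orf_by_id[i] for i in members if not resistance_only(orf_by_id[i])
            ]
            if not core:
                break
            lo = min(o.start for o in core)
            hi = max(o.end for o in core)
            in_window = [
                o
                for o in bearing
                if o.id not in members
                and o.contig_id == seed.contig_id
                and not (o.end < lo - window or o.start > hi + window)
            ]
            extenders = [o for o in in_window if has_bond(o)]
            if extenders:
                members.update(o.id for o in in_window)
            else:
                # attach remaining non-extending ORFs (incl. resistance)
                members.update(o.id for o in in_window)
                break
        member_orfs = sorted(
            (orf_by_id[i] for i in members), key=lambda o: (o.start, o.end)
        )
        member_domains = [d for o in member_orfs for d in by_orf[o.id]]
        visited.update(members)
        clusters.append(
            Cluster(
                id=f"cluster{len(clusters) + 1}",
                contig_id=seed.contig_id,
                orfs=member_orfs,
                domains=member_domains,
                window=window,
            )
        )
    return clusters


def _is_c_terminal_pptase(domain: Domain, orf: Optional[Orf]) -> bool:
    if domain.family != "PPTase":
        return False
    if orf is None or not orf.protein:
        return True
    return domain.end_aa >= 0.8 * len(orf.protein)


def classify_and_filter(cluster: Cluster) -> Cluster:
    """Assign biosynthetic family labels and apply the retention rules."""
    fams = cluster.domain_families
    orf_by_id = {o.id: o for o in cluster.orfs}
    families: set = set()
    structure_capable = False

    if fams & _THIO_BOND and fams & _THIO_ACTIVATING:
        families.add("thiotemplated")
        structure_capable = True
    if "KS_alpha" in fams and "chain_length_factor" in fams:
        families.add("type2_pks")
        structure_capable = True
    has_ct_pptase = any(
        _is_c_terminal_pptase(d, orf_by_id.get(d.orf_id)) for d in cluster.domains
    )
    has_enediyne_ks = any(
        d.family == "enediyne_KS"
        and d.annotations.get("ring_class") in (9, 10, "9", "10")
        for d in cluster.domains
    )
    if has_ct_pptase and has_enediyne_ks:
        families.add("enediyne")
    if "product_template" in fams and "ketosynthase" in fams:
        families.add("fungal_iterative_t1")
    if any(is_resistance_family(f) for f in fams):
        families.add("resistance_flagged")

    cluster.families = families
    cluster.retained = bool(families - {"resistance_flagged"})
    cluster.structure_capable = structure_capable
    return cluster


def export_bed(clusters: Sequence[Cluster]) -> str:
    """BED-like TSV summary (contig, start, end, id, families, retained)."""
    lines = []
    for c in clusters:
        fams = ",".join(sorted(c.families)) or "."
        lines.append(
            f"{c.contig_id}\t{c.start - 1}\t{c.end}\t{c.id}\t{fams}\t"
            f"{'retained' if c.retained else 'discarded'}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
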