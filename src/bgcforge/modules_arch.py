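"""Biosynthetic module architecture inference.

A module is an enzymatic domain or set of domains responsible for the
addition of a single monomer to the growing scaffold. Ten module types are
recognized; canonical elongation modules are C-(A|AL)-T for NRPS and
KS-AT-T for PKS, with tailoring domains (reductive loop, methyltransferases)
captured inside the span. Non-canonical assembly lines are handled by
constructing artificial ORFs: trans-AT insertion modules split across
consecutive ORFs are joined recursively, and trans-adenylation modules are
spliced into condensation-thiolation insertion didomains in all
permutation/combination variants. Biosynthetically plausible ORF orderings
are enumerated under initiation/termination constraints, with seeded
pseudorandom sampling of 500 orderings once the count reaches 7!.
"""

from __future__ import annotations

import itertools
import logging
import math
import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from bgcforge.annotate import Domain
from bgcforge.cluster import Cluster
from bgcforge.seqio import Orf

logger = logging.getLogger(__name__)

PERMUTATION_CAP_THRESHOLD = math.factorial(7)  # 5040
PERMUTATION_SAMPLE_SIZE = 500
DEFAULT_PERMUTATION_SEED = 0

MODULE_TYPES = (
    "adenylation",
    "trans_a",
    "trans_a_insertion",
    "initiating_adenylation",
    "acyltransferase",
    "trans_at_insertion",
    "starter_condensation",
    "acyl_adenylating_ligase",
    "prolyl_AMP_ligase",
    "type2_unit",
)

_BOUNDARY_START = {"condensation", "ketosynthase", "adenylation", "acyl_adenylating"}
_CARRIER = {"thiolation", "thioesterase"}
_ACTIVATING = {"adenylation", "acyl_adenylating"}


@dataclass
class BioModule:
    """One monomer-adding unit of the assembly line."""

    type: str
    domains: list
    orf_ids: list
    active: bool = True
    substrate: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def families(self) -> list[str]:
        return [d.family for d in self.domains]

    def has_family(self, family: str) -> bool:
        return any(d.family == family for d in self.domains)

    @property
    def reductive_loop(self) -> frozenset:
        return frozenset(
            f
            for f in ("ketoreductase", "dehydratase", "enoylreductase")
            if self.has_family(f)
        )

    @property
    def is_heterocyclization(self) -> bool:
        return any(
            d.family == "condensation"
            and d.functional_subtype == "heterocyclization"
            for d in self.domains
        )

    @property
    def ends_with_te(self) -> bool:
        return bool(self.domains) and self.domains[-1].family == "thioesterase"

    @property
    def initiates(self) -> bool:
        if self.type in (
            "starter_condensation",
            "acyl_adenylating_ligase",
            "prolyl_AMP_ligase",
            "initiating_adenylation",
        ):
            return True
        return any(
            d.family == "ketosynthase"
            and d.functional_subtype == "decarboxylative_KS"
            for d in self.domains
        )


@dataclass
class ModularOrf:
    """An ORF (or artificial ORF) with its ordered modules.

    Artificial ORFs carry more than one entry in ``source_orf_ids``; module
    order preserves source-domain order within each source ORF.
    """

    id: str
    source_orf_ids: list
    modules: list
    frame_key: tuple = ("+", 0)
    genomic_start: int = 0

    @property
    def terminates(self) -> bool:
        return bool(self.modules) and any(m.ends_with_te for m in self.modules)

    @property
    def initiates(self) -> bool:
        return any(m.initiates for m in self.modules)


def _substrate_of(domain: Domain) -> Optional[str]:
    return domain.top_substrate


def _scan_orf(orf: Orf, doms: list[Domain]) -> tuple[list[BioModule], list[Domain]]:
    """Identify modules on one ORF; also return candidate trans-acting ATs.

    A parent ORF whose domain count equals its acyltransferase count marks
    every AT on it as a candidate trans-acting acyltransferase.
    """
    modules: list[BioModule] = []
    trans_ats: list[Domain] = []
    if doms and all(d.family == "acyltransferase" for d in doms):
        return [], list(doms)

    n = len(doms)
    i = 0
    # an ORF starting with a carrier segment (e.g. KR-T) before any
    # bond-forming domain is the downstream half of a split trans-AT module
    first_boundary = next(
        (k for k, d in enumerate(doms) if d.family in _BOUNDARY_START), n
    )
    lead_t = next(
        (
            k
            for k, d in enumerate(doms[:first_boundary])
            if d.family == "thiolation"
        ),
        None,
    )
    if lead_t is not None:
        modules.append(
            BioModule(
                type="trans_at_insertion",
                domains=doms[: lead_t + 1],
                orf_ids=[orf.id],
                active=False,
                extras={"carrier_fragment": True},
            )
        )
        i = lead_t + 1
    while i < n:
        d = doms[i]
        fam = d.family
        if fam == "condensation":
            if d.functional_subtype == "starter_condensation":
                modules.append(
                    BioModule(
                        type="starter_condensation",
                        domains=[d],
                        orf_ids=[orf.id],
                        active=True,
                        substrate=d.annotations.get("substrate")
                        or _substrate_of(d),
                    )
                )
            j = i + 1
            while j < n and doms[j].family not in _CARRIER | {"condensation"}:
                j += 1
            if j < n and doms[j].family in _CARRIER:
                span = doms[i : j + 1]
                activating = [x for x in span if x.family in _ACTIVATING]
                if activating:
                    modules.append(
                        BioModule(
                            type="adenylation",
                            domains=span,
                            orf_ids=[orf.id],
                            substrate=_substrate_of(activating[0]),
                        )
                    )
                else:
                    modules.append(
                        BioModule(
                            type="trans_a_insertion",
                            domains=span,
                            orf_ids=[orf.id],
                            active=False,
                        )
                    )
                i = j + 1
                continue
            # no carrier: ORF-terminal C-A didomain is biosynthetically active
            span = doms[i:]
            activating = [x for x in span if x.family in _ACTIVATING]
            if activating and span[-1].family in _ACTIVATING:
                modules.append(
                    BioModule(
                        type="adenylation",
                        domains=span,
                        orf_ids=[orf.id],
                        substrate=_substrate_of(activating[0]),
                        extras={"orf_terminal_ca": True},
                    )
                )
            i = n
            continue
        if fam == "ketosynthase":
            j = i + 1
            while j < n and doms[j].family not in _CARRIER | {
                "ketosynthase",
                "condensation",
            }:
                j += 1
            if j < n and doms[j].family in _CARRIER:
                span = doms[i : j + 1]
                if any(x.family == "acyltransferase" for x in span):
                    at = next(
                        x for x in span if x.family == "acyltransferase"
                    )
                    modules.append(
                        BioModule(
                            type="acyltransferase",
                            domains=span,
                            orf_ids=[orf.id],
                            substrate=_substrate_of(at) or "malonate",
                        )
                    )
                else:
                    modules.append(
                        BioModule(
                            type="trans_at_insertion",
                            domains=span,
                            orf_ids=[orf.id],
                            substrate="malonate",
                        )
                    )
                i = j + 1
                continue
            # KS without carrier on this ORF: potentially split across ORFs
            modules.append(
                BioModule(
                    type="trans_at_insertion",
                    domains=doms[i:],
                    orf_ids=[orf.id],
                    substrate="malonate",
                    extras={"incomplete": True},
                )
            )
            i = n
            continue
        if fam in _ACTIVATING and i == 0:
            j = i + 1
            while j < n and doms[j].family != "thiolation":
                if doms[j].family in _BOUNDARY_START:
                    break
                j += 1
            if j < n and doms[j].family == "thiolation":
                span = doms[i : j + 1]
                mtype = "trans_a"
                modules.append(
                    BioModule(
                        type=mtype,
                        domains=span,
                        orf_ids=[orf.id],
                        substrate=_substrate_of(d),
                        extras={"didomain": True},
                    )
                )
                i = j + 1
                continue
            if n == 1 and fam == "adenylation":
                modules.append(
                    BioModule(
                        type="adenylation",
                        domains=[d],
                        orf_ids=[orf.id],
                        active=False,
                        substrate=_substrate_of(d),
                        extras={"lone_a": True},
                    )
                )
                i = n
                continue
            if fam == "acyl_adenylating":
                # free-standing acyl-adenylating ligase: active starter module
                modules.append(
                    BioModule(
                        type="acyl_adenylating_ligase",
                        domains=[d],
                        orf_ids=[orf.id],
                        active=True,
                        substrate=_substrate_of(d),
                    )
                )
                i += 1
                continue
            i += 1
            continue
        if fam == "prolyl_AMP_ligase":
            modules.append(
                BioModule(
                    type="prolyl_AMP_ligase",
                    domains=[d],
                    orf_ids=[orf.id],
                    active=True,
                    substrate="proline",
                )
            )
            i += 1
            continue
        i += 1
    return modules, trans_ats


def identify_modules(cluster: Cluster) -> list[BioModule]:
    """Emit modules of all ten types for a retained cluster.

    Order follows (genomic ORF order, domain order). For a type II PKS
    cluster a single ``type2_unit`` module is emitted for the minimal PKS.
    """
    modules: list[BioModule] = []
    for orf in cluster.orfs:
        doms = cluster.domains_on(orf.id)
        if not doms:
            continue
        orf_modules, trans_ats = _scan_orf(orf, doms)
        for at in trans_ats:
            at.annotations["trans_at_candidate"] = True
        modules.extend(orf_modules)
    if "type2_pks" in cluster.families:
        ks = cluster.domains_of_family("KS_alpha")
        clf = cluster.domains_of_family("chain_length_factor")
        if ks and clf:
            modules.append(
                BioModule(
                    type="type2_unit",
                    domains=ks + clf,
                    orf_ids=sorted({d.orf_id for d in ks + clf}),
                    active=True,
                    substrate="malonate",
                )
            )
    return modules


def assign_adenylation_activity(
    cluster: Cluster, modules: Sequence[BioModule]
) -> list[BioModule]:
    """Apply the extra-modular adenylation activity rules.

    Lone adenylation domains on their own ORF are inactive; A-T didomains
    are active; A-T didomains on their own ORF act in trans when the cluster
    also holds a C-T didomain (otherwise they initiate); ORF-terminal C-A
    didomains are active. When more than one acyl-adenylating module exists,
    exactly one initiates per permutation and the rest act as tailoring-style
    acyl transfers.
    """
    has_ct_didomain = any(m.type == "trans_a_insertion" for m in modules)
    out: list[BioModule] = []
    for m in modules:
        m = replace(m, extras=dict(m.extras), domains=list(m.domains))
        if m.extras.get("lone_a"):
            m.active = False
        elif m.type == "trans_a" and m.extras.get("didomain"):
            m.active = True
            if not has_ct_didomain:
                m.type = "initiating_adenylation"
        elif m.extras.get("orf_terminal_ca"):
            m.active = True
        out.append(m)
    al_modules = [m for m in out if m.type == "acyl_adenylating_ligase"]
    if len(al_modules) > 1:
        for m in al_modules:
            m.extras["initiator_pool"] = True
    return out


# ---------------------------------------------------------------------------
# Modular ORF construction (incl. trans-AT artificial ORFs)
# ---------------------------------------------------------------------------


def build_modular_orfs(
    cluster: Cluster, modules: Sequence[BioModule]
) -> list[ModularOrf]:
    """Wrap module-bearing ORFs as :class:`ModularOrf` in genomic order."""
    by_orf: dict[str, list[BioModule]] = {}
    for m in modules:
        by_orf.setdefault(m.orf_ids[0], []).append(m)
    out = []
    for orf in cluster.orfs:
        if orf.id in by_orf:
            out.append(
                ModularOrf(
                    id=orf.id,
                    source_orf_ids=[orf.id],
                    modules=by_orf[orf.id],
                    frame_key=orf.frame_key,
                    genomic_start=orf.start,
                )
            )
    return out


def build_trans_at_orfs(orfs: Sequence[ModularOrf]) -> list[ModularOrf]:
    """Join trans-AT insertion modules split across consecutive ORFs.

    A module whose ketosynthase ends one ORF and whose thiolation starts the
    next is merged into a single artificial ORF; joining recurses until no
    split module remains. Module count is conserved. Unresolvable splits are
    skipped with a warning.
    """
    orfs = list(orfs)
    merged = True
    while merged:
        merged = False
        for i, orf in enumerate(orfs):
            if not orf.modules:
                continue
            last = orf.modules[-1]
            if not last.extras.get("incomplete"):
                continue
            if i + 1 >= len(orfs):
                logger.warning(
                    "split trans-AT module on %s has no partner ORF; skipped",
                    orf.id,
                )
                last.extras["unresolvable"] = True
                last.extras.pop("incomplete", None)
                continue
            partner = orfs[i + 1]
            # the partner's leading carrier fragment completes the module
            if partner.modules and partner.modules[0].extras.get(
                "carrier_fragment"
            ):
                head = partner.modules[0]
                joined = BioModule(
                    type="trans_at_insertion",
                    domains=list(last.domains) + list(head.domains),
                    orf_ids=list(last.orf_ids) + list(head.orf_ids),
                    substrate="malonate",
                )
                new_modules = (
                    orf.modules[:-1] + [joined] + partner.modules[1:]
                )
                artificial = ModularOrf(
                    id=f"{orf.id}+{partner.id}",
                    source_orf_ids=orf.source_orf_ids + partner.source_orf_ids,
                    modules=new_modules,
                    frame_key=orf.frame_key,
                    genomic_start=orf.genomic_start,
                )
                orfs[i : i + 2] = [artificial]
                merged = True
                break
            logger.warning(
                "split trans-AT module on %s: partner %s does not start with "
                "a carrier segment; skipped",
                orf.id,
                partner.id,
            )
            last.extras["unresolvable"] = True
            last.extras.pop("incomplete", None)
    return orfs


def insert_trans_a_modules(orfs: Sequence[ModularOrf]) -> list[list[ModularOrf]]:
    """Enumerate trans-adenylation insertion variants.

    For each permutation of trans-A modules and each assignment of those
    modules to condensation-thiolation insertion sites, a copy of the
    insertion ORF with the trans-A module spliced immediately after the
    insertion module's condensation domain is produced. Returns one ORF-list
    variant per distinct assignment (deduplicated); when there is nothing to
    insert, the input is returned as the single variant.
    """
    trans_a = [
        (oi, mi)
        for oi, orf in enumerate(orfs)
        for mi, m in enumerate(orf.modules)
        if m.type == "trans_a" and m.active
    ]
    sites = [
        (oi, mi)
        for oi, orf in enumerate(orfs)
        for mi, m in enumerate(orf.modules)
        if m.type == "trans_a_insertion"
    ]
    if not trans_a or not sites:
        return [list(orfs)]
    k = min(len(trans_a), len(sites))
    seen = set()
    variants: list[list[ModularOrf]] = []
    for perm in itertools.permutations(trans_a):
        for combo in itertools.combinations(sites, k):
            assignment = frozenset(zip(perm[:k], combo))
            if assignment in seen:
                continue
            seen.add(assignment)
            variants.append(_apply_trans_a_assignment(orfs, dict(assignment)))
    return variants


def _apply_trans_a_assignment(
    orfs: Sequence[ModularOrf], assignment: dict
) -> list[ModularOrf]:
    inverse = {site: mod for mod, site in assignment.items()}
    donors = set(assignment.keys())
    out: list[ModularOrf] = []
    for oi, orf in enumerate(orfs):
        new_modules = []
        touched = False
        for mi, m in enumerate(orf.modules):
            key = (oi, mi)
            if key in donors:
                # the donor now acts at its insertion site, not standalone
                inactive = replace(m, extras=dict(m.extras), active=False)
                inactive.extras["spliced_away"] = True
                new_modules.append(inactive)
                touched = True
                continue
            if key in inverse:
                src_oi, src_mi = inverse[key]
                donor = orfs[src_oi].modules[src_mi]
                c_dom = [d for d in m.domains if d.family == "condensation"]
                # the donor supplies the A-T didomain; the insertion module's
                # own carrier is subsumed
                rest = [
                    d
                    for d in m.domains
                    if d.family not in ("condensation", "thiolation")
                ]
                filled = BioModule(
                    type="adenylation",
                    domains=c_dom + list(donor.domains) + rest,
                    orf_ids=sorted(set(m.orf_ids) | set(donor.orf_ids)),
                    active=True,
                    substrate=donor.substrate,
                    extras={"trans_filled": True},
                )
                new_modules.append(filled)
                touched = True
            else:
                new_modules.append(m)
        if touched:
            out.append(
                ModularOrf(
                    id=f"{orf.id}*",
                    source_orf_ids=list(orf.source_orf_ids),
                    modules=new_modules,
                    frame_key=orf.frame_key,
                    genomic_start=orf.genomic_start,
                )
            )
        else:
            out.append(orf)
    return out


# ---------------------------------------------------------------------------
# ORF permutations
# ---------------------------------------------------------------------------


def permutation_is_plausible(perm: Sequence[ModularOrf]) -> bool:
    """Initiation/termination checker, independent of the generator."""
    if not perm:
        return False
    terminators = [o for o in perm if o.terminates]
    initiators = [o for o in perm if o.initiates]
    if terminators and not perm[-1].terminates:
        return False
    if initiators and not perm[0].initiates:
        return False
    return True


def generate_orf_permutations(
    orfs: Sequence[ModularOrf],
    cap_threshold: int = PERMUTATION_CAP_THRESHOLD,
    sample_size: int = PERMUTATION_SAMPLE_SIZE,
    seed: int = DEFAULT_PERMUTATION_SEED,
) -> list[list[ModularOrf]]:
    """Enumerate biosynthetically plausible scaffold-ORF orderings.

    When all scaffold ORFs share one frame and the genomic order satisfies
    the constraints, only that single permutation is returned. Otherwise all
    constraint-satisfying orderings are generated; once their number reaches
    ``cap_threshold`` (7!), a seeded pseudorandom sample of ``sample_size``
    distinct orderings is returned instead.
    """
    scaffold = [o for o in orfs if o.modules]
    if not scaffold:
        return []
    genomic = sorted(scaffold, key=lambda o: o.genomic_start)
    same_frame = len({o.frame_key for o in scaffold}) == 1
    if same_frame and permutation_is_plausible(genomic):
        return [genomic]

    n = len(scaffold)
    count = _count_plausible(scaffold)
    if count == 0:
        logger.warning(
            "contradictory ordering constraints; falling back to genomic order"
        )
        return [genomic]
    if count >= cap_threshold:
        return _sample_permutations(scaffold, sample_size, seed)
    perms = [
        list(p)
        for p in itertools.permutations(scaffold)
        if permutation_is_plausible(p)
    ]
    return perms


def _count_plausible(scaffold: Sequence[ModularOrf]) -> int:
    n = len(scaffold)
    initiators = [o for o in scaffold if o.initiates]
    terminators = [o for o in scaffold if o.terminates]
    firsts = initiators if initiators else list(scaffold)
    lasts = terminators if terminators else list(scaffold)
    if n == 1:
        only = scaffold[0]
        return int(only in firsts and only in lasts)
    total = 0
    for f in firsts:
        for l in lasts:
            if f is l:
                continue
            total += math.factorial(n - 2)
    return total


def _sample_permutations(
    scaffold: Sequence[ModularOrf], sample_size: int, seed: int
) -> list[list[ModularOrf]]:
    rng = random.Random(seed)
    n = len(scaffold)
    initiators = [o for o in scaffold if o.initiates]
    terminators = [o for o in scaffold if o.terminates]
    firsts = initiators if initiators else list(scaffold)
    lasts = terminators if terminators else list(scaffold)
    pairs = [(f, l) for f in firsts for l in lasts if f is not l]
    out: list[list[ModularOrf]] = []
    seen: set = set()
    attempts = 0
    while len(out) < sample_size and attempts < sample_size * 50:
        attempts += 1
        f, l = pairs[rng.randrange(len(pairs))]
        middle = [o for o in scaffold if o is not f and o is not l]
        rng.shuffle(middle)
        perm = [f] + middle + [l]
        key = tuple(o.id for o in perm)
        if key in seen:
            continue
        seen.add(key)
        out.append(perm)
    return out


def active_module_sequence(perm: Sequence[ModularOrf]) -> list[BioModule]:
    """Flatten a permutation into its ordered active modules.

    When several acyl-adenylating ligase modules compete as initiators, only
    the first one in the ordering loads a monomer; the rest act as
    tailoring-style acyl transfers and are excluded from the backbone.
    """
    flat = [m for orf in perm for m in orf.modules]
    seen_initiating_al = False
    out = []
    for m in flat:
        if not m.active:
            continue
        if m.extras.get("initiator_pool"):
            if seen_initiating_al:
                continue
            seen_initiating_al = True
        out.append(m)
    return out
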