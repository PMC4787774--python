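"""Tailoring-reaction library: substrate-site detection, graph-edit
execution, and macrocyclization enumeration.

A :class:`ReactionPlan` is the action of a single tailoring reaction at a
single potential substrate site. Sites reference stable atom uids (or
residue indices), so a site chosen on the base scaffold can be re-validated
at execution time: if an earlier edit consumed it, execution fails cleanly
with no partial edit. Several hydroxyl-directed reactions (glycosylation,
sulfation, carbamoylation, phosphorylation) may act at any free hydroxyl;
chlorinases fall back down their ranked substrate classes until a non-empty
site set is found; glycopeptide P450 cross-links are position-specific per
Oxy clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from bgcforge.annotate import Domain
from bgcforge.chem_scaffold import (
    Scaffold,
    aromatic_alpha_carbons,
    carboxyl_hydroxyl,
)
from bgcforge.refdata import (
    CHLORINASE_CLASSES,
    MonomerRecord,
    TailoringReaction,
)

logger = logging.getLogger(__name__)

#: glycopeptide P450 clade -> (residue position pair, bond kind)
P450_POSITION_RULES = {
    "OxyA": ((2, 4), "ether"),
    "OxyB": ((4, 6), "ether"),
    "OxyC": ((5, 7), "ether"),
    "OxyAB": ((5, 7), "biaryl"),
}

#: ranked chlorinase substrate classes, used when a domain carries none
DEFAULT_CHLORINASE_RANKING = (
    "tyrosine_phenylglycine",
    "tryptophan",
    "histidine",
    "aromatic_starter",
    "threonine",
    "branched_chain",
)


@dataclass
class ReactionPlan:
    reaction: TailoringReaction
    site: tuple
    domain: Optional[Domain] = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# site queries
# ---------------------------------------------------------------------------


def free_hydroxyls(scaffold: Scaffold) -> list[int]:
    """Uids of free sp3 hydroxyl oxygens (not carboxyl, not phenol, not
    already substituted)."""
    out = []
    for atom in scaffold.mol.GetAtoms():
        if atom.GetSymbol() != "O" or atom.GetDegree() != 1:
            continue
        if atom.GetTotalNumHs() < 1:
            continue
        bond = atom.GetBonds()[0]
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetSymbol() != "C" or nbr.GetIsAromatic():
            continue
        if any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(nbr).GetSymbol() == "O"
            for b in nbr.GetBonds()
        ):
            continue  # carboxyl / ester carbonyl
        out.append(scaffold.uid_of(atom))
    return sorted(out)


def _residues_named(scaffold: Scaffold, names) -> list[int]:
    return [r.index for r in scaffold.residues if r.name in names]


def _amino_acid_position(scaffold: Scaffold, position: int) -> Optional[int]:
    """Residue index of the Nth amino-acid residue (1-based)."""
    count = 0
    for r in scaffold.residues:
        if r.monomer_class == "alpha_amino_acid":
            count += 1
            if count == position:
                return r.index
    return None


def _chlorination_sites(
    domain: Optional[Domain], scaffold: Scaffold
) -> list[tuple]:
    """Walk the ranked substrate classes; stop at the first with >= 1 site."""
    ranking: Sequence[str] = DEFAULT_CHLORINASE_RANKING
    if domain is not None:
        ranked = [
            payload.get("substrate_class")
            for _id, _score, payload in domain.annotations.get(
                "ranked_refs", []
            )
            if payload.get("substrate_class")
        ]
        if not ranked and domain.annotations.get("substrate_class"):
            ranked = [domain.annotations["substrate_class"]]
        if ranked:
            ranking = ranked
    for cls in ranking:
        names = CHLORINASE_CLASSES.get(cls, frozenset())
        residues = _residues_named(scaffold, names)
        if residues:
            return [("res_cl", i) for i in residues]
    return []


def find_substrate_sites(
    reaction: TailoringReaction,
    scaffold: Scaffold,
    cluster=None,
    domain: Optional[Domain] = None,
) -> list[tuple]:
    """Potential substrate sites for one tailoring reaction on one scaffold.

    Pure function of (scaffold, cluster, domain); returns site descriptors
    consumable by :func:`execute_reaction`.
    """
    rule = reaction.site_rule
    if rule == "free_hydroxyl":
        return [("O", uid) for uid in free_hydroxyls(scaffold)]
    if rule == "chlorinase_ranked":
        return _chlorination_sites(domain, scaffold)
    if rule == "p450_positions":
        subtype = (domain.functional_subtype if domain else None) or "OxyA"
        entry = P450_POSITION_RULES.get(subtype)
        if entry is None:
            return []
        (pos_a, pos_b), kind = entry
        res_a = _amino_acid_position(scaffold, pos_a)
        res_b = _amino_acid_position(scaffold, pos_b)
        if res_a is None or res_b is None:
            return []
        return [("pair", res_a, res_b, kind)]
    if rule == "cys_val_diresidue":
        out = []
        for r in scaffold.residues[:-1]:
            nxt = scaffold.residues[r.index + 1]
            if r.name == "cysteine" and nxt.name == "valine":
                out.append(("res2", r.index, nxt.index))
        return out
    if rule == "aminoadipate_residue":
        return [("res", i) for i in _residues_named(scaffold, {"2-aminoadipate"})]
    if rule == "penam_core":
        return [("penam",)] if "penam" in scaffold.flags else []
    if rule == "formylation_nitrogens":
        sites = []
        amine = scaffold.n_terminal_amine()
        if amine is not None:
            sites.append(("N", scaffold.uid_of(amine)))
        for i in _residues_named(
            scaffold, {"ornithine", "N-hydroxyornithine"}
        ):
            for atom in scaffold.atoms_of_residue(i):
                if (
                    atom.GetSymbol() == "N"
                    and atom.GetTotalNumHs() >= 1
                    and not (
                        atom.HasProp("role") and atom.GetProp("role") == "head"
                    )
                ):
                    sites.append(("N", scaffold.uid_of(atom)))
        return sites
    if rule == "tryptophan_residue":
        # kynurenine conversion is applied during scaffold elaboration
        return []
    if rule == "terminal_proline":
        if scaffold.residues and scaffold.residues[0].name == "proline":
            return [("res", 0)]
        return []
    if rule == "aromatic_alpha_carbon":
        return [("C", uid) for uid in aromatic_alpha_carbons(scaffold)]
    if rule == "none":
        return []
    logger.warning("unknown site rule %s", rule)
    return []


# ---------------------------------------------------------------------------
# graph-edit execution
# ---------------------------------------------------------------------------


def _free_oh_uid(scaffold: Scaffold, uid: int) -> bool:
    atom = scaffold.atom(uid)
    return (
        atom is not None
        and atom.GetSymbol() == "O"
        and atom.GetDegree() == 1
        and atom.GetTotalNumHs() >= 1
    )


def _chlorinate(scaffold: Scaffold, res_index: int) -> bool:
    atoms = scaffold.atoms_of_residue(res_index)
    aromatic = [
        a
        for a in atoms
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]
    pool = aromatic or [
        a
        for a in atoms
        if a.GetSymbol() == "C"
        and a.GetTotalNumHs() >= 1
        and not (a.HasProp("role") and a.GetProp("role") == "acyl")
    ]
    if not pool:
        return False
    target = min(pool, key=scaffold.uid_of)
    scaffold.add_atom("Cl", scaffold.uid_of(target))
    scaffold.sanitize()
    return True


def _aromatic_ch(scaffold: Scaffold, res_index: int):
    return [
        a
        for a in scaffold.atoms_of_residue(res_index)
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _phenol_oxygen(scaffold: Scaffold, res_index: int):
    for a in scaffold.atoms_of_residue(res_index):
        if (
            a.GetSymbol() == "O"
            and a.GetDegree() == 1
            and a.GetTotalNumHs() >= 1
            and a.GetNeighbors()[0].GetIsAromatic()
        ):
            return a
    return None


def _crosslink(scaffold: Scaffold, res_a: int, res_b: int, kind: str) -> bool:
    if kind == "ether":
        oxygen = _phenol_oxygen(scaffold, res_a)
        partners = _aromatic_ch(scaffold, res_b)
        if oxygen is None or not partners:
            return False
        target = min(partners, key=scaffold.uid_of)
        scaffold.set_bond(
            scaffold.uid_of(oxygen), scaffold.uid_of(target),
            Chem.BondType.SINGLE,
        )
    else:  # biaryl C-C
        a_list = _aromatic_ch(scaffold, res_a)
        b_list = _aromatic_ch(scaffold, res_b)
        if not a_list or not b_list:
            return False
        scaffold.set_bond(
            scaffold.uid_of(min(a_list, key=scaffold.uid_of)),
            scaffold.uid_of(min(b_list, key=scaffold.uid_of)),
            Chem.BondType.SINGLE,
        )
    scaffold.sanitize()
    return True


def _penam(scaffold: Scaffold, cys_index: int, val_index: int) -> bool:
    """Isopenicillin N synthase: bicyclize the Cys-Val diresidue."""
    from bgcforge.chem_scaffold import alpha_carbon

    cys_alpha = alpha_carbon(scaffold, cys_index)
    val_head = scaffold.role_atom(val_index, "head")
    val_alpha = alpha_carbon(scaffold, val_index)
    if cys_alpha is None or val_head is None or val_alpha is None:
        return False
    cys_beta = next(
        (
            n
            for n in cys_alpha.GetNeighbors()
            if n.GetSymbol() == "C"
            and not (n.HasProp("role") and n.GetProp("role") == "acyl")
        ),
        None,
    )
    if cys_beta is None:
        return False
    sulfur = next(
        (n for n in cys_beta.GetNeighbors() if n.GetSymbol() == "S"), None
    )
    val_beta = next(
        (
            n
            for n in val_alpha.GetNeighbors()
            if n.GetSymbol() == "C"
            and not (n.HasProp("role") and n.GetProp("role") == "acyl")
            and n.GetIdx() != val_head.GetIdx()
        ),
        None,
    )
    if sulfur is None or val_beta is None:
        return False
    try:
        scaffold.set_bond(
            scaffold.uid_of(val_head),
            scaffold.uid_of(cys_beta),
            Chem.BondType.SINGLE,
        )
        scaffold.set_bond(
            scaffold.uid_of(sulfur),
            scaffold.uid_of(val_beta),
            Chem.BondType.SINGLE,
        )
        scaffold.sanitize()
    except Exception:
        return False
    scaffold.flags["penam"] = (
        scaffold.uid_of(sulfur),
        scaffold.uid_of(val_beta),
        scaffold.uid_of(val_alpha),
    )
    return True


def _cephem(scaffold: Scaffold) -> bool:
    """Deacetoxycephalosporin C synthase: penam -> cephem ring expansion."""
    if "penam" not in scaffold.flags:
        return False
    s_uid, val_beta_uid, val_alpha_uid = scaffold.flags["penam"]
    sulfur = scaffold.atom(s_uid)
    val_beta = scaffold.atom(val_beta_uid)
    if sulfur is None or val_beta is None:
        return False
    methyl = next(
        (
            n
            for n in val_beta.GetNeighbors()
            if n.GetSymbol() == "C"
            and n.GetDegree() == 1
            and n.GetTotalNumHs() >= 2
        ),
        None,
    )
    if methyl is None:
        return False
    try:
        scaffold.remove_bond(s_uid, val_beta_uid)
        scaffold.set_bond(s_uid, scaffold.uid_of(methyl), Chem.BondType.SINGLE)
        scaffold.set_bond(val_beta_uid, val_alpha_uid, Chem.BondType.DOUBLE)
        scaffold.sanitize()
    except Exception:
        return False
    scaffold.flags.pop("penam")
    scaffold.flags["cephem"] = True
    return True


def _phenylacetyl_exchange(scaffold: Scaffold, res_index: int) -> bool:
    """Isopenicillin N acyltransferase: swap the aminoadipoyl cap for
    phenylacetyl at the matched residue."""
    acyl = scaffold.role_atom(res_index, "acyl")
    if acyl is None:
        return False
    acyl_uid = scaffold.uid_of(acyl)
    keep = {acyl_uid}
    for nbr in acyl.GetNeighbors():
        bond = scaffold.mol.GetBondBetweenAtoms(acyl.GetIdx(), nbr.GetIdx())
        if (
            nbr.GetSymbol() == "O"
            and bond.GetBondType() == Chem.BondType.DOUBLE
        ):
            keep.add(scaffold.uid_of(nbr))
    doomed = [
        scaffold.uid_of(a)
        for a in scaffold.atoms_of_residue(res_index)
        if scaffold.uid_of(a) not in keep
    ]
    try:
        for uid in doomed:
            scaffold.remove_atom(uid)
        scaffold.attach("[CH2:1]c1ccccc1", acyl_uid, res_index=res_index)
        scaffold.sanitize()
    except Exception:
        return False
    return True


def _pyrrole(scaffold: Scaffold, res_index: int) -> bool:
    """Proline dehydrogenase: aromatize a terminal pyrrolidine to pyrrole."""
    from bgcforge.chem_scaffold import alpha_carbon

    nitrogen = scaffold.role_atom(res_index, "head")
    alpha = alpha_carbon(scaffold, res_index)
    if nitrogen is None or alpha is None or nitrogen.GetTotalNumHs() < 1:
        return False
    ring = [
        a
        for a in scaffold.atoms_of_residue(res_index)
        if a.IsInRing() and a.GetSymbol() == "C"
    ]
    if len(ring) != 4:
        return False
    c3 = next(
        (
            n
            for n in alpha.GetNeighbors()
            if n.IsInRing() and n.GetSymbol() == "C"
        ),
        None,
    )
    if c3 is None:
        return False
    c4 = next(
        (
            n
            for n in c3.GetNeighbors()
            if n.IsInRing()
            and n.GetSymbol() == "C"
            and n.GetIdx() != alpha.GetIdx()
        ),
        None,
    )
    c5 = next(
        (
            n
            for n in nitrogen.GetNeighbors()
            if n.IsInRing()
            and n.GetSymbol() == "C"
            and n.GetIdx() != alpha.GetIdx()
        ),
        None,
    )
    if c4 is None or c5 is None:
        return False
    try:
        scaffold.set_bond(
            scaffold.uid_of(alpha), scaffold.uid_of(c3), Chem.BondType.DOUBLE
        )
        scaffold.set_bond(
            scaffold.uid_of(c4), scaffold.uid_of(c5), Chem.BondType.DOUBLE
        )
        scaffold.sanitize()
    except Exception:
        return False
    return True


def attach_sugar(
    scaffold: Scaffold, record: MonomerRecord, site: tuple
) -> Optional[list[int]]:
    """Attach a sugar at a hydroxyl ('O', uid) or aromatic carbon ('C', uid)
    site; returns the new atom uids or None on failure."""
    kind, uid = site[0], site[1]
    if kind == "O":
        if not _free_oh_uid(scaffold, uid):
            return None
    elif kind == "C":
        atom = scaffold.atom(uid)
        if atom is None or not atom.GetIsAromatic() or atom.GetTotalNumHs() < 1:
            return None
    else:
        return None
    try:
        new_uids = scaffold.attach(record.smiles, uid)
        scaffold.sanitize()
        return new_uids
    except Exception:
        return None


_HYDROXYL_EDITS = {
    "glycosylate": None,  # handled via attach_sugar
    "sulfate": "[S:1](=O)(=O)O",
    "carbamoylate": "[C:1](=O)N",
    "phosphorylate": "[P:1](=O)(O)O",
}


def execute_reaction(
    plan: ReactionPlan, scaffold: Scaffold
) -> Optional[Scaffold]:
    """Execute one reaction plan on a copy of the scaffold.

    Returns the edited scaffold with ``reaction_count`` incremented, or
    ``None`` when the site is no longer available or the edit would violate
    valence (no partial edit in either case).
    """
    work = scaffold.copy()
    edit = plan.reaction.graph_edit
    ok = False
    try:
        if edit in _HYDROXYL_EDITS and edit != "glycosylate":
            uid = plan.site[1]
            if _free_oh_uid(work, uid):
                work.attach(_HYDROXYL_EDITS[edit], uid)
                work.sanitize()
                ok = True
        elif edit == "glycosylate" or edit == "c_glycosylate":
            record = plan.extras.get("sugar")
            if record is not None:
                ok = attach_sugar(work, record, plan.site) is not None
        elif edit == "chlorinate":
            ok = _chlorinate(work, plan.site[1])
        elif edit == "crosslink":
            ok = _crosslink(work, plan.site[1], plan.site[2], plan.site[3])
        elif edit == "penam":
            ok = _penam(work, plan.site[1], plan.site[2])
        elif edit == "cephem":
            ok = _cephem(work)
        elif edit == "phenylacetyl_exchange":
            ok = _phenylacetyl_exchange(work, plan.site[1])
        elif edit == "formylate":
            atom = work.atom(plan.site[1])
            if atom is not None and atom.GetTotalNumHs() >= 1:
                c_uid = work.add_atom("C", plan.site[1])
                o_uid = work.add_atom("O", c_uid, Chem.BondType.DOUBLE)
                work.sanitize()
                ok = True
        elif edit == "pyrrole":
            ok = _pyrrole(work, plan.site[1])
        elif edit == "kynurenine":
            ok = False  # applied during elaboration, never as a plan
    except Exception:
        return None
    if not ok or not work.is_valid():
        return None
    work.reaction_count += 1
    return work


# ---------------------------------------------------------------------------
# macrocyclization
# ---------------------------------------------------------------------------


def enumerate_macrocyclizations(scaffold: Scaffold, cluster=None) -> list[tuple]:
    """All release patterns for a linear scaffold.

    One macrolactone per eligible hydroxyl nucleophile and one macrolactam
    per eligible amine, plus the linear free acid; a cluster with a
    C-terminal reductase domain instead releases exactly the linear aldehyde
    and the cyclic imine.
    """
    has_terminal_reductase = cluster is not None and any(
        d.family == "reductase_terminal" for d in cluster.domains
    )
    if has_terminal_reductase:
        return [("linear_aldehyde",), ("cyclic_imine",)]
    if cluster is not None and "type2_pks" in getattr(cluster, "families", ()):
        # type II chains are cyclized by dedicated cyclases, not released
        # through thioesterase-style macrocyclization
        return [("linear",)]
    patterns: list[tuple] = []
    acyl = scaffold.terminal_acyl()
    for uid in free_hydroxyls(scaffold):
        if _macrocycle_size_ok(scaffold, acyl, uid):
            patterns.append(("macrolactone", uid))
    amine = scaffold.n_terminal_amine()
    if amine is not None and _macrocycle_size_ok(
        scaffold, acyl, scaffold.uid_of(amine)
    ):
        patterns.append(("macrolactam", scaffold.uid_of(amine)))
    patterns.append(("linear",))
    return patterns


MIN_MACROCYCLE_ATOMS = 5


def _macrocycle_size_ok(scaffold: Scaffold, acyl, nucleophile_uid: int) -> bool:
    if acyl is None:
        return False
    atom = scaffold.atom(nucleophile_uid)
    if atom is None:
        return False
    path = Chem.GetShortestPath(
        scaffold.mol, acyl.GetIdx(), atom.GetIdx()
    )
    return len(path) >= MIN_MACROCYCLE_ATOMS


def execute_cyclization(
    pattern: tuple, scaffold: Scaffold
) -> Optional[Scaffold]:
    """Apply one release pattern; None on failure (site consumed etc.)."""
    work = scaffold.copy()
    kind = pattern[0]
    if kind == "linear":
        return work
    acyl = work.terminal_acyl()
    if acyl is None:
        return None
    acyl_uid = work.uid_of(acyl)
    try:
        if kind == "macrolactone":
            uid = pattern[1]
            if not _free_oh_uid(work, uid):
                return None
            oh = carboxyl_hydroxyl(acyl)
            if oh is None:
                return None
            work.remove_atom(work.uid_of(oh))
            work.set_bond(acyl_uid, uid, Chem.BondType.SINGLE)
        elif kind == "macrolactam":
            uid = pattern[1]
            atom = work.atom(uid)
            if atom is None or atom.GetSymbol() != "N" or atom.GetTotalNumHs() < 1:
                return None
            oh = carboxyl_hydroxyl(acyl)
            if oh is None:
                return None
            work.remove_atom(work.uid_of(oh))
            work.set_bond(acyl_uid, uid, Chem.BondType.SINGLE)
        elif kind == "linear_aldehyde":
            oh = carboxyl_hydroxyl(acyl)
            if oh is None:
                return None
            work.remove_atom(work.uid_of(oh))
        elif kind == "cyclic_imine":
            amine = work.n_terminal_amine()
            if amine is None:
                return None
            oh = carboxyl_hydroxyl(acyl)
            if oh is None:
                return None
            keto = next(
                (
                    n
                    for n in acyl.GetNeighbors()
                    if n.GetSymbol() == "O"
                    and work.mol.GetBondBetweenAtoms(
                        acyl.GetIdx(), n.GetIdx()
                    ).GetBondType()
                    == Chem.BondType.DOUBLE
                ),
                None,
            )
            if keto is None:
                return None
            amine_uid = work.uid_of(amine)
            work.remove_atom(work.uid_of(oh))
            work.remove_atom(work.uid_of(keto))
            work.set_bond(acyl_uid, amine_uid, Chem.BondType.DOUBLE)
        else:
            return None
        work.sanitize()
    except Exception:
        return None
    if not work.is_valid():
        return None
    return work
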