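"""Linear NRP/PK scaffold assembly and type II polyketide backbones.

Scaffolds are RDKit molecular graphs. Every atom carries three integer/string
properties that survive graph edits: ``uid`` (a stable handle used by
reaction plans), ``res`` (the residue index it came from) and optionally
``role`` (``head`` — the amine nitrogen, ester oxygen, ketide alpha carbon
or anomeric carbon; ``acyl`` — the tail carboxyl carbon). Residues are
condensed head-to-tail: amide bonds for amino-acid modules, ester bonds for
hydroxy-acid modules, carbon-carbon ketide bonds for acyltransferase modules
(beta-keto by default, with the reductive loop setting the oxidation state).
Module-local tailoring (reductive loop, N/C/O-methylation,
heterocyclization) is applied during elaboration, before inter-residue
chemistry is finalized. Stereochemistry is not predicted; all output SMILES
are achiral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import RWMol

from bgcforge.errors import BgcforgeError, MonomerLibraryError
from bgcforge.modules_arch import BioModule
from bgcforge.refdata import (
    CYCLASE_RING_PATTERNS,
    TYPE2_CMT_CARBON,
    TYPE2_KR_CARBON,
    TYPE2_STARTER_GATES,
    TYPE2_STARTERS,
    MonomerLibrary,
    MonomerRecord,
)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")


class ScaffoldError(BgcforgeError):
    """Scaffold construction failed (degenerate input or invalid chemistry)."""


@dataclass
class Residue:
    index: int
    name: str
    monomer_class: str
    module: Optional[BioModule] = None


class Scaffold:
    """A growing molecular graph with residue provenance and stable atom uids."""

    def __init__(self):
        self.mol = RWMol()
        self.reaction_count = 0
        self.residues: list[Residue] = []
        self.flags: dict = {}
        self._next_uid = 0

    # -- atom bookkeeping ---------------------------------------------------

    def idx(self, uid: int) -> Optional[int]:
        for atom in self.mol.GetAtoms():
            if atom.HasProp("uid") and atom.GetIntProp("uid") == uid:
                return atom.GetIdx()
        return None

    def atom(self, uid: int):
        i = self.idx(uid)
        return None if i is None else self.mol.GetAtomWithIdx(i)

    def uid_of(self, atom) -> int:
        return atom.GetIntProp("uid")

    def atoms_of_residue(self, res_index: int) -> list:
        return [
            a
            for a in self.mol.GetAtoms()
            if a.HasProp("res") and a.GetIntProp("res") == res_index
        ]

    def role_atom(self, res_index: int, role: str):
        for a in self.atoms_of_residue(res_index):
            if a.HasProp("role") and a.GetProp("role") == role:
                return a
        return None

    @property
    def residue_map(self) -> dict:
        out: dict[int, list[int]] = {}
        for a in self.mol.GetAtoms():
            if a.HasProp("res"):
                out.setdefault(a.GetIntProp("res"), []).append(
                    a.GetIntProp("uid")
                )
        return out

    # -- construction -------------------------------------------------------

    def _tag_fragment(self, mol, offset: int, res_index: int, head, tail):
        for atom in mol.GetAtoms():
            if atom.GetIdx() < offset:
                continue
            atom.SetIntProp("uid", self._next_uid)
            atom.SetIntProp("res", res_index)
            self._next_uid += 1
        if head is not None:
            mol.GetAtomWithIdx(offset + head).SetProp("role", "head")
        if tail is not None:
            mol.GetAtomWithIdx(offset + tail).SetProp("role", "acyl")

    def add_residue(
        self, record: MonomerRecord, module: Optional[BioModule] = None
    ) -> Residue:
        """Append a monomer, condensing it onto the current tail."""
        frag, head, tail = parse_monomer(record)
        res_index = len(self.residues)
        offset = self.mol.GetNumAtoms()
        combined = RWMol(Chem.CombineMols(self.mol, frag))
        self._tag_fragment(combined, offset, res_index, head, tail)
        self.mol = combined
        if self.residues:
            if head is None:
                raise ScaffoldError(
                    f"monomer {record.name} has no head attachment and "
                    "cannot extend a chain"
                )
            prev_acyl = self.role_atom(res_index - 1, "acyl")
            if prev_acyl is None:
                raise ScaffoldError("previous residue has no acyl tail")
            self._condense(prev_acyl, self.role_atom(res_index, "head"))
        residue = Residue(res_index, record.name, record.monomer_class, module)
        self.residues.append(residue)
        self.sanitize()
        return residue

    def _condense(self, acyl_atom, head_atom) -> None:
        """Form the inter-residue bond, losing the tail hydroxyl as water."""
        oh = carboxyl_hydroxyl(acyl_atom)
        if oh is None:
            raise ScaffoldError("tail carboxyl already consumed")
        acyl_uid = self.uid_of(acyl_atom)
        head_uid = self.uid_of(head_atom)
        self.mol.RemoveAtom(oh.GetIdx())
        self.mol.AddBond(
            self.idx(acyl_uid), self.idx(head_uid), Chem.BondType.SINGLE
        )

    # -- edit primitives (shared with the tailoring-reaction library) -------

    def add_atom(self, symbol: str, bonded_to_uid: int,
                 bond=Chem.BondType.SINGLE) -> int:
        atom = Chem.Atom(symbol)
        atom.SetIntProp("uid", self._next_uid)
        self._next_uid += 1
        new_idx = self.mol.AddAtom(atom)
        self.mol.AddBond(self.idx(bonded_to_uid), new_idx, bond)
        return self.mol.GetAtomWithIdx(new_idx).GetIntProp("uid")

    def remove_atom(self, uid: int) -> None:
        i = self.idx(uid)
        if i is not None:
            self.mol.RemoveAtom(i)

    def set_bond(self, uid_a: int, uid_b: int, order) -> None:
        bond = self.mol.GetBondBetweenAtoms(self.idx(uid_a), self.idx(uid_b))
        if bond is None:
            self.mol.AddBond(self.idx(uid_a), self.idx(uid_b), order)
        else:
            bond.SetBondType(order)

    def remove_bond(self, uid_a: int, uid_b: int) -> None:
        self.mol.RemoveBond(self.idx(uid_a), self.idx(uid_b))

    def attach(
        self,
        smiles: str,
        to_uid: int,
        bond=Chem.BondType.SINGLE,
        res_index: Optional[int] = None,
    ) -> list[int]:
        """Graft a fragment (attachment atom = map 1) onto an existing atom;
        returns the uids of the new atoms."""
        frag = Chem.MolFromSmiles(smiles)
        if frag is None:
            raise ScaffoldError(f"unparseable fragment SMILES {smiles!r}")
        attach_idx = None
        for atom in frag.GetAtoms():
            if atom.GetAtomMapNum() == 1:
                attach_idx = atom.GetIdx()
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(False)
                atom.SetNumRadicalElectrons(0)
            atom.SetAtomMapNum(0)
        if attach_idx is None:
            raise ScaffoldError(f"fragment {smiles!r} lacks an attachment map")
        Chem.SanitizeMol(frag)
        offset = self.mol.GetNumAtoms()
        combined = RWMol(Chem.CombineMols(self.mol, frag))
        new_uids = []
        for atom in combined.GetAtoms():
            if atom.GetIdx() < offset:
                continue
            atom.SetIntProp("uid", self._next_uid)
            if res_index is not None:
                atom.SetIntProp("res", res_index)
            new_uids.append(self._next_uid)
            self._next_uid += 1
        self.mol = combined
        self.set_bond(to_uid, new_uids[attach_idx], bond)
        return new_uids

    def sanitize(self) -> None:
        Chem.SanitizeMol(self.mol)

    def is_valid(self) -> bool:
        try:
            Chem.SanitizeMol(RWMol(self.mol))
            return True
        except Exception:
            return False

    # -- queries ------------------------------------------------------------

    def terminal_acyl(self):
        """The chain-terminal acyl carbon (last residue's tail)."""
        for res in reversed(self.residues):
            atom = self.role_atom(res.index, "acyl")
            if atom is not None:
                return atom
        return None

    def n_terminal_amine(self):
        """The free (unacylated) head amine of the first residue, if any."""
        if not self.residues:
            return None
        head = self.role_atom(0, "head")
        if head is None or head.GetSymbol() != "N":
            return None
        if head.GetTotalNumHs() >= 2 or (
            head.IsInRing() and head.GetTotalNumHs() >= 1
        ):
            return head
        return None

    def copy(self) -> "Scaffold":
        new = Scaffold()
        new.mol = RWMol(Chem.Mol(self.mol))
        new.reaction_count = self.reaction_count
        new.residues = list(self.residues)
        new.flags = dict(self.flags)
        new._next_uid = self._next_uid
        return new

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


# ---------------------------------------------------------------------------
# monomer parsing
# ---------------------------------------------------------------------------


def parse_monomer(record: MonomerRecord):
    """Parse a monomer SMILES; return (mol, head_idx, tail_idx)."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise MonomerLibraryError(
            f"monomer {record.name}: unparseable SMILES {record.smiles!r}"
        )
    head = tail = None
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            head = atom.GetIdx()
        elif atom.GetAtomMapNum() == 2:
            tail = atom.GetIdx()
        if atom.GetAtomMapNum():
            # mapped attachment atoms must gain/lose hydrogens freely
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
            atom.SetNumRadicalElectrons(0)
        atom.SetAtomMapNum(0)
    Chem.SanitizeMol(mol)
    if tail is None and record.monomer_class != "sugar":
        raise MonomerLibraryError(
            f"monomer {record.name}: missing tail attachment label"
        )
    if head is None and record.monomer_class == "sugar":
        raise MonomerLibraryError(
            f"monomer {record.name}: sugar lacks an anomeric attachment label"
        )
    return mol, head, tail


def carboxyl_hydroxyl(acyl_atom):
    """The removable -OH oxygen on a carboxyl carbon, or None."""
    for nbr in acyl_atom.GetNeighbors():
        if nbr.GetSymbol() != "O" or nbr.GetDegree() != 1:
            continue
        bond = acyl_atom.GetOwningMol().GetBondBetweenAtoms(
            acyl_atom.GetIdx(), nbr.GetIdx()
        )
        if bond.GetBondType() == Chem.BondType.SINGLE:
            return nbr
    return None


def alpha_carbon(scaffold: Scaffold, res_index: int):
    """The residue's carbon bonded to both its head atom and its acyl carbon."""
    head = scaffold.role_atom(res_index, "head")
    acyl = scaffold.role_atom(res_index, "acyl")
    if acyl is None:
        return None
    if head is not None and head.GetSymbol() == "C":
        return head  # ketide: the head IS the alpha carbon
    for nbr in acyl.GetNeighbors():
        if nbr.GetSymbol() != "C":
            continue
        if head is not None and scaffold.mol.GetBondBetweenAtoms(
            nbr.GetIdx(), head.GetIdx()
        ):
            return nbr
    return None


# ---------------------------------------------------------------------------
# module-local tailoring
# ---------------------------------------------------------------------------


def apply_reductive_loop(module: BioModule, scaffold: Scaffold) -> Scaffold:
    """Set the oxidation state of a ketide module's beta position.

    KR alone gives the beta-hydroxy, KR+DH the alpha,beta-enoyl, KR+DH+ER the
    fully saturated methylene; without a loop the unit stays beta-keto. A DH
    or ER without KR is biosynthetically inconsistent and is left beta-keto
    with a warning. The beta carbon is the acyl carbon contributed by the
    preceding residue.
    """
    loop = module.reductive_loop
    if not loop:
        return scaffold
    if loop & {"dehydratase", "enoylreductase"} and "ketoreductase" not in loop:
        logger.warning(
            "dehydratase/enoylreductase without ketoreductase; module left "
            "beta-keto"
        )
        return scaffold
    res_index = next(
        (r.index for r in scaffold.residues if r.module is module), None
    )
    if res_index is None or res_index == 0:
        return scaffold
    beta = scaffold.role_atom(res_index - 1, "acyl")
    head = scaffold.role_atom(res_index, "head")
    if beta is None or head is None:
        return scaffold
    keto_o = next(
        (
            n
            for n in beta.GetNeighbors()
            if n.GetSymbol() == "O"
            and scaffold.mol.GetBondBetweenAtoms(beta.GetIdx(), n.GetIdx())
            .GetBondType()
            == Chem.BondType.DOUBLE
        ),
        None,
    )
    if keto_o is None:
        return scaffold
    beta_uid = scaffold.uid_of(beta)
    head_uid = scaffold.uid_of(head)
    o_uid = scaffold.uid_of(keto_o)
    if loop == {"ketoreductase"}:
        scaffold.set_bond(beta_uid, o_uid, Chem.BondType.SINGLE)
    elif loop == {"ketoreductase", "dehydratase"}:
        scaffold.remove_atom(o_uid)
        scaffold.set_bond(beta_uid, head_uid, Chem.BondType.DOUBLE)
    else:  # KR + DH + ER
        scaffold.remove_atom(o_uid)
        scaffold.set_bond(beta_uid, head_uid, Chem.BondType.SINGLE)
    scaffold.sanitize()
    return scaffold


def heterocyclize(
    module: BioModule,
    scaffold: Scaffold,
    cluster_families: frozenset = frozenset(),
) -> Scaffold:
    """Cyclize a cysteine/serine residue onto the preceding amide.

    Cysteine gives a thiazoline, serine an oxazoline; a cluster-level
    nitroreductase oxidizes the ring to the thiazole/oxazole. Any other
    residue condenses normally with a warning.
    """
    res_index = next(
        (r.index for r in scaffold.residues if r.module is module), None
    )
    if res_index is None or res_index == 0:
        return scaffold
    residue = scaffold.residues[res_index]
    if residue.name not in ("cysteine", "serine"):
        logger.warning(
            "heterocyclization condensation on %s; plain condensation applied",
            residue.name,
        )
        return scaffold
    hetero_symbol = "S" if residue.name == "cysteine" else "O"
    prev_acyl = scaffold.role_atom(res_index - 1, "acyl")
    head_n = scaffold.role_atom(res_index, "head")
    alpha = alpha_carbon(scaffold, res_index)
    if prev_acyl is None or head_n is None or alpha is None:
        return scaffold
    # side-chain CH2-X walks alpha -> beta -> heteroatom
    beta = next(
        (
            n
            for n in alpha.GetNeighbors()
            if n.GetSymbol() == "C"
            and n.GetIdx() != prev_acyl.GetIdx()
            and not (n.HasProp("role") and n.GetProp("role") == "acyl")
        ),
        None,
    )
    if beta is None:
        return scaffold
    hetero = next(
        (
            n
            for n in beta.GetNeighbors()
            if n.GetSymbol() == hetero_symbol and n.GetDegree() == 1
        ),
        None,
    )
    if hetero is None:
        return scaffold
    carbonyl_o = next(
        (
            n
            for n in prev_acyl.GetNeighbors()
            if n.GetSymbol() == "O"
            and scaffold.mol.GetBondBetweenAtoms(
                prev_acyl.GetIdx(), n.GetIdx()
            ).GetBondType()
            == Chem.BondType.DOUBLE
        ),
        None,
    )
    if carbonyl_o is None:
        return scaffold
    c2 = scaffold.uid_of(prev_acyl)
    n3 = scaffold.uid_of(head_n)
    c4 = scaffold.uid_of(alpha)
    c5 = scaffold.uid_of(beta)
    x1 = scaffold.uid_of(hetero)
    scaffold.remove_atom(scaffold.uid_of(carbonyl_o))
    scaffold.set_bond(x1, c2, Chem.BondType.SINGLE)
    scaffold.set_bond(n3, c2, Chem.BondType.DOUBLE)
    if "nitroreductase" in cluster_families:
        scaffold.set_bond(c4, c5, Chem.BondType.DOUBLE)
    scaffold.sanitize()
    return scaffold


def _methylate(scaffold: Scaffold, module: BioModule, res_index: int) -> None:
    """Apply module-embedded N-, C-, and O-methyltransferases."""
    if module.has_family("methyltransferase_N"):
        head = scaffold.role_atom(res_index, "head")
        if head is not None and head.GetSymbol() == "N" and head.GetTotalNumHs():
            scaffold.add_atom("C", scaffold.uid_of(head))
    if module.has_family("methyltransferase_C"):
        alpha = alpha_carbon(scaffold, res_index)
        if alpha is not None and alpha.GetTotalNumHs():
            scaffold.add_atom("C", scaffold.uid_of(alpha))
    if module.has_family("methyltransferase_O"):
        for atom in scaffold.atoms_of_residue(res_index):
            if (
                atom.GetSymbol() == "O"
                and atom.GetDegree() == 1
                and atom.GetTotalNumHs() == 1
                and not atom.GetIsAromatic()
            ):
                nbr = atom.GetNeighbors()[0]
                if any(
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(nbr).GetSymbol() == "O"
                    for b in nbr.GetBonds()
                ):
                    continue  # carboxyl, not a methylatable hydroxyl
                scaffold.add_atom("C", scaffold.uid_of(atom))
                break
    scaffold.sanitize()


# ---------------------------------------------------------------------------
# linear scaffold assembly
# ---------------------------------------------------------------------------

_SKIPPED_TYPES = {"type2_unit"}


def _resolve_substrate(
    module: BioModule, cluster_families: frozenset
) -> Optional[str]:
    name = module.substrate
    if name is None and module.type in ("acyltransferase", "trans_at_insertion"):
        name = "malonate"
    if name == "tryptophan" and "tryptophan_dioxygenase" in cluster_families:
        name = "kynurenine"  # dioxygenase converts the residue during assembly
    return name


def build_linear_scaffold(
    permutation: Sequence[BioModule],
    monomers: MonomerLibrary,
    cluster_families: frozenset = frozenset(),
) -> Scaffold:
    """Condense the active modules of one permutation into a linear scaffold.

    Residues are joined starter-to-thioesterase; module-local tailoring
    (reductive loop, methylation, heterocyclization) is applied as each
    residue is added. Unknown substrate names raise
    :class:`MonomerLibraryError`.
    """
    active = [
        m
        for m in permutation
        if m.active and m.type not in _SKIPPED_TYPES
        and not m.extras.get("carrier_fragment")
        and not m.extras.get("unresolvable")
    ]
    if not active:
        raise ScaffoldError("no active modules in permutation")
    scaffold = Scaffold()
    for module in active:
        name = _resolve_substrate(module, cluster_families)
        if name is None:
            raise MonomerLibraryError(
                f"module of type {module.type} has no resolvable substrate"
            )
        record = monomers.get(name)
        residue = scaffold.add_residue(record, module)
        if record.monomer_class == "ketide":
            apply_reductive_loop(module, scaffold)
        if module.is_heterocyclization:
            heterocyclize(module, scaffold, cluster_families)
        _methylate(scaffold, module, residue.index)
    scaffold.sanitize()
    return scaffold


# ---------------------------------------------------------------------------
# type II polyketides
# ---------------------------------------------------------------------------


@dataclass
class Type2Chain:
    """A linear poly-beta-ketothioester chain with its carbon numbering.

    ``carbon_numbering`` maps linear carbon numbers (C1 = the thioester /
    terminal acyl carbonyl) to atom uids.
    """

    scaffold: Scaffold
    extensions: int
    starter: MonomerRecord
    carbon_numbering: dict = field(default_factory=dict)

    @property
    def chain_carbons(self) -> int:
        return len(self.carbon_numbering)


def _select_type2_starter(cluster, monomers: MonomerLibrary) -> MonomerRecord:
    """Priming-AT-annotated starter with prerequisite gating; acetate default."""
    fams = cluster.domain_families
    priming = cluster.domains_of_family("priming_AT")
    if not priming:
        return monomers.get("acetate")
    dom = priming[0]
    candidates: list[str] = []
    primary = dom.annotations.get("substrate") or dom.top_substrate
    if primary:
        candidates.append(primary)
    for _ref, _score, payload in dom.annotations.get("ranked_refs", []):
        sub = payload.get("substrate")
        if sub and sub not in candidates:
            candidates.append(sub)
    for name in candidates:
        if name not in TYPE2_STARTERS:
            continue
        gate = TYPE2_STARTER_GATES.get(name)
        if gate is not None and gate not in fams:
            logger.warning(
                "starter %s requires %s; falling back", name, gate
            )
            continue
        return monomers.get(name)
    return monomers.get("acetate")


def build_type2_chain(cluster, monomers: Optional[MonomerLibrary] = None) -> Type2Chain:
    """Generate the unreduced linear poly-beta-ketide chain of a type II PKS.

    The extension count comes from the chain length factor annotation (the
    single most homologous reference); the starter is acetate unless a
    priming acyltransferase is annotated with an alternative (benzoate and
    malonamate additionally require a phenylalanine ammonia-lyase or an
    amidotransferase in the cluster). Acyl-adenylating ligases are inactive
    when a priming AT is present.
    """
    monomers = monomers or MonomerLibrary()
    clf = cluster.domains_of_family("chain_length_factor")
    if not clf or "extensions" not in clf[0].annotations:
        raise ScaffoldError(
            "type II chain length unknown: no annotated chain length factor"
        )
    extensions = int(clf[0].annotations["extensions"])
    starter = _select_type2_starter(cluster, monomers)
    scaffold = Scaffold()
    scaffold.add_residue(starter)
    malonate = monomers.get("malonate")
    for _ in range(extensions):
        scaffold.add_residue(malonate)
    numbering: dict[int, int] = {}
    num = 1
    for res in reversed(scaffold.residues):
        acyl = scaffold.role_atom(res.index, "acyl")
        head = scaffold.role_atom(res.index, "head")
        if acyl is not None:
            numbering[num] = scaffold.uid_of(acyl)
            num += 1
        if head is not None and head.GetSymbol() == "C":
            numbering[num] = scaffold.uid_of(head)
            num += 1
        elif res.index == 0:
            # walk the starter's carbon skeleton away from the acyl carbon
            prev = acyl
            current = next(
                (
                    n
                    for n in acyl.GetNeighbors()
                    if n.GetSymbol() == "C"
                    and n.GetIntProp("res") == res.index
                ),
                None,
            )
            while current is not None:
                numbering[num] = scaffold.uid_of(current)
                num += 1
                nxt = next(
                    (
                        n
                        for n in current.GetNeighbors()
                        if n.GetSymbol() == "C"
                        and n.GetIdx() != prev.GetIdx()
                        and n.GetIntProp("res") == res.index
                        and not n.GetIsAromatic()
                    ),
                    None,
                )
                prev, current = current, nxt
    return Type2Chain(
        scaffold=scaffold,
        extensions=extensions,
        starter=starter,
        carbon_numbering=numbering,
    )


def _reduce_carbonyl(scaffold: Scaffold, carbon_uid: int) -> bool:
    atom = scaffold.atom(carbon_uid)
    if atom is None:
        return False
    for nbr in atom.GetNeighbors():
        bond = scaffold.mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
        if nbr.GetSymbol() == "O" and bond.GetBondType() == Chem.BondType.DOUBLE:
            bond.SetBondType(Chem.BondType.SINGLE)
            scaffold.sanitize()
            return True
    return False


def _close_ring(scaffold: Scaffold, pair: tuple, numbering: dict) -> bool:
    """Aldol-type ring closure between two numbered chain carbons.

    The odd-numbered carbon of the pair is the attacked carbonyl (reduced to
    a hydroxyl); the even-numbered carbon is the nucleophile.
    """
    a, b = pair
    if a not in numbering or b not in numbering:
        return False
    carbonyl_num = a if a % 2 == 1 else b
    nucleo_num = b if carbonyl_num == a else a
    c_uid = numbering[carbonyl_num]
    n_uid = numbering[nucleo_num]
    c_atom = scaffold.atom(c_uid)
    n_atom = scaffold.atom(n_uid)
    if c_atom is None or n_atom is None or n_atom.GetTotalNumHs() < 1:
        return False
    if not _reduce_carbonyl(scaffold, c_uid):
        return False
    try:
        scaffold.set_bond(c_uid, n_uid, Chem.BondType.SINGLE)
        scaffold.sanitize()
    except Exception:
        return False
    return True


def aromatic_alpha_carbons(scaffold: Scaffold) -> list[int]:
    """Aromatic alpha carbons with exactly two bonds: the candidate
    C-glycosylation sites."""
    return [
        scaffold.uid_of(a)
        for a in scaffold.mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetDegree() == 2
    ]


def apply_type2_tailoring(chain: Type2Chain, cluster) -> list[Scaffold]:
    """Apply regiospecific type II tailoring (KR, cyclases, MTs, oxygenases,
    aminotransferase) to the linear chain.

    Each regiospecific domain acts at its single clade-determined carbon, so
    no combinatorics arise here; C-glycosylation sites are computed but
    attachment itself happens in the combinatorial engine. Cyclase clades
    without a pattern entry leave the chain uncyclized with a warning.
    """
    scaffold = chain.scaffold.copy()
    numbering = dict(chain.carbon_numbering)
    fams = cluster.domain_families

    for fam, carbon in TYPE2_KR_CARBON.items():
        if fam in fams and carbon in numbering:
            if _reduce_carbonyl(scaffold, numbering[carbon]):
                scaffold.reaction_count += 1

    clf = cluster.domains_of_family("chain_length_factor")
    clf_pattern = clf[0].annotations.get("clf_pattern") if clf else None
    for dom in cluster.domains:
        if not dom.family.startswith("cyclase_clade"):
            continue
        key = dom.family
        if key == "cyclase_clade_VIb":
            key = f"cyclase_clade_VIb:{clf_pattern or 'anthracycline'}"
        pattern = CYCLASE_RING_PATTERNS.get(key)
        if pattern is None:
            logger.warning(
                "no ring pattern for %s; chain left uncyclized", key
            )
            continue
        for pair in pattern:
            if _close_ring(scaffold, pair, numbering):
                scaffold.reaction_count += 1

    if "aminotransferase_C2" in fams and 2 in numbering:
        atom = scaffold.atom(numbering[2])
        if atom is not None and atom.GetTotalNumHs() >= 1:
            scaffold.add_atom("N", numbering[2])
            scaffold.sanitize()
            scaffold.reaction_count += 1

    for fam, carbon in TYPE2_CMT_CARBON.items():
        if fam in fams and carbon in numbering:
            atom = scaffold.atom(numbering[carbon])
            if atom is not None and atom.GetTotalNumHs() >= 1:
                scaffold.add_atom("C", numbering[carbon])
                scaffold.sanitize()
                scaffold.reaction_count += 1

    if "MT_C2" in fams and 2 in numbering:
        c2 = scaffold.atom(numbering[2])
        nitrogen = next(
            (n for n in c2.GetNeighbors() if n.GetSymbol() == "N"), None
        )
        oxygen = next(
            (
                n
                for n in c2.GetNeighbors()
                if n.GetSymbol() == "O" and n.GetTotalNumHs() >= 1
            ),
            None,
        )
        if nitrogen is not None:
            # N,N-dimethylation when nitrogen is present at C2
            scaffold.add_atom("C", scaffold.uid_of(nitrogen))
            scaffold.add_atom("C", scaffold.uid_of(nitrogen))
            scaffold.sanitize()
            scaffold.reaction_count += 1
        elif oxygen is not None:
            scaffold.add_atom("C", scaffold.uid_of(oxygen))
            scaffold.sanitize()
            scaffold.reaction_count += 1

    if "MT_O_carboxy" in fams:
        acyl = scaffold.terminal_acyl()
        if acyl is not None:
            oh = carboxyl_hydroxyl(acyl)
            if oh is not None:
                scaffold.add_atom("C", scaffold.uid_of(oh))
                scaffold.sanitize()
                scaffold.reaction_count += 1

    for fam in ("MT_O_C11_cladeA", "MT_O_C11_cladeB"):
        if fam in fams and 11 in numbering:
            c11 = scaffold.atom(numbering[11])
            oxygen = next(
                (
                    n
                    for n in c11.GetNeighbors()
                    if n.GetSymbol() == "O" and n.GetTotalNumHs() >= 1
                ),
                None,
            )
            if oxygen is not None:
                scaffold.add_atom("C", scaffold.uid_of(oxygen))
                scaffold.sanitize()
                scaffold.reaction_count += 1

    for fam in ("anthrone_oxygenase", "quinone_forming_oxygenase"):
        if fam in fams:
            # quinone-forming oxidation: hydroxylate the first ring carbon
            # bearing a hydrogen (provisional regiochemistry)
            target = next(
                (
                    a
                    for a in scaffold.mol.GetAtoms()
                    if a.IsInRing()
                    and a.GetSymbol() == "C"
                    and a.GetTotalNumHs() >= 1
                ),
                None,
            )
            if target is not None:
                scaffold.add_atom("O", scaffold.uid_of(target))
                scaffold.sanitize()
                scaffold.reaction_count += 1

    if "baeyer_villiger_monooxygenase" in fams:
        inserted = _baeyer_villiger(scaffold, numbering)
        if inserted:
            scaffold.reaction_count += 1
    if "favorskiiase" in fams:
        logger.warning(
            "favorskii rearrangement is provisional; no graph edit applied"
        )

    return [scaffold]


def _baeyer_villiger(scaffold: Scaffold, numbering: dict) -> bool:
    """Insert an oxygen next to the first remaining chain ketone."""
    for num in sorted(numbering):
        if num % 2 == 0 or num == 1:
            continue
        atom = scaffold.atom(numbering[num])
        if atom is None:
            continue
        has_keto = any(
            n.GetSymbol() == "O"
            and scaffold.mol.GetBondBetweenAtoms(atom.GetIdx(), n.GetIdx())
            .GetBondType()
            == Chem.BondType.DOUBLE
            for n in atom.GetNeighbors()
        )
        if not has_keto:
            continue
        partner_num = num + 1
        if partner_num not in numbering:
            continue
        partner_uid = numbering[partner_num]
        if scaffold.atom(partner_uid) is None:
            continue
        try:
            scaffold.remove_bond(numbering[num], partner_uid)
            o_uid = scaffold.add_atom("O", numbering[num])
            scaffold.set_bond(o_uid, partner_uid, Chem.BondType.SINGLE)
            scaffold.sanitize()
            return True
        except Exception:
            return False
    return False
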