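"""Combinatorial plan generation and execution.

A combinatorial plan is the intersection of one module permutation, one
macrocyclization pattern, one sugar combination with an attachment
assignment, and one set of tailoring reaction plans (one site choice per
firing reaction). Plans are the Cartesian product of the four components,
capped at 1000 per cluster by seeded pseudorandom selection. Execution runs
scaffold build -> tailoring reactions -> sugar attachment -> macrocyclization;
plans whose events cannot all execute are discarded. The scaffold library
keeps only scaffolds whose successfully-executed-reaction count matches the
library's (resetting the library whenever a richer scaffold appears),
deduplicates canonical SMILES, and stops at the maximum library size (50 by
default) using seeded pseudorandom plan selection.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from bgcforge.annotate import Domain
from bgcforge.chem_scaffold import Scaffold
from bgcforge.reactions import (
    ReactionPlan,
    attach_sugar,
    enumerate_macrocyclizations,
    execute_cyclization,
    execute_reaction,
    find_substrate_sites,
)
from bgcforge.refdata import MonomerLibrary, TailoringReaction
from bgcforge.sugars import SugarCombination, enumerate_attachments

logger = logging.getLogger(__name__)

DEFAULT_MAX_PLANS = 1000
DEFAULT_MAX_LIBRARY = 50
DEFAULT_SEED = 0


@dataclass
class CombinatorialPlan:
    permutation_index: int
    cyclization: tuple
    sugar_assignment: Optional[tuple]  # (SugarCombination, site tuple) or None
    reaction_plans: tuple = ()


@dataclass
class ScaffoldLibrary:
    scaffolds: list = field(default_factory=list)
    reaction_count: int = 0
    plans_evaluated: int = 0
    caps: dict = field(
        default_factory=lambda: {
            "max_plans": DEFAULT_MAX_PLANS,
            "max_library": DEFAULT_MAX_LIBRARY,
        }
    )

    @property
    def smiles(self) -> list[str]:
        return [Chem.MolToSmiles(s.mol) for s in self.scaffolds]


def generate_plans(
    base_scaffolds: Sequence[Scaffold],
    cluster,
    sugar_combinations: Sequence[SugarCombination] = (),
    tailoring: Sequence[tuple] = (),
    max_plans: int = DEFAULT_MAX_PLANS,
    seed: int = DEFAULT_SEED,
    allow_c_glycosylation: bool = False,
) -> tuple[list[CombinatorialPlan], dict]:
    """Cartesian product of permutations x cyclizations x sugar assignments
    x reaction-plan sets, capped at ``max_plans`` by seeded selection.

    ``tailoring`` is a sequence of (TailoringReaction, Domain) pairs fired by
    the cluster's domains. Returns (plans, accounting) where accounting
    mirrors the combinatorial information block of the report.
    """
    plans: list[CombinatorialPlan] = []
    n_cyc = 0
    n_sugar_assign = 0
    n_reaction_plans = 0
    for pi, base in enumerate(base_scaffolds):
        cyclizations = enumerate_macrocyclizations(base, cluster)
        n_cyc = max(n_cyc, len(cyclizations))
        sugar_options: list[Optional[tuple]] = []
        for comb in sugar_combinations:
            for assignment in enumerate_attachments(
                comb, base, allow_aromatic_carbon=allow_c_glycosylation
            ):
                sugar_options.append((comb, assignment))
        if not sugar_options:
            sugar_options = [None]
        n_sugar_assign = max(
            n_sugar_assign, sum(1 for s in sugar_options if s is not None)
        )
        per_reaction_sites: list[list[ReactionPlan]] = []
        for reaction, domain in tailoring:
            sites = find_substrate_sites(reaction, base, cluster, domain)
            if sites:
                per_reaction_sites.append(
                    [ReactionPlan(reaction, site, domain) for site in sites]
                )
        reaction_sets: list[tuple]
        if per_reaction_sites:
            reaction_sets = [
                tuple(combo)
                for combo in itertools.product(*per_reaction_sites)
            ]
        else:
            reaction_sets = [()]
        n_reaction_plans += sum(len(s) for s in per_reaction_sites)
        for cyc in cyclizations:
            for sugar in sugar_options:
                for rset in reaction_sets:
                    plans.append(
                        CombinatorialPlan(
                            permutation_index=pi,
                            cyclization=cyc,
                            sugar_assignment=sugar,
                            reaction_plans=rset,
                        )
                    )
    total = len(plans)
    if total > max_plans:
        rng = random.Random(seed)
        keep = sorted(rng.sample(range(total), max_plans))
        plans = [plans[i] for i in keep]
    accounting = {
        "permutations": len(base_scaffolds),
        "cyclizations": n_cyc,
        "sugar_combinations": len(sugar_combinations),
        "sugar_assignments": n_sugar_assign,
        "tailoring_reaction_plans": n_reaction_plans,
        "total_plans": total,
        "plans_evaluated": len(plans),
    }
    return plans, accounting


def execute_plan(
    plan: CombinatorialPlan,
    base_scaffolds: Sequence[Scaffold],
    monomers: MonomerLibrary,
) -> Optional[Scaffold]:
    """Run one plan to a finished scaffold, or None when any event fails."""
    scaffold = base_scaffolds[plan.permutation_index].copy()
    for rplan in plan.reaction_plans:
        result = execute_reaction(rplan, scaffold)
        if result is None:
            return None
        scaffold = result
    if plan.sugar_assignment is not None:
        comb, assignment = plan.sugar_assignment
        attached_uids: list[list[int]] = []
        for sugar_name, site in zip(comb.sugars, assignment):
            record = monomers.get(sugar_name)
            if site[0] == "sugar":
                donor_uids = attached_uids[site[1]]
                target = _free_sugar_hydroxyl(scaffold, donor_uids)
                if target is None:
                    return None
                site = ("O", target)
            work = scaffold.copy()
            new_uids = attach_sugar(work, record, site)
            if new_uids is None:
                return None
            scaffold = work
            scaffold.reaction_count += 1
            attached_uids.append(new_uids)
    result = execute_cyclization(plan.cyclization, scaffold)
    if result is None:
        return None
    return result


def _free_sugar_hydroxyl(scaffold: Scaffold, uids: list[int]) -> Optional[int]:
    for uid in uids:
        atom = scaffold.atom(uid)
        if (
            atom is not None
            and atom.GetSymbol() == "O"
            and atom.GetDegree() == 1
            and atom.GetTotalNumHs() >= 1
            and not atom.GetIsAromatic()
        ):
            return uid
    return None


def execute_plans(
    plans: Sequence[CombinatorialPlan],
    base_scaffolds: Sequence[Scaffold],
    monomers: MonomerLibrary,
    max_library: int = DEFAULT_MAX_LIBRARY,
    seed: int = DEFAULT_SEED,
) -> ScaffoldLibrary:
    """Execute plans into a reaction-count-filtered, deduplicated library.

    When more plans exist than the library can hold, a seeded pseudorandom
    order selects plans until the library is full or plans are exhausted.
    Scaffolds below the library's reaction count are dropped; a scaffold
    above it resets the library.
    """
    order = list(plans)
    if len(order) > max_library:
        rng = random.Random(seed)
        rng.shuffle(order)
    library = ScaffoldLibrary(plans_evaluated=len(plans))
    library.caps["max_library"] = max_library
    seen: set[str] = set()
    any_success = False
    for plan in order:
        scaffold = execute_plan(plan, base_scaffolds, monomers)
        if scaffold is None:
            continue
        any_success = True
        rc = scaffold.reaction_count
        if rc > library.reaction_count:
            library.scaffolds = []
            seen = set()
            library.reaction_count = rc
        elif rc < library.reaction_count:
            continue
        smi = Chem.MolToSmiles(scaffold.mol)
        if smi in seen:
            continue
        seen.add(smi)
        library.scaffolds.append(scaffold)
        if len(library.scaffolds) >= max_library:
            break
    if plans and not any_success:
        logger.warning("all combinatorial plans failed to execute")
    return library
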