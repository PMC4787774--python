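"""Combinatorial deoxysugar prediction and glycosyltransferase classification.

The number of deoxysugar glycosyltransferases in a cluster is assumed to
equal the number of deoxysugars on the product. Candidate sugar multisets of
that size are enumerated exhaustively (fewer than four sugars) or sampled
pseudorandomly (2500 seeded draws at four or more), and scored against the
observed set of sugar-biosynthesis gene families by two mismatch counts:
genes observed but not required, and genes required but not observed.
Combinations minimizing both counts are retained (up to 100), and identified
hexose sugars are appended to each retained combination. Attachment sites —
free hydroxyls, permitted aromatic carbons for C-glycosyltransferases, and
hydroxyls of already-attached sugars (oligosaccharide chains) — are then
combinatorialized per retained combination.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from bgcforge.annotate import Domain
from bgcforge.chem_scaffold import Scaffold, aromatic_alpha_carbons
from bgcforge.reactions import free_hydroxyls

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZE = 2500
DEFAULT_RETAIN_MAX = 100
EXHAUSTIVE_BELOW = 4

HEXOSE_SUBSTRATES = ("glucose", "mannose", "gulose", "N-acetylglucosamine")


@dataclass(frozen=True)
class SugarCombination:
    """A multiset of deoxysugar names with its mismatch score.

    ``mismatch`` is (genes observed in the cluster but not needed by the
    combination's pathways, genes needed but not observed). Shared genes
    between pathways count once: the requirement is the union.
    """

    sugars: tuple
    mismatch: tuple


def candidate_multisets(
    gt_count: int,
    code: dict,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
) -> list[tuple]:
    """Candidate sugar multisets of size ``gt_count``.

    Exhaustive combinations-with-repetition below four sugars; a seeded
    pseudorandom set of exactly ``sample_size`` evaluated draws at four or
    more.
    """
    names = sorted(code)
    if gt_count < EXHAUSTIVE_BELOW:
        return list(itertools.combinations_with_replacement(names, gt_count))
    rng = random.Random(seed)
    return [
        tuple(sorted(rng.choice(names) for _ in range(gt_count)))
        for _ in range(sample_size)
    ]


def _score(sugars: tuple, observed: frozenset, code: dict) -> tuple:
    required = frozenset().union(*(code[s] for s in sugars)) if sugars else frozenset()
    return (len(observed - required), len(required - observed))


def predict_sugar_combinations(
    gt_count: int,
    observed,
    code: dict,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    retain_max: int = DEFAULT_RETAIN_MAX,
    seed: int = 0,
    hexose_sugars: Sequence[str] = (),
) -> list[SugarCombination]:
    """Retained minimal sugar combinations for a cluster.

    Candidates of size ``gt_count`` are exhaustive below four, else a seeded
    pseudorandom set of ``sample_size`` distinct multisets. Minimization is
    lexicographic on (total mismatch, genes-missing count); when a
    simultaneous minimizer of both counts exists this equals the set of
    simultaneous minimizers. Retention order is lowest total mismatch first,
    then lexicographic sugar names, capped at ``retain_max``. Identified
    hexose sugars are appended to every retained combination afterwards.
    """
    if gt_count == 0:
        return []
    if not code:
        raise ValueError("empty glycogenetic code")
    observed = frozenset(observed)
    candidates = candidate_multisets(gt_count, code, sample_size, seed)
    scored = [(c, _score(c, observed, code)) for c in candidates]
    best_key = min((m[0] + m[1], m[1]) for _c, m in scored)
    seen_multisets: set = set()
    retained = []
    for c, m in scored:
        if (m[0] + m[1], m[1]) != best_key or c in seen_multisets:
            continue
        seen_multisets.add(c)
        retained.append(SugarCombination(c, m))
    pareto_min = (
        min(m[0] for _c, m in scored),
        min(m[1] for _c, m in scored),
    )
    if best_key[0] != pareto_min[0] + pareto_min[1]:
        logger.info(
            "no combination minimizes both mismatch counts simultaneously "
            "(minima %s); lexicographic minimizers retained", pareto_min
        )
    retained.sort(key=lambda sc: (sum(sc.mismatch), sc.sugars))
    retained = retained[:retain_max]
    if hexose_sugars:
        retained = [
            SugarCombination(sc.sugars + tuple(hexose_sugars), sc.mismatch)
            for sc in retained
        ]
    return retained


def classify_glycosyltransferases(
    gt_domains: Sequence[Domain],
) -> tuple[list[Domain], list[Domain], list[Domain]]:
    """Split GT domains into (hexose, deoxysugar, C-glycosyl) lists.

    Hexose GTs carry an alignment-refined hexose substrate (glucose,
    mannose, gulose, or N-acetylglucosamine); C-glycosyltransferases attach
    through carbon; all remaining glycosyltransferases are considered
    deoxysugar-specific.
    """
    hexose, deoxy, c_glyco = [], [], []
    for d in gt_domains:
        if d.family == "c_glycosyltransferase" or d.functional_subtype == "c_glycosyl":
            c_glyco.append(d)
        elif d.functional_subtype == "hexose" or (
            d.annotations.get("substrate") in HEXOSE_SUBSTRATES
        ):
            hexose.append(d)
        else:
            deoxy.append(d)
    return hexose, deoxy, c_glyco


def enumerate_attachments(
    combination: SugarCombination,
    scaffold: Scaffold,
    allow_aromatic_carbon: bool = False,
) -> list[tuple]:
    """All assignments of the combination's sugars to attachment sites.

    Each assignment maps every sugar, in order, to a free hydroxyl
    (``('O', uid)``), a permitted aromatic carbon (``('C', uid)``), or an
    earlier sugar in the same assignment (``('sugar', k)`` — an
    oligosaccharide linkage). Assignments in which two events claim the same
    scaffold site are excluded.
    """
    base_sites: list[tuple] = [("O", uid) for uid in free_hydroxyls(scaffold)]
    if allow_aromatic_carbon:
        base_sites += [("C", uid) for uid in aromatic_alpha_carbons(scaffold)]
    n = len(combination.sugars)
    if n == 0:
        return []
    assignments: list[tuple] = []

    def recurse(i: int, chosen: list):
        if i == n:
            assignments.append(tuple(chosen))
            return
        used = {s for s in chosen if s[0] != "sugar"}
        for site in base_sites:
            if site in used:
                continue
            recurse(i + 1, chosen + [site])
        for k in range(i):
            recurse(i + 1, chosen + [("sugar", k)])

    recurse(0, [])
    return assignments
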