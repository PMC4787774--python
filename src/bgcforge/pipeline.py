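"""End-to-end pipeline driver and JSON/SMILES/BED reporting.

Stages: sequence input -> domain annotation (precomputed table or HMM
backend) -> greedy clustering and family retention -> module architecture
(trans-AT/trans-A artificial ORFs, permutations) -> scaffold construction
(NRPS/type I linear, type II chain + tailoring) -> sugar prediction ->
combinatorial plan generation/execution -> genetic and chemical
dereplication -> report. A failure in any per-cluster stage is recorded in
the report without aborting the remaining clusters.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

from bgcforge import __version__
from bgcforge.annotate import (
    Domain,
    DomainModel,
    annotate_domains,
    apply_prerequisite_rules,
    read_annotation_table,
)
from bgcforge.cluster import (
    Cluster,
    build_clusters,
    classify_and_filter,
    export_bed,
)
from bgcforge.comb_engine import (
    DEFAULT_MAX_LIBRARY,
    DEFAULT_MAX_PLANS,
    execute_plans,
    generate_plans,
)
from bgcforge.chem_scaffold import (
    apply_type2_tailoring,
    build_linear_scaffold,
    build_type2_chain,
)
from bgcforge.derep import (
    ArtificialDerepOrf,
    dereplicate_chemical,
    dereplicate_genetic,
    make_artificial_orf,
    read_compound_db,
)
from bgcforge.errors import ConfigurationError
from bgcforge.families import DEOXYSUGAR_GENE_FAMILIES, is_resistance_family
from bgcforge.modules_arch import (
    active_module_sequence,
    assign_adenylation_activity,
    build_modular_orfs,
    build_trans_at_orfs,
    generate_orf_permutations,
    identify_modules,
    insert_trans_a_modules,
)
from bgcforge.refdata import MonomerLibrary, reaction_registry
from bgcforge.seqio import find_orfs, load_contigs
from bgcforge.sugars import (
    classify_glycosyltransferases,
    predict_sugar_combinations,
)

logger = logging.getLogger(__name__)

#: ORF function labels and their report colors
FUNCTION_COLORS = {
    "scaffold": "#1f77b4",
    "tailoring": "#2ca02c",
    "sugar": "#9467bd",
    "resistance": "#d62728",
    "other": "#7f7f7f",
}

_SCAFFOLD_FAMILIES = {
    "condensation",
    "ketosynthase",
    "adenylation",
    "acyl_adenylating",
    "acyltransferase",
    "thiolation",
    "thioesterase",
    "KS_alpha",
    "chain_length_factor",
    "prolyl_AMP_ligase",
}


@dataclass
class RunConfig:
    input_path: str
    annotation_table: Optional[str] = None
    models: Optional[list] = None  # DomainModel library for the HMM backend
    max_library: int = DEFAULT_MAX_LIBRARY
    max_plans: int = DEFAULT_MAX_PLANS
    window: int = 20000
    seed: int = 0
    tanimoto_cutoff: float = 0.0
    homology_cutoff: float = 0.0
    top_k: int = 10
    derep_enabled: bool = True
    compound_db: Optional[str] = None
    cluster_db: Optional[list] = None  # list of ArtificialDerepOrf
    anchors: Optional[dict] = None
    monomers: Optional[MonomerLibrary] = None
    glyco_code: Optional[dict] = None

    def __post_init__(self):
        for name in ("max_library", "max_plans", "window", "top_k"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.tanimoto_cutoff <= 1.0:
            raise ConfigurationError("tanimoto_cutoff must be in [0, 1]")


def _orf_function(cluster: Cluster, orf_id: str) -> str:
    fams = {d.family for d in cluster.domains_on(orf_id)}
    if fams & _SCAFFOLD_FAMILIES:
        return "scaffold"
    if any(is_resistance_family(f) for f in fams):
        return "resistance"
    if any(f in DEOXYSUGAR_GENE_FAMILIES or "glycosyltransferase" in f for f in fams):
        return "sugar"
    if fams:
        return "tailoring"
    return "other"


def _thiotemplated_scaffolds(cluster: Cluster, config: RunConfig, monomers):
    """Base scaffolds (one per plausible permutation) for a thiotemplated
    cluster, plus the permutation count."""
    modules = identify_modules(cluster)
    modules = assign_adenylation_activity(cluster, modules)
    orfs = build_modular_orfs(cluster, modules)
    orfs = build_trans_at_orfs(orfs)
    variants = insert_trans_a_modules(orfs)
    fams = frozenset(cluster.domain_families)
    scaffolds = []
    n_perms = 0
    for variant in variants:
        perms = generate_orf_permutations(variant, seed=config.seed)
        n_perms += len(perms)
        for perm in perms:
            seq = active_module_sequence(perm)
            if not seq:
                continue
            try:
                scaffolds.append(build_linear_scaffold(seq, monomers, fams))
            except Exception as exc:
                logger.warning(
                    "%s: permutation failed to build: %s", cluster.id, exc
                )
    return scaffolds, n_perms, modules


def _type2_scaffolds(cluster: Cluster, monomers):
    chain = build_type2_chain(cluster, monomers)
    return apply_type2_tailoring(chain, cluster), chain


def _cluster_tailoring(cluster: Cluster) -> list[tuple]:
    """(reaction, triggering domain) pairs; sugar attachment is handled by
    the sugar component, so glycosyltransferase triggers are excluded."""
    pairs = []
    for reaction in reaction_registry():
        if reaction.trigger in ("glycosyltransferase", "c_glycosyltransferase"):
            continue
        for domain in cluster.domains:
            if domain.family == reaction.trigger:
                pairs.append((reaction, domain))
    return pairs


def analyze_cluster(cluster: Cluster, config: RunConfig) -> dict:
    """Run the structure-prediction and dereplication stages for one
    retained cluster; returns the per-cluster report entry."""
    monomers = config.monomers or MonomerLibrary()
    from bgcforge.refdata import GLYCO_CODE

    glyco_code = config.glyco_code or GLYCO_CODE
    entry: dict = {
        "id": cluster.id,
        "contig": cluster.contig_id,
        "start": cluster.start,
        "end": cluster.end,
        "families": sorted(cluster.families),
        "retained": cluster.retained,
        "orfs": [
            {
                "id": o.id,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "function": _orf_function(cluster, o.id),
                "color": FUNCTION_COLORS[_orf_function(cluster, o.id)],
                "domains": [
                    {
                        "family": d.family,
                        "start_aa": d.start_aa,
                        "end_aa": d.end_aa,
                        "score": d.score,
                        "functional_subtype": d.functional_subtype,
                        "substrates": [list(s) for s in d.substrates],
                    }
                    for d in cluster.domains_on(o.id)
                ],
            }
            for o in cluster.orfs
        ],
        "modules": [],
        "accounting": {},
        "scaffolds": [],
        "genetic_dereplication": [],
        "chemical_dereplication": [],
        "errors": [],
    }
    if not cluster.structure_capable:
        entry["errors"].append("no structure prediction for this family")
        return entry

    cluster.domains = apply_prerequisite_rules(
        cluster.domains, cluster.domain_families
    )

    try:
        if "thiotemplated" in cluster.families:
            scaffolds, n_perms, modules = _thiotemplated_scaffolds(
                cluster, config, monomers
            )
            entry["modules"] = [
                {"type": m.type, "substrate": m.substrate, "active": m.active}
                for m in modules
            ]
        else:  # type II PKS
            scaffolds, _chain = _type2_scaffolds(cluster, monomers)
            n_perms = 1
            entry["modules"] = [{"type": "type2_unit", "substrate": "malonate",
                                 "active": True}]
    except Exception as exc:
        entry["errors"].append(f"scaffold stage failed: {exc}")
        return entry
    if not scaffolds:
        entry["errors"].append("no buildable scaffold")
        return entry

    gt_domains = [
        d
        for d in cluster.domains
        if d.family in ("glycosyltransferase", "c_glycosyltransferase")
    ]
    hexose, deoxy, c_glyco = classify_glycosyltransferases(gt_domains)
    observed = cluster.domain_families & DEOXYSUGAR_GENE_FAMILIES
    hexose_names = [
        d.annotations.get("substrate") or "glucose" for d in hexose
    ]
    sugar_combos = predict_sugar_combinations(
        len(deoxy),
        observed,
        glyco_code,
        seed=config.seed,
        hexose_sugars=hexose_names,
    )

    tailoring = _cluster_tailoring(cluster)
    plans, accounting = generate_plans(
        scaffolds,
        cluster,
        sugar_combos,
        tailoring,
        max_plans=config.max_plans,
        seed=config.seed,
        allow_c_glycosylation=bool(c_glyco),
    )
    accounting["permutations"] = n_perms
    library = execute_plans(
        plans,
        scaffolds,
        monomers,
        max_library=config.max_library,
        seed=config.seed,
    )
    entry["accounting"] = accounting
    entry["library_reaction_count"] = library.reaction_count
    entry["scaffolds"] = library.smiles
    logger.info(
        "%s: %d permutations, %d cyclizations, %d sugar combinations, "
        "%d reaction plans, %d total plans, %d scaffolds",
        cluster.id,
        accounting["permutations"],
        accounting["cyclizations"],
        accounting["sugar_combinations"],
        accounting["tailoring_reaction_plans"],
        accounting["total_plans"],
        len(library.scaffolds),
    )

    if config.derep_enabled:
        if config.cluster_db:
            try:
                query = make_artificial_orf(cluster, config.anchors)
                hits = dereplicate_genetic(query, config.cluster_db)
                entry["genetic_dereplication"] = [
                    {
                        "reference": h.reference_cluster_id,
                        "score": round(float(h.score), 4),
                        "coverage": round(float(h.coverage), 4),
                        "orf_identity": round(float(h.orf_identity), 2),
                    }
                    for h in hits[: config.top_k]
                    if h.score >= config.homology_cutoff
                ]
            except Exception as exc:
                entry["errors"].append(f"genetic dereplication failed: {exc}")
        if config.compound_db and library.scaffolds:
            compounds = read_compound_db(config.compound_db)
            hits = dereplicate_chemical(library, compounds, top_k=config.top_k)
            entry["chemical_dereplication"] = [
                {
                    "compound": h.compound_id,
                    "name": h.compound_name,
                    "ecfp6_tanimoto": round(h.ecfp6_tanimoto, 4),
                    "fcfp6_tanimoto": round(h.fcfp6_tanimoto, 4),
                }
                for h in hits
                if h.ecfp6_tanimoto >= config.tanimoto_cutoff
            ]
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report (JSON-serializable)."""
    monomers = config.monomers or MonomerLibrary()
    # configuration errors must surface before any stage runs
    if config.annotation_table is None and not config.models:
        raise ConfigurationError(
            "no annotation backend: provide an annotation table or a domain "
            "model library"
        )
    if config.annotation_table is not None and not os.path.exists(
        config.annotation_table
    ):
        raise ConfigurationError(
            f"annotation table not found: {config.annotation_table}"
        )
    contigs = load_contigs(config.input_path)
    orfs = [o for c in contigs for o in find_orfs(c)]
    if config.annotation_table is not None:
        domains = read_annotation_table(config.annotation_table)
        known = {o.id for o in orfs}
        missing = {d.orf_id for d in domains} - known
        if missing:
            logger.warning(
                "annotation table references unknown ORFs: %s",
                ", ".join(sorted(missing)),
            )
        domains = [d for d in domains if d.orf_id in known]
        by_orf = {o.id: o for o in orfs}
        for d in domains:
            if not d.sequence:
                d.sequence = by_orf[d.orf_id].protein[d.start_aa - 1 : d.end_aa]
    else:
        domains = annotate_domains(orfs, config.models)
    clusters = build_clusters(domains, orfs, window=config.window)
    clusters = [classify_and_filter(c) for c in clusters]
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "input": os.path.basename(config.input_path),
            "window": config.window,
            "max_plans": config.max_plans,
            "max_library": config.max_library,
            "derep_enabled": config.derep_enabled,
        },
        "n_contigs": len(contigs),
        "n_orfs": len(orfs),
        "n_domains": len(domains),
        "clusters": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for cl in clusters:
        if not cl.retained:
            report["clusters"].append(
                {
                    "id": cl.id,
                    "contig": cl.contig_id,
                    "families": sorted(cl.families),
                    "retained": False,
                }
            )
            continue
        try:
            report["clusters"].append(analyze_cluster(cl, config))
        except Exception as exc:  # stage failure must not abort other clusters
            logger.exception("cluster %s failed", cl.id)
            report["clusters"].append(
                {"id": cl.id, "retained": True, "errors": [str(exc)]}
            )
    report["_cluster_objects"] = clusters  # stripped before serialization
    return report


def write_report(report: dict, out_dir: str) -> list[str]:
    """Write report.json, per-cluster SMILES files, and the BED-like TSV.

    Content is deterministic under a fixed seed; the timestamp is the only
    nondeterministic field.
    """
    os.makedirs(out_dir, exist_ok=True)
    clusters = report.pop("_cluster_objects", [])
    written = []
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)
    for entry in report["clusters"]:
        smiles = entry.get("scaffolds") or []
        if not smiles:
            continue
        spath = os.path.join(out_dir, f"{entry['id']}.smiles")
        with open(spath, "w") as fh:
            for i, smi in enumerate(smiles):
                fh.write(f"{smi}\t{entry['id']}_scaffold{i + 1}\n")
        written.append(spath)
    if clusters:
        bpath = os.path.join(out_dir, "clusters.bed")
        with open(bpath, "w") as fh:
            fh.write(export_bed(clusters))
        written.append(bpath)
    return written
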