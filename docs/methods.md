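# Methods

## Scope and model

`bgcforge` predicts chemical structures for thiotemplated (NRPS, type I PKS,
hybrid) and type II PKS biosynthetic gene clusters under the colinearity
assumption: adjacent domains form modules, each module adds one monomer, and
the module order (after accounting for trans-acting domains and ORF
permutations) dictates the backbone. Enediyne and fungal iterative type I
clusters are identified by their marker domains but no structure is
predicted for them; the same holds for any iterative logic. Where biology is
underdetermined — tailoring-enzyme substrates, macrocyclization points,
deoxysugar identities, ORF order — the engine enumerates all interpretations
consistent with the observed domain complement rather than guessing one, and
caps the enumeration (below).

Stereochemistry is never predicted; every emitted SMILES is achiral.
Epimerization domains therefore have no structural effect.

## Pipeline stages and the decisions behind them

**ORF calling.** Stop-to-stop scanning on six frames, start codons
ATG/GTG/TTG, minimum 60 aa, bacterial translation table, N → X. This is a
deliberately simple caller: the package's contribution is downstream of gene
calling, and the precomputed-annotation-table backend lets any external
caller/annotator substitute for both the caller and the HMM search. Contigs
< 500 nt are dropped, at most the 1000 largest contigs are analyzed (ties at
the cutoff keep input order), and input files over 50 MB are rejected.

**Annotation.** Two interchangeable backends: pyhmmer searches over a
profile library with per-model bitscore cutoffs, or a TSV of precomputed
domain calls (`orf_id, family, start_aa, end_aa, score, functional_subtype,
substrates, annotations`). Overlapping same-family hits on one ORF resolve
to the best score. Refinement of C/KS/chlorinase/GT/priming-AT/CLF calls
uses in-process local protein alignment (BLOSUM62, open −11 / extend −1)
against annotated reference records, copying the best reference's payload
and keeping the full ranked list for fallback logic; ties break to the
lexicographically first reference id. Substrate prediction ranks
substrate-specific profiles by bitscore (alphabetical on ties); acyl-
adenylating domains are scored only against acyl profiles, never amino-acid
profiles. Rare substrates (methoxymalonate, capreomycidine,
diaminopropionate, 3-hydroxypipecolate, 3-hydroxyanthranilate) are demoted
below the next ungated substrate — never removed — unless all their
prerequisite biosynthesis families are present in the cluster.

**Clustering.** Greedy window expansion (default 20 000 bp) seeded on
bond-forming domains; distances are measured between domain-bearing ORF
boundaries. Only bond-forming domains trigger boundary extension;
non-bond-forming (and resistance) ORFs inside the window are attached in the
final round. Clusters never span contigs.

**Module architecture.** The ten module types follow the span definitions
(C…A/AL…T|TE; KS…AT…T|TE; C–T and KS…T insertion didomains; A/AL–T
didomains heading their ORF; standalone AL and prolyl-AMP ligases; starter
condensations; the KSα/CLF type II unit). Activity rules: lone A-domain ORFs
inactive; A–T didomains active, acting in trans iff the cluster holds a C–T
didomain (otherwise initiating); ORF-terminal C–A didomains active; with
several AL ligases, exactly one initiates per permutation and the rest are
skipped from the backbone. Split trans-AT insertion modules are joined
across consecutive ORFs recursively (a leading carrier fragment on the
downstream ORF completes the upstream KS span); all trans-acting ATs select
malonyl-CoA. Trans-A splicing enumerates permutations of trans-A modules ×
injective assignments to insertion sites, deduplicated; the donor module is
spliced after the insertion module's condensation domain and deactivated at
its source.

**ORF permutations.** An ORF with a module ending in a thioesterase must be
last; an ORF with a starter-condensation, ligase, decarboxylative-KS or
initiating-adenylation module must be first. If all scaffold ORFs share one
frame (same strand and codon phase) and genomic order satisfies the
constraints, only that order is used. Otherwise all constraint-satisfying
orderings are enumerated; at ≥ 7! (5040) candidates a pseudorandom sample of
500 distinct orderings is drawn — uniformly over the valid set, seed 0 by
default (the sampling seed is fixed for reproducibility; the spec of valid
orderings is checked by a generator-independent predicate in the tests).
Contradictory constraints fall back to genomic order with a warning.

**Scaffold chemistry.** Monomers are reference data (name → achiral SMILES
with labelled head/tail attachment atoms; ~80 entries covering the
proteinogenic and named nonproteinogenic amino acids, ketide extenders, acyl
and aryl starters, hydroxy acids and sugars). Unknown substrate names raise
an error rather than guessing. Condensation removes the tail hydroxyl and
bonds tail to head (amide, ester, or C–C for ketides; ketide condensation
loses the malonyl carboxylate by construction of the extender unit).
Module-local tailoring is applied during elaboration: the reductive loop
sets the β-position (KR → hydroxyl, KR+DH → enoyl, KR+DH+ER → methylene; DH
or ER without KR is inconsistent input and stays β-keto with a warning),
N/C/O-methyltransferases methylate the amide nitrogen, α-carbon, or first
free side-chain hydroxyl, and heterocyclization condensations convert
Cys/Ser onto the preceding amide into thiazolines/oxazolines (oxidized to
the aromatic azole when the cluster has a nitroreductase). A
tryptophan-dioxygenase in the cluster rewrites tryptophan residues to
kynurenine at assembly time, which is equivalent to a post-assembly edit at
scaffold level and much simpler on the graph.

**Type II PKS.** Chain length comes from the CLF annotation (single most
homologous reference); the chain is the starter plus that many C2 β-keto
units, numbered from the terminal acyl carbon (C1). Starters other than
acetate require a priming AT annotation, and benzoate/malonamate
additionally require a phenylalanine ammonia-lyase/amidotransferase;
acyl-adenylating ligases are inactive when a priming AT is present.
Regiospecific tailoring acts at single clade-determined carbons (C9/C11/…
ketoreductases; C6/C8/C10 C-MTs; the C2 reaction is N,N-dimethylation iff
nitrogen is present at C2, else O-methylation). The cyclase clade →
ring-closure table is **provisional**: it encodes first/second/third-ring
aldol closures as carbon-number pairs, with the polyphyletic clade VIb
resolved through the CLF annotation; the authoritative topologies live in
the cyclase phylogeny literature, and rings are left as non-aromatized
cyclic aldols (closure bond + carbonyl→hydroxyl) rather than fully
dehydrated aromatic systems. A clade without a table entry leaves the chain
uncyclized with a warning. Type II chains are not macrocyclized (release is
hydrolytic; ring formation is the cyclases' job).

**Tailoring reactions.** The registry is data-driven (name, trigger
family/subtype, site rule, graph edit); the concretely described reactions
are implemented (hydroxyl-directed glycosylation/sulfation/carbamoylation/
phosphorylation, ranked-fallback chlorination, position-specific glycopeptide
P450 cross-links, isopenicillin-N synthase/acyltransferase and the
penam→cephem ring expansion, N-formylation, kynurenine and pyrrole
conversions, C-glycosylation at two-bond aromatic α-carbons), and the
remaining registry slots up to the nominal 54 are explicit provisional
placeholders that never fire. Sites are referenced by stable atom uids, so a
site consumed by an earlier edit fails cleanly at execution with no partial
edit. "Free hydroxyl" means an sp3 O–H that is neither a carboxyl nor a
phenol nor already substituted. Chlorinases try their ranked substrate
classes in order and halt at the first class with ≥ 1 site; one site per
chlorinase domain (iteratively acting halogenases are not modelled).

**Macrocyclization.** One pattern per eligible nucleophile (free hydroxyls
and the free N-terminal amine) plus the linear acid; a C-terminal reductase
domain instead yields exactly the linear aldehyde and the cyclic imine. A
nucleophile must be ≥ 5 atoms from the terminal acyl carbon along the graph
— closer nucleophiles would give 3- or 4-membered lactones/lactams, which
thioesterases do not form.

**Combinatorial engine.** Plans are the Cartesian product permutation ×
cyclization × (sugar combination, attachment assignment) × reaction-site
choices, iterated in that fixed order for reproducibility; above 1000 plans
a seeded pseudorandom subset of exactly 1000 is kept (sampling, by symmetry
with the library cap, as the cap's behaviour is otherwise unspecified).
Execution order is reactions → sugars → cyclization; any failed event
discards the plan. The library keeps scaffolds only at its current maximal
reaction count (sugar attachments and tailoring reactions count; chain
release does not), resets whenever a richer scaffold appears, deduplicates
canonical SMILES before counting, and stops at 50 scaffolds, processing
plans in a seeded pseudorandom order when more plans exist than fit. All
randomness uses Python's Mersenne-Twister `random.Random` with seed 0 by
default — a documented portable PRNG; determinism, not bit-compatibility
with any other implementation, is the contract.

**Deoxysugar prediction.** Deoxysugar GT count = sugar count. Candidate
multisets are exhaustive below four GTs and a seeded set of exactly 2500
draws otherwise. Scoring counts genes observed-but-not-required and
required-but-not-observed against the union of the combination's pathways
(shared enzymes count once). "Minimize both" is implemented as lexicographic
minimization of (total mismatch, missing-gene count): when a simultaneous
minimizer of both counts exists this retains exactly the simultaneous
minimizers, and otherwise picks the balanced optimum; a log line notes the
degenerate case. Retention is capped at 100 (lowest total first, then
lexicographic names); identified hexoses (glucose, mannose, gulose,
N-acetylglucosamine from GT refinement) are appended to every retained
combination. Attachment assignments map each sugar to a free hydroxyl, a
permitted aromatic carbon (C-GTs only), or a hydroxyl of an earlier sugar
(oligosaccharides); double-claimed scaffold sites are excluded. Redundant or
inactive GTs break the count assumption and are knowingly not corrected.

**Dereplication.** Genetic: bond-forming domains grouped by family in
alphabetical order ("arbitrary but consistent"), within-family by descending
alignment bitscore to a per-family anchor (ties by locus order),
concatenated without separators; query vs reference local alignment score ÷
aligned residues, hits under 25 % query coverage dropped. The reported ORF
identity is the alignment-length-weighted mean identity of per-domain best
alignments — the weighting scheme was left open by the source material and
this choice is provisional. Chemical: 1024-bit hashed circular fingerprints
of radius 3 (ECFP6; FCFP6 via feature invariants), pairs ranked by
descending ECFP6 Tanimoto with deterministic tie-breaks.

## Parameter defaults

| parameter | default | unit | why |
|---|---|---|---|
| min contig length | 500 | nt | shorter contigs cannot hold a domain worth calling |
| max contigs | 1000 | — | input cap for large assemblies |
| min ORF length | 60 | aa | shortest plausible standalone domain fragment |
| cluster window | 20 000 | bp | intergenic reach of the greedy expansion |
| permutation cap | 7! → 500 sampled | orderings | keeps the plan space bounded |
| sugar sampling | ≥ 4 GTs → 2500 draws | multisets | exhaustive space grows combinatorially |
| retained sugar combos | 100 | — | cap on tied minimizers |
| plan cap | 1000 | plans/cluster | bounds execution cost |
| library cap | 50 | scaffolds | bounds reported structures |
| derep coverage | 0.25 | fraction | below this an alignment is a domain-level, not cluster-level, match |
| fingerprints | 1024 bits, radius 3 | — | ECFP6/FCFP6 convention |
| seeds | 0 | — | all sampling reproducible by default |
| fixture HMM cutoff | 25 | bits | arbitrary but documented; real per-model cutoffs require curation |

## Synthetic data: what it does and does not show

The fixture bundle emulates the *shapes* the pipeline must handle: domain
layouts per ORF, gene order and spacing, frame agreement, split modules,
annotation metadata (CLF extension counts, chlorinase substrate classes,
sugar-gene complements) and the ambiguities that drive combinatorics. Its
profiles are built from eight mutated copies of 60-residue random consensi —
they test the search plumbing, not remote-homology sensitivity; its DNA is
reverse-translated with a fixed codon table and A/C-only filler — it tests
coordinate bookkeeping, not gene finding in real genomic context; its
glycogenetic code is a 10-sugar curated subset of the 63-sugar concept.
Passing tests therefore demonstrate that the combinatorial logic, the
chemistry, and the accounting are correct on inputs whose ground truth is
known exactly; they do not demonstrate detection performance on real
genomes, which depends entirely on the curated model library a deployment
supplies.

Problem sizes throughout the suite (genomes of ≤ 10 genes, libraries of ≤ a
few hundred plans) are chosen so the full suite runs in seconds; every cap
(500/1000/2500/100/50) is still exercised at its exact boundary.

## Known limitations

- No iterative type I, enediyne, fungal PKS, RiPP, terpenoid or alkaloid
  structures; no docking-domain ordering.
- The cyclase ring-pattern table and several registry slots are provisional;
  type II oxygenase regiochemistry beyond the named clades is not predicted,
  and the favorskiiase applies no graph edit.
- Sugar acylation, iterative halogenation, and trans-supplied reductive-loop
  activities are not modelled.
- One structural interpretation per plan; no scoring of plan plausibility
  beyond the reaction-count filter.
- The annotation-table backend trusts its input: garbage families error, but
  biologically inconsistent layouts are interpreted literally.
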