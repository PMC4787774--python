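# bgcforge

Genome mining and combinatorial structure prediction for microbial natural
products.

Bacteria and fungi encode nonribosomal peptides (NRPs) and polyketides (PKs)
— the chemical families behind most clinical antibiotics — in biosynthetic
gene clusters (BGCs): co-located genes for modular assembly-line enzymes
(NRPS/PKS megasynthases), tailoring enzymes, sugar biosynthesis genes and
resistance determinants. `bgcforge` is for genome miners who want to go from
a nucleotide sequence to *chemical structures*: it detects NRPS and type
I/II PKS clusters, enumerates every assembly-line interpretation consistent
with biosynthetic logic, executes each interpretation into a predicted
molecule (SMILES), and dereplicates the results against cluster and compound
databases so that known metabolites can be recognized and novel ones
prioritized.

## The method

1. **ORFs and domains.** All six-frame ORFs (stop-to-stop, ATG/GTG/TTG
   starts, ≥ 60 aa) are translated and scanned either with a profile-HMM
   library (pyhmmer) or a precomputed annotation table. Contigs under 500 nt
   are discarded; only the 1000 largest contigs are analyzed. Condensation
   (C), ketosynthase (KS), chlorinase, glycosyltransferase (GT), priming-AT
   and chain-length-factor (CLF) calls are refined against curated annotated
   references by local protein alignment; adenylation (A), acyl-adenylating
   (AL) and acyltransferase (AT) domains get ranked substrate predictions,
   with rare substrates (e.g. methoxymalonate) demoted unless their
   biosynthesis genes are present.
2. **Clusters.** A greedy algorithm seeds on bond-forming domains (C/KS) and
   expands in a 20 kb window; thiotemplated clusters are retained iff they
   hold ≥ 1 substrate-activating (A/AL/AT) and ≥ 1 bond-forming (C/KS)
   domain, type II PKS clusters iff they hold both a KSα and a CLF.
   Resistance genes are attached but never extend a cluster.
3. **Module architecture.** Ten module types (C–A–T elongation, trans-A and
   trans-AT insertion modules, starter condensations, standalone ligases,
   the minimal type II PKS, …) are identified; insertion modules split
   across ORFs are joined into artificial ORFs recursively; all
   biosynthetically plausible ORF permutations are generated (genomic order
   when all scaffold ORFs share a frame and the order is plausible; a seeded
   sample of 500 once the count reaches 7!).
4. **Combinatorial scaffolds.** Each plan = one module permutation × one
   macrocyclization × one sugar combination/attachment × one set of
   tailoring-reaction site choices (≤ 1000 plans/cluster). Deoxysugars are
   predicted by matching the observed sugar-gene complement against a
   glycogenetic code (exhaustive below 4 GTs, 2500 sampled combinations
   otherwise, ≤ 100 minimal combinations retained). Executed scaffolds are
   kept only at the library's maximal successfully-executed-reaction count,
   deduplicated, and capped at 50.
5. **Dereplication.** Genetically: bond-forming domains are concatenated in
   a fixed family order (MLST-style) and locally aligned against a cluster
   database (score ÷ aligned residues, ≥ 25 % query coverage). Chemically:
   1024-bit ECFP6/FCFP6 fingerprints, ranked by ECFP6 Tanimoto.

## Worked example

All reference data ship as seed-deterministic synthetic fixtures — the
`fixtures` subcommand writes six annotated test genomes plus the reference
tables, including a flagship NRPS cluster (acyl starter, Ser/Thr/Cys/Ser/Tyr
modules with a heterocyclization, a chlorinase, one deoxysugar GT with a
two-sugar-ambiguous gene complement):

```sh
$ bgcforge fixtures --seed 0 --out refdata
wrote 6 genomes, 28 domain models, 22 compounds to refdata

$ bgcforge --verbose predict refdata/flagship.fasta \
    -t refdata/flagship.annotation.tsv \
    --compound-db refdata/compounds.tsv -o out
INFO bgcforge.pipeline: cluster1: 1 permutations, 4 cyclizations, 2 sugar combinations, 1 reaction plans, 24 total plans, 9 scaffolds
1 cluster(s), 1 retained; report written to out/report.json
```

The accounting line is the combinatorial bookkeeping: one ORF permutation
(both scaffold ORFs share a frame and genomic order is plausible), four
release patterns (three macrolactones + the linear acid), two candidate
deoxysugars for the lone GT × three free-hydroxyl attachment sites, and one
chlorination site — 1 × 4 × 6 × 1 = 24 combinatorial plans. Plans whose
events collide (glycosylation and macrolactonization at the same hydroxyl)
fail and are discarded; the nine surviving distinct structures appear in
`out/cluster1.smiles`, e.g.

```
CC(C)CC(=O)NC1COC(=O)C(Cc2ccc(O)cc2Cl)NC(=O)C(CO)NC(=O)C2CSC(=N2)C(C(C)OC2CC(O)C(O)C(C)O2)NC1=O
```

— the isovaleryl-capped pentapeptide with its thiazoline, the chlorinated
tyrosine, one 2,6-dideoxysugar on a side-chain hydroxyl, and one of the
three macrolactones. `out/report.json` carries the full per-cluster report
(ORFs with function labels, modules, accounting, scaffolds, dereplication
hits); `out/clusters.bed` summarizes cluster coordinates.

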