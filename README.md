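# orthoprof

Ortholog assignment and phylogenetic profiling of protein families across
eukaryotic proteomes — built for the kind of question peroxisome biology
keeps asking: *which species have which PEX proteins, which apparent absences
are secondary losses, and which "new" family members are just lineage-
specific duplicates of old ones?* The package is family-agnostic: it takes
per-species protein FASTA files, a species table assigning each species to a
eukaryotic supergroup (Opisthokonta, Amoebozoa, Archaeplastida, SAR,
Excavata), and seed sequences per family.

It is aimed at comparative genomicists and organelle biologists who want a
reproducible, inspectable version of a workflow usually stitched together
from search tools, aligners and hand curation.

## What it computes

**Ortholog assignment** runs two reciprocal-search routes per family and
seed organism and reconciles them:

- *Approach A*: reciprocal single-sequence search. Seed → target proteome;
  the best hit must find the seed back at the acceptance E-value. If
  full-sequence reciprocity fails (multidomain fusions), the target protein
  with the best **domain** E-value is retried using only its domain segment —
  the `domain_fallback` route.
- *Approach B*: reciprocal iterative profile search (PSSM grown from the
  seed over two rounds with an inclusion E-value, scanned both ways).
  Family classes set the stringency: `tm_or_repeat` → 2 iterations at a
  relaxed E = 1e-2; `common_domain` → 2 iterations at a constrained
  E = 1e-20; `default` → 1e-3.

Candidates are merged (agreement → consensus; disagreement → flagged), an
alignment-identity outlier filter replaces manual inspection (robust z-score
on median pairwise identity, cutoff −2.5), and species left uncovered get a
one-directional profile **recovery** pass, flagged distinctly.

E-values follow `E(S) = κ·m·n·e^(−λS)`, with (λ, κ) fitted per database by a
Gumbel fit to maximal local scores of seeded shuffled pairs — valid for
gapped sequence scores and profile scores alike.

**Feature annotation** reproduces the usual family-table columns:
transmembrane segments (19-residue Kyte–Doolittle windows > 1.6), intrinsic
disorder (logistic blend of charge, flexibility and hydropathy over
21-residue windows), domain architecture from user profiles, the C-terminal
CaaX box (`C-[AVIL]-[AVIL]-[STQAM]`, final four residues only), WxxxF/Y
motifs, conserved N-terminal cysteines, and amphipathic helices by the
hydrophobic moment μH = |Σ h_k·e^(ik·100°)|/N on the Eisenberg scale.

**Phylogenetic profiling** turns kept assignments into a Coulson-style
presence/absence matrix with distribution labels (`Eukaryotes`, `Fungi`,
`Amoebozoa/SAR`, ...), reconstructs gains and losses under Dollo parsimony
(one gain at the MRCA of present species, minimal losses below it), and
classifies duplications on midpoint-rooted bootstrap NJ gene trees by the
species-overlap rule — **deep** paralogs (both child clades span ≥2
supergroups, i.e. the duplication predates eukaryote diversification)
vs **in-paralogs** (restricted to a named clade).

**Synthetic proteomes with ground truth.** A first-class simulator evolves
families along random supergroup-labeled species trees (Gillespie
duplication/loss, BLOSUM62-derived substitutions, clade-restricted domain
blocks, planted motifs, Markov decoys) and logs every event — so every stage
of the pipeline is benchmarked against known truth, offline.

## A worked example

`examples/03_reciprocal_orthology.py` simulates five species across four
supergroups, evolves one family at substitution scale 0.5, adds six decoys
per species, and runs the full assignment from one seed gene:

```
species        gene sources confidence status
  AMO01 fam_AMO01_1     A+B  consensus   kept
  EXC01 fam_EXC01_1     A+B  consensus   kept
  OPI01 fam_OPI01_1     A+B  consensus   kept
  OPI02 fam_OPI02_1     A+B  consensus   kept
  SAR01 fam_SAR01_1     A+B  consensus   kept

5/5 kept assignments match simulator truth (true family size: 5 genes)
```

Every species' true ortholog was found independently by both approaches
(`sources A+B`, `confidence consensus`) and survived the alignment filter;
no decoy was assigned. The other scripts under `examples/` walk through the
simulator, the search engine and E-value calibration, feature annotation,
phylogenetic profiling, and the end-to-end YAML-configured pipeline (also
available as a CLI: `orthoprof run-all -c config.yaml`).

## Layout

```
src/orthoprof/
  core.py        species metadata, proteome container, alphabet
  seqsim.py      synthetic species trees, family evolution, ground truth
  searchcore.py  alignment engine, E-value calibration, profiles
  alignment.py   MSA container, center-star multiple alignment
  orthology.py   reciprocal searches, consensus, filter, recovery
  protfeat.py    TM / disorder / domains / motifs / helices
  phyloprof.py   distances, NJ, bootstrap, midpoint, Dollo, paralog calls
  benchmark.py   the default benchmark grid and evaluation metrics
  workbench.py   YAML config, staged pipeline, persistence, Coulson output
  cli.py         thin command-line interface
```

Methodological details, defaults and limitations: `docs/methods.md`.
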