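# Methods

`orthoprof` implements a comparative-genomics workflow for mapping a set of
protein families — motivated by the peroxins (PEX proteins) of peroxisome
biogenesis, but family-agnostic — across eukaryotic proteomes: find each
family's orthologs in every species, annotate the proteins' structural
features, and read the resulting presence/absence patterns phylogenetically.
This note records the models, the parameters that matter, and the places
where the design was genuinely open.

## Ortholog assignment

Orthology is called by reciprocal search, run through two independent routes
and reconciled:

**Approach A — reciprocal single-sequence search.** The seed gene is searched
against the target proteome; the best hit is searched back against the source
proteome. Reciprocity holds when the return search ranks the seed first, with
both E-values at or below the family's acceptance threshold. Because many of
the motivating proteins are multidomain, a failed full-sequence reciprocity
triggers a fallback: the target protein with the best *single-domain* E-value
is taken, and only its domain segment is searched back. A fusion protein whose
second domain drags the full-sequence return search toward an unrelated
protein is thereby still recovered, flagged `domain_fallback`.

**Approach B — reciprocal iterative profile search.** A position-specific
profile is grown from the seed inside the source proteome (round one is the
seed alone; each further round scans the proteome and folds hits at or below
the inclusion E-value into the alignment, rebuilding the profile). The profile
scans the target; the best accepted hit must reciprocate by the same
profile-iteration procedure run from its side. Profiles detect divergent
orthologs single sequences miss, but misbehave on promiscuous domains, which
is what the threshold classes are for.

**Threshold policy classes.** Families declare one of three classes:

| class | iterations | inclusion / acceptance E |
|---|---|---|
| `tm_or_repeat` | 2 | 1e-2 (relaxed — TM and tandem-repeat families align poorly) |
| `common_domain` | 2 | 1e-20 (constrained — keeps widespread domains from flooding the profile) |
| `default` | 2 | 1e-3 |

**Consensus.** Per species: agreement of A and B yields a `consensus`
assignment; one succeeding method yields a provisional `single_method`
assignment; disagreement emits both candidates flagged for the filter. The
union-then-filter rule (rather than strict intersection) maximizes recall and
routes ambiguity to the explicit filtering stage; an `agreement` mode is
available as a config switch.

**Alignment filter.** As a reproducible surrogate for visual inspection of
the family alignment, all kept candidates are multiply aligned; each
sequence's median pairwise identity to the rest is computed; robust z-scores
(median/MAD) below −2.5 mark removals, after which the set is re-aligned once
and re-tested. The robust scale is floored at 0.05 (five identity points):
in a tight family the MAD collapses toward zero and ordinary divergence must
not read as an outlier. Conflicting duplicate candidates for one species are
resolved toward the higher-identity candidate. Seed genes are never removed.

**Recovery.** Species left with no kept assignment get a one-directional
sensitivity pass: a profile built from the kept members' alignment scans the
suspect proteome, and the best hit at the family's acceptance E-value is
admitted with confidence `recovered`. Reciprocity is deliberately not
required here; the distinct flag preserves auditability.

## The search engine

The engine is a self-contained substitute for a profile-HMM package, with the
same interface contracts (full-sequence vs best-domain E-values, iterative
inclusion); the assignment logic above is the analytical substance and is
engine-agnostic. An easy-family cross-check against an independent
phmmer implementation is part of the test suite.

- **Alignment.** Affine-gap Smith–Waterman (numba-compiled), BLOSUM62 with
  gap open −11 / extend −1 (community defaults); `X` scores zero. Coordinates
  are 1-based inclusive everywhere. A gap of length k costs
  `open + (k−1)·extend`.
- **Full vs domain score.** The best local segment is the domain score; the
  full-sequence score adds up to two further disjoint segments, each only if
  individually significant (segment E ≤ 0.1). Without that significance gate,
  summed noise segments inflate full scores enough to corrupt profile
  inclusion — this is a load-bearing constant.
- **E-values.** `E(S) = κ·m·n·exp(−λS)` with m the query/profile length and
  n the database residue count. λ and κ come from a Gumbel fit
  (`scipy.stats.gumbel_r`) to maximal local scores of seeded shuffled pairs
  (200 shuffles for sequence scoring, 100 per profile). An empirical fit is
  used instead of analytic Karlin–Altschul because it is equally valid for
  gapped and profile scores. Fits are seeded from the master seed by stable
  hashing, so results are independent of evaluation order.
- **Profiles.** Consensus columns are those with ≤50% gaps. Column scores are
  `2·log2(p/background)` — half-bit log-odds with matrix-informed pseudocounts:
  estimated probabilities `(n·f + α·g)/(n+α)` with `g = f·P(b|a)`,
  `P(b|a) ∝ bg_b·2^(S_ab/2)`, and pseudocount weight α = 2. With a
  single-sequence alignment this reduces to the substitution matrix's own
  preference order, which is the behavior one wants from a seed profile.
  Iterated profiles keep the seed's consensus columns as their coordinate
  system; insertions relative to the profile are dropped.
- **Multiple alignment.** Center-star: the center maximizes summed global
  pairwise scores; others are merged against it under "once a gap, always a
  gap". Every input residue appears exactly once. This is cruder than a
  modern progressive aligner but deterministic, dependency-free, and accurate
  enough for identity-based filtering and profile construction at the
  divergences involved.
- **Ties.** Hits are ranked by ascending full E-value, then descending
  score, then lexicographic target id — determinism everywhere.

## Feature annotation

Transparent windowed heuristics, not reimplementations of dedicated
predictors; the downstream use is presence/absence summaries and planted-
segment benchmarks, and an auditable predictor is worth more there than two
extra points of accuracy. All parameters are exposed.

- **Transmembrane:** Kyte–Doolittle mean over a 19-residue window; windows
  above 1.6 merge into segments; segments under 15 residues are dropped.
- **Disorder:** per-residue logistic score from a 21-residue window:
  `σ(6·(charge_fraction + flexibility − normalized_hydropathy − 0.5))`, with
  a shipped flexibility propensity table; calls are runs ≥10 residues above
  0.5. Borderline proteins keep their raw scores so users can re-cut.
- **Domain architecture:** user-supplied profiles scanned at E ≤ 1e-3,
  overlaps resolved greedily by score, reported in sequence order.
- **Motifs:** CaaX is checked only at the final four residues, `C-a-a-X` with
  a ∈ {A,V,I,L} (the aliphatic set is a config key) and X ∈ {S,T,Q,A,M};
  WxxxF/Y finds all, possibly overlapping, occurrences; the conserved
  N-terminal cysteine scan takes the highest-occupancy Cys column (≥0.9,
  leftmost on ties) within the first 60 consensus columns.
- **Amphipathic helices:** per-residue hydrophobic moment on an ideal
  100°/residue wheel with the Eisenberg consensus scale; windows of 18 with
  μH > 0.35 are reported. Charged-position conservation is computed per
  user-declared subgroup as the K/R fraction per column; empty subgroups are
  reported as missing, never zero.

## Phylogenetic profiling

- **Trees.** Maximum-likelihood inference is deliberately replaced by a
  desk-scale engine: Poisson-corrected p-distance (−ln(1−p), p capped at
  0.95) over mutually ungapped columns, neighbor-joining with lexicographic
  tie-breaking on the Q-matrix, classic column-resampling bootstrap
  (default 100 replicates), and midpoint rooting (diameter-path ties broken
  by the smallest leaf pair). The classification logic consuming the trees is
  the substance; the tree engine is a documented substitution, and trees of
  divergent families should be read with the same caution any distance tree
  deserves.
- **Alignment trimming** drops columns whose gap fraction exceeds 0.5
  (config key), after the fashion of standard gap-trimming tools.
- **Duplication calls.** Species-overlap rule: an internal node of the rooted
  gene tree is a duplication iff its children share species. It is **deep** —
  predating the diversification of the sampled lineages — iff each child
  clade spans ≥2 supergroups; otherwise it is an **in-paralog**, implicated
  in the smallest named clade (species < kingdom < supergroup < Eukaryotes)
  containing the duplicated leaves. This is a testable formalization of the
  informal clade-composition reasoning practitioners apply.
- **Presence matrix.** Cell (family, species) is true iff ≥1 kept assignment
  exists. Distribution labels: present in every supergroup → `Eukaryotes`;
  confined to one kingdom/supergroup → its name; otherwise the sorted list of
  per-supergroup labels (kingdom-resolved inside Opisthokonta).
- **Dollo reconstruction.** One gain at the MRCA of the present species; the
  losses are the branches subtending maximal all-absent subtrees below it —
  the unique minimal single-gain explanation (enumeration-verified in tests).

## The synthetic benchmark

The simulator is first-class code, because every downstream claim is measured
against its ground truth. Families evolve along a random species tree whose
supergroups are monophyletic by construction: per-branch Gillespie birth-death
events (duplication/loss, per-lineage exponential waiting times — chosen for
its closed-form mean `exp((b−d)t)` as an oracle), substitutions drawn per
site from BLOSUM62-derived exchangeabilities (diagonal zeroed) at
class-specific rates, domain blocks with optional clade restriction and fixed
root sequences, motif planting at emission, and order-2 Markov decoys fit to
family composition (harder negatives than uniform noise). Root copies beyond
the first receive extra stem divergence (default 0.6 substitutions/site)
before descending the tree — without a stem, deep paralogs would be
phylogenetically unresolvable, which real deep paralogs are not. Seeds derive
from one master seed by stable (SHA-256) hashing, so per-family streams
survive reordering.

The default benchmark fixes 12 species across the five supergroups (two
kingdoms inside Opisthokonta), 20 families and 8 decoys per species, master
seed 42. The family grid spans: four clean 1:1 families at substitution
scales 0.1–1.0, deep and in-paralog duplication regimes, parasite-biased
loss, a clade-restricted fusion architecture whose partner block also sits
nearly intact in decoys (exercising the domain fallback), a promiscuous
common domain planted divergently in decoys (exercising the 1e-20 class), a
TM/tandem-repeat family (the 1e-2 class), a fungi-restricted family, and
families carrying each planted motif. Benchmark precision is the fraction of
kept assignments whose gene truly belongs to the assigned family and species;
recall is the fraction of truth (family, species) pairs with at least one
correct kept assignment. Paralog-classification accuracy matches each logged
duplication event (with survivors on both sides) to the smallest called
duplication node covering its descendants.

What the simulator does **not** emulate — and hence what green tests do not
certify about real proteomes: indels beyond block boundaries, rate
heterogeneity within a block, domain shuffling beyond planted fusions,
incomplete proteomes, fragmented gene models, and contamination. Real-data
runs should treat borderline E-values and single-method assignments with
correspondingly more suspicion.

## Determinism and scale

Every stochastic step (tree simulation, sequence evolution, decoys, shuffle
calibrations, bootstrap) draws from generators seeded by stable hashes of the
master seed, so a config plus seed reproduces every TSV byte-for-byte; the
provenance block records the config hash and seed needed to do so. The
benchmark sizes (12 species, ~30 proteins each, 250-aa families, 100-150
calibration shuffles, 100 bootstrap replicates) were chosen so a full run
completes in a few minutes on a single CPU while keeping E-value tails and
support values meaningful; they are config keys, not constants.

## Known limitations

- The engine has no forward/backward probabilistic scoring; E-values are
  shuffle-calibrated and coarser than a mature HMM implementation's.
- Center-star alignment degrades on highly gappy, multidomain families;
  the filter's identity statistics inherit that.
- NJ trees of saturated families (p near the 0.95 cap) compress distances;
  deep/in-paralog calls on such families are less reliable than the benchmark
  (which includes moderate divergence only) suggests.
- The single-gain Dollo model is inappropriate where horizontal transfer is
  plausible.
- Recovery accepts the best hit without reciprocity by design; its
  `recovered` flag should be honored in downstream interpretation.
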