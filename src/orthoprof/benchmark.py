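"""The default synthetic benchmark: 12 species, 5 supergroups, 20 families.

The family grid spans the regimes the pipeline must handle: near-identical and
highly divergent 1:1 families, ancestral (deep) and lineage-restricted
(in-paralog) duplications, secondary losses concentrated in parasite-like
lineages, a clade-restricted fusion architecture, a promiscuous common domain
also planted in decoys, tandem repeats with transmembrane segments, a
fungi-specific family, and families carrying planted motifs (CaaX, WxxxF/Y,
N-terminal cysteine, disorder and amphipathic-helix segments). Eight decoys
per species act as hard negatives.

Also provides the evaluation metrics used by the acceptance checks:
assignment precision/recall against simulator truth and deep/in-paralog
classification accuracy against the logged duplication events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, SpeciesTable, stable_seed
from .phyloprof import build_gene_tree, classify_paralogs
from .seqsim import (
    DomainBlock,
    FamilySpec,
    FamilyTruth,
    PlantedMotif,
    SpeciesTree,
    evolve_family,
    emit_proteomes,
    simulate_species_tree,
)

#: species composition: 4 Opisthokonta (2 Metazoa + 2 Fungi), 2 of each other supergroup
SUPERGROUP_PLAN = {
    "Opisthokonta:Metazoa": 2,
    "Opisthokonta:Fungi": 2,
    "Amoebozoa": 2,
    "Archaeplastida": 2,
    "SAR": 2,
    "Excavata": 2,
}
N_SPECIES = 12
N_DECOYS = 8
DEFAULT_MASTER_SEED = 42


def _fixed_block_seq(seed: int, token: str, length: int, hydrophobic_bias: bool = False) -> str:
    """A reproducible root sequence for blocks shared between families and decoys."""
    rng = np.random.default_rng(stable_seed(seed, "shared-block", token))
    from .core import BACKGROUND_FREQS

    p = BACKGROUND_FREQS.copy()
    if hydrophobic_bias:
        for aa in "LIVFAM":
            p[AMINO_ACIDS.index(aa)] *= 3.0
        p = p / p.sum()
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=p))


def benchmark_families(master_seed: int = DEFAULT_MASTER_SEED):
    """The fixed 20-family grid plus the decoy insert blocks it shares with decoys."""
    fusion_block = _fixed_block_seq(master_seed, "fusion-Z", 200)
    common_block = _fixed_block_seq(master_seed, "common-C", 180)
    repeat_unit = _fixed_block_seq(master_seed, "repeat-R", 34)

    fams = [
        FamilySpec("fam01_core_low", substitution_scale=0.1,
                   domain_blocks=[DomainBlock("core", 250)]),
        FamilySpec("fam02_core_mid", substitution_scale=0.3,
                   domain_blocks=[DomainBlock("core", 250)]),
        FamilySpec("fam03_core_high", substitution_scale=0.6,
                   domain_blocks=[DomainBlock("core", 250)]),
        FamilySpec("fam04_core_vhigh", substitution_scale=1.0,
                   domain_blocks=[DomainBlock("core", 300)]),
        FamilySpec("fam05_deep", root_copy_count=2, substitution_scale=0.3,
                   deep_stem_time=0.8, domain_blocks=[DomainBlock("core", 220)]),
        FamilySpec("fam06_inpar", duplication_rate=0.25, substitution_scale=0.3,
                   domain_blocks=[DomainBlock("core", 220)]),
        FamilySpec("fam07_loss", loss_rate=0.12, substitution_scale=0.3,
                   loss_bias={"Excavata": 6.0}, domain_blocks=[DomainBlock("core", 220)]),
        FamilySpec("fam08_fusion", substitution_scale=0.5,
                   domain_blocks=[
                       DomainBlock("recv", 150),
                       DomainBlock("fusZ", 200, "conserved", clades=("SAR",),
                                   root_seq=fusion_block),
                   ]),
        FamilySpec("fam09_common", substitution_scale=0.25, policy_class="common_domain",
                   domain_blocks=[
                       DomainBlock("comC", 180, "conserved", root_seq=common_block),
                       DomainBlock("spec", 120),
                   ]),
        FamilySpec("fam10_tm_repeat", substitution_scale=0.4, policy_class="tm_or_repeat",
                   domain_blocks=[
                       DomainBlock("base", 150),
                       DomainBlock("rep1", 34, root_seq=repeat_unit),
                       DomainBlock("rep2", 34, root_seq=repeat_unit),
                       DomainBlock("rep3", 34, root_seq=repeat_unit),
                   ],
                   planted_motifs=[PlantedMotif("tm_segment")]),
        FamilySpec("fam11_divergent", substitution_scale=1.4,
                   domain_blocks=[DomainBlock("core", 250)]),
        FamilySpec("fam12_fungi", substitution_scale=0.25,
                   restrict_to_clades=("Fungi",),
                   domain_blocks=[DomainBlock("core", 200)]),
        FamilySpec("fam13_twodomain", substitution_scale=0.3,
                   domain_blocks=[DomainBlock("domX", 140), DomainBlock("domY", 160)]),
        FamilySpec("fam14_caax", substitution_scale=0.3,
                   domain_blocks=[DomainBlock("core", 200)],
                   planted_motifs=[
                       PlantedMotif("caax", ("Opisthokonta", "Archaeplastida"))
                   ]),
        FamilySpec("fam15_features", substitution_scale=0.3,
                   domain_blocks=[DomainBlock("core", 280)],
                   planted_motifs=[
                       PlantedMotif("nterm_cys"),
                       PlantedMotif("wxxxfy"),
                       PlantedMotif("tm_segment"),
                       PlantedMotif("disorder_segment"),
                   ]),
        FamilySpec("fam16_duploss", duplication_rate=0.15, loss_rate=0.08,
                   substitution_scale=0.4, domain_blocks=[DomainBlock("core", 220)]),
        FamilySpec("fam17_amph", substitution_scale=0.3,
                   domain_blocks=[DomainBlock("core", 200)],
                   planted_motifs=[PlantedMotif("amphipathic_helix")]),
        FamilySpec("fam18_identical", substitution_scale=0.02,
                   domain_blocks=[DomainBlock("core", 150)]),
        FamilySpec("fam19_deep_loss", root_copy_count=2, loss_rate=0.08,
                   substitution_scale=0.35, deep_stem_time=0.8,
                   domain_blocks=[DomainBlock("core", 200)]),
        FamilySpec("fam20_mixed", duplication_rate=0.1, loss_rate=0.05,
                   substitution_scale=0.6,
                   domain_blocks=[DomainBlock("n_dom", 120), DomainBlock("c_dom", 140)]),
    ]
    decoy_inserts = [
        (fusion_block, 3, 0.3),   # near-intact fusion partner: defeats full-seq reciprocity
        (common_block, 4, 1.3),   # distant common-domain relatives: 1e-2 vs 1e-20 regime
    ]
    return fams, decoy_inserts


def build_benchmark(master_seed: int = DEFAULT_MASTER_SEED, out_dir=None):
    """Simulate the full default benchmark.

    Returns ``(species_tree, proteomes, truths, truth_df)`` where ``truths``
    maps family id to its :class:`FamilyTruth`.
    """
    tree = simulate_species_tree(N_SPECIES, SUPERGROUP_PLAN, seed=master_seed)
    fams, decoy_inserts = benchmark_families(master_seed)
    evolved = []
    truths: dict[str, FamilyTruth] = {}
    for spec in fams:
        seqs, truth = evolve_family(tree, spec, seed=master_seed)
        evolved.append((seqs, truth))
        truths[spec.family_id] = truth
    proteomes, truth_df = emit_proteomes(
        evolved, tree.species_table(), N_DECOYS, master_seed,
        out_dir=out_dir, decoy_inserts=decoy_inserts,
    )
    return tree, proteomes, truths, truth_df


def pick_seed_gene(truth: FamilyTruth, preferred_species: str = "OPI01") -> tuple[str, str]:
    """Deterministic seed organism/gene for a family (first gene of the
    preferred species, falling back to the first species with any gene)."""
    order = [preferred_species] + sorted(truth.genes_by_species)
    for sp in order:
        genes = truth.genes_by_species.get(sp, [])
        if genes:
            return sp, sorted(genes)[0]
    raise ValueError(f"family {truth.family_id} has no surviving genes")


def precision_recall(
    assignments: pd.DataFrame, truths: dict[str, FamilyTruth]
) -> tuple[float, float, int, int]:
    """Assignment precision and recall against simulator truth.

    Precision: fraction of kept assignments whose gene truly belongs to the
    assigned family in that species. Recall: fraction of (family, species)
    pairs with at least one true gene for which at least one correct kept
    assignment exists.
    """
    kept = assignments[assignments["status"] == "kept"]
    n_kept = len(kept)
    correct = 0
    hit_pairs = set()
    for _, row in kept.iterrows():
        fam, sp, gene = row["family"], row["species"], row["gene"]
        truth = truths.get(fam)
        if truth is not None and gene in truth.genes_by_species.get(sp, []):
            correct += 1
            hit_pairs.add((fam, sp))
    truth_pairs = {
        (fam, sp)
        for fam, truth in truths.items()
        for sp, genes in truth.genes_by_species.items()
        if genes
    }
    precision = correct / n_kept if n_kept else 1.0
    recall = len(hit_pairs & truth_pairs) / len(truth_pairs) if truth_pairs else 1.0
    return precision, recall, n_kept, len(truth_pairs)


def paralog_classification_accuracy(
    tree: SpeciesTree,
    truths: dict[str, FamilyTruth],
    family_seqs: dict[str, dict[str, str]],
    scheme,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of logged duplication events receiving the correct label.

    For each family with surviving duplications, a gene tree is built from the
    true member sequences; each logged event is matched to the called
    duplication node spanning its surviving descendants, and the deep vs
    in-paralog labels are compared.
    """
    table = tree.species_table()
    sg = {i.species: i.supergroup for i in table}
    kd = {i.species: i.kingdom for i in table}
    total = correct = 0
    for fam, truth in sorted(truths.items()):
        events = [
            (ev, left, right)
            for ev, left, right in truth.duplication_descendants()
            if left and right
        ]
        if not events:
            continue
        seqs = {g: family_seqs[fam][g] for g in truth.all_genes}
        if len(seqs) < 3:
            continue
        species_of = {g: g.split("_")[-2] for g in seqs}
        gt, _ = build_gene_tree(
            seqs, scheme, species_of,
            {g: sg[s] for g, s in species_of.items()},
            {g: kd[s] for g, s in species_of.items()},
            n_boot=n_boot, seed=seed,
        )
        calls = classify_paralogs(gt)
        for ev, left, right in events:
            total += 1
            want = frozenset(left) | frozenset(right)
            match = None
            for c in calls:
                if c.node_leaves >= want and (
                    match is None or len(c.node_leaves) < len(match.node_leaves)
                ):
                    match = c
            expect = "deep" if ev.classification == "deep" else "in-paralog"
            if match is not None and match.classification == expect:
                correct += 1
    acc = correct / total if total else 1.0
    return acc, total
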