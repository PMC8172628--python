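"""Shared fixtures: scoring scheme, small synthetic worlds, the full benchmark."""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
import pytest

from orthoprof.benchmark import (
    benchmark_families,
    build_benchmark,
    pick_seed_gene,
)
from orthoprof.core import Proteome, stable_seed
from orthoprof.orthology import (
    SearchContext,
    assignments_to_frame,
    get_policy,
    run_family,
)
from orthoprof.searchcore import blosum62_scheme
from orthoprof.seqsim import (
    DomainBlock,
    FamilySpec,
    evolve_family,
    emit_proteomes,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def scheme():
    return blosum62_scheme()


@pytest.fixture(scope="session")
def small_world():
    """4 species, one clean family, a few decoys — for orthology unit tests."""
    tree = simulate_species_tree(
        4, {"Opisthokonta:Fungi": 2, "SAR": 1, "Excavata": 1}, seed=7
    )
    spec = FamilySpec("famA", substitution_scale=0.35)
    seqs, truth = evolve_family(tree, spec, seed=7)
    proteomes, truth_df = emit_proteomes(
        [(seqs, truth)], tree.species_table(), 5, seed=7
    )
    ctx = SearchContext(proteomes, master_seed=7)
    return {
        "tree": tree,
        "proteomes": proteomes,
        "truth": truth,
        "truth_df": truth_df,
        "ctx": ctx,
    }


@pytest.fixture(scope="session")
def fusion_world(scheme):
    """Planted multidomain fusion: the target species' family gene carries an
    extra block that also occurs (nearly intact) in decoys of every species,
    so full-sequence reverse search prefers a decoy while the best-domain
    segment still reciprocates."""
    from orthoprof.benchmark import _fixed_block_seq

    fusion_block = _fixed_block_seq(99, "fusion-test", 220)
    tree = simulate_species_tree(
        4, {"Opisthokonta:Metazoa": 2, "SAR": 1, "Excavata": 1}, seed=99
    )
    spec = FamilySpec(
        "fusfam",
        substitution_scale=0.55,
        domain_blocks=[
            DomainBlock("recv", 150),
            DomainBlock("fusZ", 220, "conserved", clades=("SAR",), root_seq=fusion_block),
        ],
    )
    seqs, truth = evolve_family(tree, spec, seed=99)
    proteomes, _ = emit_proteomes(
        [(seqs, truth)], tree.species_table(), 6, seed=99,
        decoy_inserts=[(fusion_block, 3, 0.25)],
    )
    ctx = SearchContext(proteomes, master_seed=99)
    return {"tree": tree, "proteomes": proteomes, "truth": truth, "ctx": ctx}


@pytest.fixture(scope="session")
def benchmark_run():
    """The default benchmark (12 species / 5 supergroups / 20 families / 8
    decoys per species / master seed 42) with full assignment output."""
    tree, proteomes, truths, truth_df = build_benchmark(42)
    fams, _ = benchmark_families(42)
    family_seqs = {}
    for spec in fams:
        seqs, _ = evolve_family(tree, spec, seed=42)
        family_seqs[spec.family_id] = seqs
    ctx = SearchContext(proteomes, master_seed=42)
    frames = []
    t0 = time.time()
    for spec in fams:
        truth = truths[spec.family_id]
        pref = "OPI03" if spec.restrict_to_clades else "OPI01"
        try:
            sp, gene = pick_seed_gene(truth, pref)
        except ValueError:
            continue
        res = run_family(
            spec.family_id, {sp: gene}, proteomes, get_policy(spec.policy_class), ctx
        )
        frames.append(assignments_to_frame(res))
    wall = time.time() - t0
    assignments = pd.concat(frames, ignore_index=True)
    return {
        "tree": tree,
        "proteomes": proteomes,
        "truths": truths,
        "truth_df": truth_df,
        "family_specs": {f.family_id: f for f in fams},
        "family_seqs": family_seqs,
        "assignments": assignments,
        "ctx": ctx,
        "wall_seconds": wall,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(stable_seed(0, "tests"))
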