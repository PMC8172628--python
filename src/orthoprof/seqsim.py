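"""Synthetic proteome simulator with known ortholog/paralog ground truth.

Generates a rooted species tree partitioned into labeled eukaryotic supergroups,
evolves protein families along it (amino-acid substitutions from a fixed
exchangeability table; duplication and loss as Poisson birth-death processes per
branch), plants sequence motifs (CaaX, WxxxF/Y, N-terminal Cys, transmembrane,
disorder, amphipathic-helix segments) restricted to designated clades, and
emits per-species FASTA proteomes with order-2 Markov decoys plus a truth table.

Every downstream stage of the pipeline is testable against this ground truth
without any external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    BACKGROUND_FREQS,
    KINGDOMS,
    SUPERGROUPS,
    Proteome,
    SpeciesInfo,
    SpeciesTable,
    decode_seq,
    encode_seq,
    stable_seed,
)

SG_PREFIX = {
    "Opisthokonta": "OPI",
    "Amoebozoa": "AMO",
    "Archaeplastida": "ARC",
    "SAR": "SAR",
    "Excavata": "EXC",
}

#: substitution-rate multiplier and residue composition per domain conservation class
CLASS_RATE = {
    "conserved": 0.35,
    "normal": 1.0,
    "fast": 2.0,
    "tm": 0.5,
    "disorder": 1.5,
}

_HYDROPHOBIC = "LIVFAM"
_DISORDER_PROMOTING = "EKSPQDRG"


def _class_freqs(cls: str) -> np.ndarray:
    freqs = BACKGROUND_FREQS.copy()
    if cls == "tm":
        for aa in _HYDROPHOBIC:
            freqs[AMINO_ACIDS.index(aa)] *= 6.0
    elif cls == "disorder":
        for aa in _DISORDER_PROMOTING:
            freqs[AMINO_ACIDS.index(aa)] *= 6.0
    return freqs / freqs.sum()


def _exchange_matrix() -> np.ndarray:
    """Replacement distribution P(b | a), diagonal zeroed, from BLOSUM62 odds."""
    from .searchcore import blosum62_scheme

    scheme = blosum62_scheme()
    q = BACKGROUND_FREQS[None, :] * np.exp2(scheme.matrix[:20, :20] / 2.0)
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)


_EXCHANGE: np.ndarray | None = None


def _get_exchange() -> np.ndarray:
    global _EXCHANGE
    if _EXCHANGE is None:
        _EXCHANGE = _exchange_matrix()
    return _EXCHANGE


class SpeciesTree:
    """Rooted binary species tree with supergroup (and kingdom) leaf labels."""

    def __init__(
        self,
        tree: dendropy.Tree,
        clade_labels: dict[str, str],
        kingdom_labels: dict[str, str | None] | None = None,
    ):
        self.tree = tree
        self.clade_labels = dict(clade_labels)
        self.kingdom_labels = dict(kingdom_labels or {})
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        for lf in leaves:
            if lf not in self.clade_labels:
                raise ValueError(f"leaf {lf!r} has no supergroup label")
            if self.clade_labels[lf] not in SUPERGROUPS:
                raise ValueError(f"unknown supergroup {self.clade_labels[lf]!r}")
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and (node.edge.length or 0) <= 0:
                raise ValueError("all branch lengths must be > 0")

    @property
    def species(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def species_table(self) -> SpeciesTable:
        return SpeciesTable(
            [
                SpeciesInfo(s, self.clade_labels[s], self.kingdom_labels.get(s))
                for s in self.species
            ]
        )

    def clade_species(self, clade: str) -> set[str]:
        """Species contained in a named clade (species/kingdom/supergroup/Eukaryotes)."""
        if clade == "Eukaryotes":
            return set(self.species)
        out = set()
        for s in self.species:
            if s == clade or self.clade_labels[s] == clade or self.kingdom_labels.get(s) == clade:
                out.add(s)
        return out

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    @classmethod
    def from_newick(cls, path_or_str: str | Path, species_table: SpeciesTable) -> "SpeciesTree":
        text = str(path_or_str)
        if Path(text).exists():
            tree = dendropy.Tree.get(path=text, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        clades = {s: species_table.supergroup_of(s) for s in species_table.species}
        kingdoms = {i.species: i.kingdom for i in species_table}
        return cls(tree, clades, kingdoms)


def _join_random(rng: np.random.Generator, subtrees: list[dendropy.Node], taxon_ns) -> dendropy.Node:
    """Randomly join a list of clades into one rooted binary clade."""
    clades = list(subtrees)
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        right = clades.pop(j)
        left = clades.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        left.edge.length = float(rng.exponential(0.12) + 0.02)
        right.edge.length = float(rng.exponential(0.12) + 0.02)
        clades.append(parent)
    return clades[0]


def simulate_species_tree(
    n_species: int,
    supergroup_plan: dict[str, int],
    seed: int,
) -> SpeciesTree:
    """Random rooted binary species tree with monophyletic supergroups.

    ``supergroup_plan`` maps supergroup names (optionally kingdom-qualified, as
    in ``"Opisthokonta:Fungi"``) to leaf counts. Kingdom-qualified blocks are
    monophyletic within their supergroup. Deterministic for a fixed seed.
    """
    parsed: list[tuple[str, str | None, int]] = []
    for key, count in supergroup_plan.items():
        if ":" in key:
            sg, kingdom = key.split(":", 1)
        else:
            sg, kingdom = key, None
        if sg not in SUPERGROUPS:
            raise ValueError(f"unknown supergroup {sg!r}; expected one of {SUPERGROUPS}")
        if kingdom is not None and kingdom not in KINGDOMS.get(sg, ()):
            raise ValueError(f"kingdom {kingdom!r} invalid for supergroup {sg!r}")
        if count < 1:
            raise ValueError(f"supergroup plan count for {key!r} must be >= 1, got {count}")
        parsed.append((sg, kingdom, int(count)))
    total = sum(c for _, _, c in parsed)
    if total != n_species:
        raise ValueError(f"n_species={n_species} != sum of plan counts ({total})")

    rng = np.random.default_rng(stable_seed(seed, "species-tree"))
    taxon_ns = dendropy.TaxonNamespace()
    clade_labels: dict[str, str] = {}
    kingdom_labels: dict[str, str | None] = {}
    sg_order = [sg for sg in SUPERGROUPS if any(p[0] == sg for p in parsed)]
    counters: dict[str, int] = {}
    sg_clades = []
    for sg in sg_order:
        blocks = []
        for psg, kingdom, count in parsed:
            if psg != sg:
                continue
            leaves = []
            for _ in range(count):
                counters[sg] = counters.get(sg, 0) + 1
                name = f"{SG_PREFIX[sg]}{counters[sg]:02d}"
                taxon = taxon_ns.new_taxon(name)
                node = dendropy.Node(taxon=taxon)
                leaves.append(node)
                clade_labels[name] = sg
                kingdom_labels[name] = kingdom
            blocks.append(_join_random(rng, leaves, taxon_ns))
        sg_clades.append(_join_random(rng, blocks, taxon_ns))
    root = _join_random(rng, sg_clades, taxon_ns)
    if root.edge.length is None:
        root.edge.length = None  # root has no branch
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    # stable internal-node labels (preorder)
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = None
        else:
            node.label = f"N{k}"
            k += 1
    return SpeciesTree(tree, clade_labels, kingdom_labels)


@dataclass(frozen=True)
class DomainBlock:
    """One sequence block of a family's domain architecture."""

    block_id: str
    length: int
    conservation_class: str = "normal"
    clades: tuple[str, ...] | None = None  # None = present in all species
    root_seq: str | None = None

    def __post_init__(self):
        if self.root_seq is not None:
            object.__setattr__(self, "length", len(self.root_seq))
        if self.length < 10:
            raise ValueError(f"domain block {self.block_id!r} length must be >= 10")
        if self.conservation_class not in CLASS_RATE:
            raise ValueError(
                f"unknown conservation class {self.conservation_class!r}; "
                f"expected one of {sorted(CLASS_RATE)}"
            )


MOTIF_KINDS = (
    "caax",
    "wxxxfy",
    "nterm_cys",
    "tm_segment",
    "disorder_segment",
    "amphipathic_helix",
)


@dataclass(frozen=True)
class PlantedMotif:
    kind: str
    clades: tuple[str, ...] = ("Eukaryotes",)

    def __post_init__(self):
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"unknown motif kind {self.kind!r}; expected {MOTIF_KINDS}")


@dataclass
class FamilySpec:
    """Parameters of one simulated protein family."""

    family_id: str
    root_copy_count: int = 1
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    substitution_scale: float = 1.0
    domain_blocks: list[DomainBlock] = field(
        default_factory=lambda: [DomainBlock("core", 250)]
    )
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    loss_bias: dict[str, float] = field(default_factory=dict)
    restrict_to_clades: tuple[str, ...] | None = None
    #: extra divergence time applied to each root copy after a deep duplication
    deep_stem_time: float = 0.6
    policy_class: str = "default"

    def __post_init__(self):
        if self.root_copy_count < 1:
            raise ValueError("root_copy_count must be >= 1")
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication/loss rates must be >= 0")
        if self.substitution_scale < 0:
            raise ValueError("substitution_scale must be >= 0")
        if not self.domain_blocks:
            raise ValueError("at least one domain block required")
        valid_clades = set(SUPERGROUPS) | {k for ks in KINGDOMS.values() for k in ks}
        valid_clades.add("Eukaryotes")
        for m in self.planted_motifs:
            for c in m.clades:
                if c not in valid_clades:
                    raise ValueError(f"motif clade {c!r} references no known clade")
        for b in self.domain_blocks:
            for c in b.clades or ():
                if c not in valid_clades:
                    raise ValueError(f"block clade {c!r} references no known clade")
        for sg in self.loss_bias:
            if sg not in valid_clades:
                raise ValueError(f"loss_bias key {sg!r} references no known clade")


@dataclass
class Event:
    """One logged birth-death event on a species-tree branch."""

    kind: str  # "duplication" | "loss"
    branch: str  # label of the child node of the branch
    classification: str | None  # "deep" | "in-paralog" for duplications
    lineage: str  # lineage lost, or parent lineage duplicated
    children: tuple[str, str] | None = None  # new lineage ids for duplications


@dataclass
class FamilyTruth:
    """Simulator ground truth for one family."""

    family_id: str
    genes_by_species: dict[str, list[str]]
    events: list[Event]
    ortholog_group: dict[str, str]
    gene_lineage: dict[str, str]
    lineage_parent: dict[str, str | None]
    motifs: list[tuple[str, str, int, int]]  # gene, kind, start, end (1-based)

    @property
    def all_genes(self) -> list[str]:
        return [g for genes in self.genes_by_species.values() for g in genes]

    def lineage_ancestors(self, lineage: str) -> list[str]:
        out = [lineage]
        while self.lineage_parent.get(out[-1]) is not None:
            out.append(self.lineage_parent[out[-1]])
        return out

    def duplication_descendants(self):
        """Per duplication event: classification and surviving genes per side."""
        gene_anc = {
            g: set(self.lineage_ancestors(lin)) for g, lin in self.gene_lineage.items()
        }
        out = []
        for ev in self.events:
            if ev.kind != "duplication" or ev.children is None:
                continue
            left = sorted(g for g, anc in gene_anc.items() if ev.children[0] in anc)
            right = sorted(g for g, anc in gene_anc.items() if ev.children[1] in anc)
            out.append((ev, left, right))
        return out

    def replay_counts(self, tree: SpeciesTree, spec: FamilySpec) -> dict[str, int]:
        """Replay the event log over the tree; returns per-species gene counts.

        Used to check the conservation invariant: the emitted gene set equals
        births minus losses replayed from the log.
        """
        by_branch: dict[str, list[Event]] = {}
        for ev in self.events:
            by_branch.setdefault(ev.branch, []).append(ev)
        allowed = _allowed_species(tree, spec.restrict_to_clades)
        counts: dict[str, int] = {}
        root_live = ["R0"]
        for ev in by_branch.get("root", []):
            root_live.remove(ev.lineage)
            root_live.extend(ev.children)

        def walk(node, live):
            label = node.taxon.label if node.is_leaf() else node.label
            if node.parent_node is not None:
                for ev in by_branch.get(label, []):
                    if ev.kind == "loss":
                        live = [x for x in live if x != ev.lineage]
                    else:
                        live = [x for x in live if x != ev.lineage] + list(ev.children)
            if node.is_leaf():
                if label in allowed:
                    counts[label] = len(live)
                return
            for ch in node.child_nodes():
                walk(ch, list(live))

        walk(self.tree_root(tree), root_live)
        return counts

    @staticmethod
    def tree_root(tree: SpeciesTree):
        return tree.tree.seed_node


def _allowed_species(tree: SpeciesTree, restrict: tuple[str, ...] | None) -> set[str]:
    if restrict is None:
        return set(tree.species)
    out: set[str] = set()
    for clade in restrict:
        out |= tree.clade_species(clade)
    return out


def _mutate(seq: np.ndarray, rates: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Apply substitutions over time t; per-site rates in substitutions/site/unit."""
    if t <= 0:
        return seq.copy()
    out = seq.copy()
    p_hit = 1.0 - np.exp(-rates * t)
    hits = np.nonzero(rng.random(len(seq)) < p_hit)[0]
    exchange = _get_exchange()
    for i in hits:
        out[i] = rng.choice(20, p=exchange[out[i]])
    return out


class _FamilySimulator:
    def __init__(self, tree: SpeciesTree, spec: FamilySpec, seed: int):
        self.tree = tree
        self.spec = spec
        self.rng = np.random.default_rng(stable_seed(seed, "family", spec.family_id))
        self.events: list[Event] = []
        self.lineage_parent: dict[str, str | None] = {"R0": None}
        self.lineage_group: dict[str, str] = {}
        self.lineage_inpar: dict[str, bool] = {"R0": False}
        self._lineage_counter = 0
        self.leaf_lineages: dict[str, list[tuple[str, np.ndarray]]] = {}
        self.allowed = _allowed_species(tree, spec.restrict_to_clades)
        # per-site substitution rates and block boundaries
        rates = []
        bounds = {}
        pos = 0
        for b in spec.domain_blocks:
            rates.extend([CLASS_RATE[b.conservation_class] * spec.substitution_scale] * b.length)
            bounds[b.block_id] = (pos, pos + b.length)
            pos += b.length
        self.site_rates = np.array(rates)
        self.block_bounds = bounds
        self.total_len = pos
        # loss-bias per node: multiplier if all descendant leaves sit in a biased clade
        self._node_loss_mult = {}
        biased = {c: _allowed_species(tree, (c,)) for c in spec.loss_bias}
        for node in tree.tree.postorder_node_iter():
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            mult = 1.0
            for clade, species in biased.items():
                if leaves <= species:
                    mult = max(mult, spec.loss_bias[clade])
            self._node_loss_mult[id(node)] = mult

    def _new_lineage(self, parent: str, inpar: bool) -> str:
        self._lineage_counter += 1
        lid = f"L{self._lineage_counter}"
        self.lineage_parent[lid] = parent
        self.lineage_inpar[lid] = inpar or self.lineage_inpar.get(parent, False)
        return lid

    def _root_sequence(self) -> np.ndarray:
        parts = []
        for b in self.spec.domain_blocks:
            if b.root_seq is not None:
                parts.append(encode_seq(b.root_seq))
            else:
                freqs = _class_freqs(b.conservation_class)
                parts.append(self.rng.choice(20, size=b.length, p=freqs).astype(np.uint8))
        return np.concatenate(parts)

    def run(self):
        spec = self.spec
        root_seq = self._root_sequence()
        # deep duplications at the root (caterpillar order), with stem divergence
        live: list[tuple[str, np.ndarray]] = [("R0", root_seq)]
        self.lineage_group["R0"] = "og1"
        for k in range(2, spec.root_copy_count + 1):
            parent, pseq = live[-1]
            c1 = self._new_lineage(parent, False)
            c2 = self._new_lineage(parent, False)
            self.lineage_group[c1] = self.lineage_group[parent]
            self.lineage_group[c2] = f"og{k}"
            self.events.append(
                Event("duplication", "root", "deep", parent, (c1, c2))
            )
            live[-1] = (c1, pseq)
            stem = _mutate(
                pseq, self.site_rates, spec.deep_stem_time, self.rng
            )
            live.append((c2, stem))
            # the continuing copy also drifts on its own stem
            live[-2] = (c1, _mutate(pseq, self.site_rates, spec.deep_stem_time, self.rng))
        root = self.tree.tree.seed_node
        for child in root.child_nodes():
            self._walk(child, [(lid, seq.copy()) for lid, seq in live])
        return self._emit()

    def _subtree_has_allowed(self, node) -> bool:
        return any(lf.taxon.label in self.allowed for lf in node.leaf_iter())

    def _walk(self, node, live: list[tuple[str, np.ndarray]]):
        if not self._subtree_has_allowed(node):
            return
        label = node.taxon.label if node.is_leaf() else node.label
        t = float(node.edge.length)
        b = self.spec.duplication_rate
        d = self.spec.loss_rate * self._node_loss_mult[id(node)]
        survivors: list[tuple[str, np.ndarray]] = []
        for lid, seq in live:
            survivors.extend(self._evolve_lineage(lid, seq, t, b, d, label))
        if node.is_leaf():
            self.leaf_lineages[label] = survivors
        else:
            for child in node.child_nodes():
                self._walk(child, [(lid, s.copy()) for lid, s in survivors])

    def _evolve_lineage(self, lid, seq, time_left, b, d, branch):
        total = b + d
        if total <= 0:
            return [(lid, _mutate(seq, self.site_rates, time_left, self.rng))]
        dt = float(self.rng.exponential(1.0 / total))
        if dt >= time_left:
            return [(lid, _mutate(seq, self.site_rates, time_left, self.rng))]
        seq = _mutate(seq, self.site_rates, dt, self.rng)
        if self.rng.random() < b / total:
            c1 = self._new_lineage(lid, False)
            c2 = self._new_lineage(lid, True)
            self.lineage_group[c1] = self.lineage_group[lid]
            self.lineage_group[c2] = self.lineage_group[lid]
            self.events.append(Event("duplication", branch, "in-paralog", lid, (c1, c2)))
            out = self._evolve_lineage(c1, seq, time_left - dt, b, d, branch)
            out += self._evolve_lineage(c2, seq.copy(), time_left - dt, b, d, branch)
            return out
        self.events.append(Event("loss", branch, None, lid))
        return []

    # --- motif planting -------------------------------------------------
    def _plant_motifs(self, species: str, seq: np.ndarray):
        """Plant motifs for one leaf gene; returns (sequence, [(kind, start, end)])."""
        planted = []
        s = seq.copy()
        for m in self.spec.planted_motifs:
            allowed = set()
            for c in m.clades:
                allowed |= self.tree.clade_species(c)
            if species not in allowed:
                continue
            loc = self._write_motif(m.kind, s)
            if loc is not None:
                planted.append((m.kind, loc[0], loc[1]))
        return s, planted

    def _write_motif(self, kind: str, s: np.ndarray):
        rng = self.rng
        L = len(s)

        def put(pos0, text):
            s[pos0 : pos0 + len(text)] = encode_seq(text)
            return pos0 + 1, pos0 + len(text)  # 1-based inclusive

        if kind == "caax":
            if L < 4:
                return None
            a = "AVIL"
            x = "STQAM"
            text = "C" + a[rng.integers(4)] + a[rng.integers(4)] + x[rng.integers(5)]
            return put(L - 4, text)
        if kind == "wxxxfy":
            if L < 40:
                return None
            pos = 14
            s[pos] = AMINO_ACIDS.index("W")
            s[pos + 4] = AMINO_ACIDS.index("FY"[rng.integers(2)])
            return pos + 1, pos + 5
        if kind == "nterm_cys":
            if L < 20:
                return None
            s[7] = AMINO_ACIDS.index("C")
            return 8, 8
        if kind == "tm_segment":
            if L < 80:
                return None
            pos = L // 3
            tm = "".join(_HYDROPHOBIC[rng.integers(4)] for _ in range(21))
            return put(pos, tm)
        if kind == "disorder_segment":
            if L < 120:
                return None
            pos = 2 * L // 3
            dis = "".join(_DISORDER_PROMOTING[rng.integers(6)] for _ in range(40))
            return put(pos, dis)
        if kind == "amphipathic_helix":
            if L < 80:
                return None
            pos = L // 2
            helix = amphipathic_pattern(18)
            return put(pos, helix)
        return None  # pragma: no cover

    def _emit(self):
        sequences: dict[str, str] = {}
        genes_by_species: dict[str, list[str]] = {}
        ortholog_group: dict[str, str] = {}
        gene_lineage: dict[str, str] = {}
        motifs: list[tuple[str, str, int, int]] = []
        keep = self._block_keep_mask()
        for species in self.tree.species:
            if species not in self.leaf_lineages:
                if species in self.allowed:
                    genes_by_species[species] = []
                continue
            genes_by_species[species] = []
            for k, (lid, seq) in enumerate(self.leaf_lineages[species], start=1):
                gene = f"{self.spec.family_id}_{species}_{k}"
                seq2, planted = self._plant_motifs(species, seq)
                seq2 = seq2[keep[species]]
                # motif coordinates after block excision
                offset = np.cumsum(~keep[species])
                for kind, start, end in planted:
                    if keep[species][start - 1] and keep[species][end - 1]:
                        motifs.append(
                            (gene, kind, start - int(offset[start - 1]), end - int(offset[end - 1]))
                        )
                sequences[gene] = decode_seq(seq2)
                genes_by_species[species].append(gene)
                group = self.lineage_group.get(self._group_ancestor(lid), "og1")
                ortholog_group[gene] = group
                gene_lineage[gene] = lid
        truth = FamilyTruth(
            family_id=self.spec.family_id,
            genes_by_species=genes_by_species,
            events=self.events,
            ortholog_group=ortholog_group,
            gene_lineage=gene_lineage,
            lineage_parent=self.lineage_parent,
            motifs=motifs,
        )
        return sequences, truth

    def _group_ancestor(self, lid: str) -> str:
        while lid not in self.lineage_group:
            lid = self.lineage_parent[lid]
        return lid

    def _block_keep_mask(self) -> dict[str, np.ndarray]:
        out = {}
        for species in self.tree.species:
            mask = np.ones(self.total_len, dtype=bool)
            for b in self.spec.domain_blocks:
                if b.clades is None:
                    continue
                allowed = set()
                for c in b.clades:
                    allowed |= self.tree.clade_species(c)
                if species not in allowed:
                    lo, hi = self.block_bounds[b.block_id]
                    mask[lo:hi] = False
            out[species] = mask
        return out


def amphipathic_pattern(length: int = 18) -> str:
    """Ideal amphipathic helix: hydrophobic face on a 100 deg/residue helical wheel."""
    polar = "KESQ"
    out = []
    for k in range(length):
        ang = math.radians(100.0 * k)
        if math.cos(ang) > 0.25:
            out.append("LF"[k % 2])
        else:
            out.append(polar[k % 4])
    return "".join(out)


def evolve_family(tree: SpeciesTree, spec: FamilySpec, seed: int):
    """Evolve one family along the species tree.

    Returns ``(sequences, truth)``: a gene->sequence map and the ground truth.
    Total loss of the family everywhere returns an empty gene set with the
    complete event log (not an error).
    """
    return _FamilySimulator(tree, spec, seed).run()


def _fit_markov2(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order-2 Markov model (add-one smoothed) of residue composition."""
    p0 = np.ones(20)
    p1 = np.ones((20, 20))
    p2 = np.ones((20, 20, 20))
    for s in seqs:
        e = encode_seq(s)
        e = e[e < 20]
        if len(e) == 0:
            continue
        np.add.at(p0, e, 1)
        if len(e) > 1:
            np.add.at(p1, (e[:-1], e[1:]), 1)
        if len(e) > 2:
            np.add.at(p2, (e[:-2], e[1:-1], e[2:]), 1)
    p0 /= p0.sum()
    p1 /= p1.sum(axis=1, keepdims=True)
    p2 /= p2.sum(axis=2, keepdims=True)
    return p0, p1, p2


def _sample_markov2(model, length: int, rng: np.random.Generator) -> str:
    p0, p1, p2 = model
    seq = [int(rng.choice(20, p=p0))]
    if length > 1:
        seq.append(int(rng.choice(20, p=p1[seq[0]])))
    while len(seq) < length:
        seq.append(int(rng.choice(20, p=p2[seq[-2], seq[-1]])))
    return "".join(AMINO_ACIDS[i] for i in seq)


def emit_proteomes(
    families: list[tuple[dict[str, str], FamilyTruth]],
    species_table: SpeciesTable,
    n_decoys_per_species: int,
    seed: int,
    out_dir: str | Path | None = None,
    decoy_inserts: list[tuple[str, int, float]] | None = None,
) -> tuple[dict[str, Proteome], pd.DataFrame]:
    """Assemble per-species proteomes (family genes + decoys) and the truth table.

    Decoys are order-2 Markov sequences fit to the pooled family composition —
    harder negatives than uniform random — and are never descended from any
    family. ``decoy_inserts`` optionally plants lightly mutated copies of given
    blocks into some decoys of every species (promiscuous-domain scenario).
    Writes one FASTA per species plus ``truth.tsv`` when ``out_dir`` is given.
    """
    all_ids: set[str] = set()
    for sequences, truth in families:
        for g in sequences:
            if g in all_ids:
                raise ValueError(f"gene identifier collision: {g!r}")
            all_ids.add(g)
    fam_seqs = [s for sequences, _ in families for s in sequences.values()]
    model = _fit_markov2(fam_seqs if fam_seqs else ["".join(AMINO_ACIDS)])
    mean_len = int(np.mean([len(s) for s in fam_seqs])) if fam_seqs else 250

    proteomes: dict[str, Proteome] = {}
    rows = []
    for info in species_table:
        sp = info.species
        rng = np.random.default_rng(stable_seed(seed, "decoys", sp))
        seqs: dict[str, str] = {}
        for sequences, truth in families:
            for gene in truth.genes_by_species.get(sp, []):
                seqs[gene] = sequences[gene]
                lid = truth.gene_lineage[gene]
                prov = []
                if truth.ortholog_group[gene] != "og1" or any(
                    ev.kind == "duplication" and ev.classification == "deep"
                    for ev in truth.events
                ):
                    if any(ev.classification == "deep" for ev in truth.events):
                        prov.append("deep")
                inpar = False
                cur: str | None = lid
                while cur is not None:
                    for ev in truth.events:
                        if ev.children and cur in ev.children and ev.classification == "in-paralog":
                            inpar = True
                    cur = truth.lineage_parent.get(cur)
                if inpar:
                    prov.append("in-paralog")
                rows.append(
                    {
                        "gene": gene,
                        "species": sp,
                        "family": truth.family_id,
                        "ortholog_group": f"{truth.family_id}:{truth.ortholog_group[gene]}",
                        "provenance": "+".join(prov) if prov else "speciation",
                    }
                )
        # each insert block occupies its own run of decoy indices, so a decoy
        # carries at most one planted block
        slot_of: dict[int, tuple[str, float]] = {}
        next_slot = 1
        for entry in decoy_inserts or []:
            block, n_copies, divergence = entry
            for _ in range(n_copies):
                slot_of[next_slot] = (block, divergence)
                next_slot += 1
        if next_slot - 1 > n_decoys_per_species:
            raise ValueError("decoy_inserts require more decoys than available")
        for i in range(1, n_decoys_per_species + 1):
            gene = f"{sp}_decoy{i:02d}"
            if gene in all_ids:
                raise ValueError(f"gene identifier collision: {gene!r}")
            length = int(np.clip(rng.normal(mean_len, mean_len / 4), 60, 600))
            s = _sample_markov2(model, length, rng)
            if i in slot_of:
                block, divergence = slot_of[i]
                if len(block) >= length:
                    length = len(block) + 60
                    s = _sample_markov2(model, length, rng)
                mutated = decode_seq(
                    _mutate(
                        encode_seq(block),
                        np.full(len(block), 1.0),
                        divergence,
                        rng,
                    )
                )
                pos = (length - len(block)) // 2
                s = s[:pos] + mutated + s[pos + len(block) :]
            seqs[gene] = s
            rows.append(
                {
                    "gene": gene,
                    "species": sp,
                    "family": "",
                    "ortholog_group": "",
                    "provenance": "decoy",
                }
            )
        proteomes[sp] = Proteome(species=sp, sequences=seqs)

    truth_df = pd.DataFrame(rows, columns=["gene", "species", "family", "ortholog_group", "provenance"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sp, prot in proteomes.items():
            prot.write_fasta(out / f"{sp}.fasta")
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return proteomes, truth_df
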