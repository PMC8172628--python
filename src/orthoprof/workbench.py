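"""Pipeline orchestration: configuration, staged execution, persistence, report.

A run proceeds through five stages — simulate (or load), assign, features,
profile, report — each persisting plain-text outputs (FASTA, TSV, Newick,
JSON) under the output directory, so any stage can be inspected or replaced by
external tools. Runs are deterministic for a fixed config and master seed, and
stages can be resumed from their persisted outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import MSA
from .core import Proteome, SpeciesTable, stable_seed
from .orthology import (
    POLICY_TABLE,
    SearchContext,
    assignments_to_frame,
    get_policy,
    run_family,
)
from .phyloprof import (
    PresenceMatrix,
    build_gene_tree,
    build_presence_matrix,
    classify_paralogs,
    dollo_ancestral,
)
from .protfeat import annotate_protein, feature_table, intervals_bed
from .searchcore import blosum62_scheme
from .seqsim import FamilySpec, DomainBlock, PlantedMotif, SpeciesTree, evolve_family, emit_proteomes, simulate_species_tree

log = logging.getLogger("orthoprof")

STAGES = ("simulate", "assign", "features", "profile", "report")


@dataclass
class SyntheticConfig:
    n_species: int
    supergroup_plan: dict[str, int]
    n_decoys_per_species: int = 8
    families: list[FamilySpec] = field(default_factory=list)
    decoy_inserts: list[tuple[str, int, float]] = field(default_factory=list)


@dataclass
class InputConfig:
    species_table: Path
    fasta: dict[str, Path]
    species_tree: Path | None = None


@dataclass
class FamilyRun:
    family: str
    seeds: dict[str, str]  # species -> gene (may be empty for synthetic autoseeding)
    policy: str = "default"


@dataclass
class RunConfig:
    """Validated run configuration."""

    master_seed: int
    output_dir: Path
    synthetic: SyntheticConfig | None = None
    inputs: InputConfig | None = None
    family_runs: list[FamilyRun] = field(default_factory=list)
    z_cutoff: float = -2.5
    consensus_mode: str = "union"
    use_domain_fallback: bool = True
    n_boot: int = 100
    gap_fraction_max: float = 0.5
    n_shuffles: int = 100
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


def _parse_family_spec(d: dict) -> FamilySpec:
    blocks = [
        DomainBlock(
            b["block_id"], b.get("length", 0),
            b.get("conservation_class", "normal"),
            tuple(b["clades"]) if b.get("clades") else None,
            b.get("root_seq"),
        )
        for b in d.get("domain_blocks", [{"block_id": "core", "length": 250}])
    ]
    motifs = [
        PlantedMotif(m["kind"], tuple(m.get("clades", ["Eukaryotes"])))
        for m in d.get("planted_motifs", [])
    ]
    return FamilySpec(
        family_id=d["family_id"],
        root_copy_count=d.get("root_copy_count", 1),
        duplication_rate=d.get("duplication_rate", 0.0),
        loss_rate=d.get("loss_rate", 0.0),
        substitution_scale=d.get("substitution_scale", 1.0),
        domain_blocks=blocks,
        planted_motifs=motifs,
        loss_bias=d.get("loss_bias", {}),
        restrict_to_clades=tuple(d["restrict_to_clades"]) if d.get("restrict_to_clades") else None,
        deep_stem_time=d.get("deep_stem_time", 0.6),
        policy_class=d.get("policy_class", "default"),
    )


def validate_config(path: str | Path) -> RunConfig:
    """Parse and cross-check a YAML run config, reporting all errors at once."""
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ValueError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    master_seed = raw.get("seed", 0)
    output_dir = Path(raw.get("output_dir", "orthoprof_out"))

    synthetic = None
    inputs = None
    known_species: set[str] = set()
    if "synthetic" in raw:
        s = raw["synthetic"]
        from .core import KINGDOMS, SUPERGROUPS

        for key in (s.get("supergroup_plan") or {}):
            sg, _, kingdom = key.partition(":")
            if sg not in SUPERGROUPS:
                errors.append(f"unknown supergroup {sg!r} in supergroup_plan")
            elif kingdom and kingdom not in KINGDOMS.get(sg, ()):
                errors.append(f"unknown kingdom {kingdom!r} for supergroup {sg!r}")
        try:
            fams = [_parse_family_spec(f) for f in s.get("families", [])]
            synthetic = SyntheticConfig(
                n_species=s["n_species"],
                supergroup_plan=s["supergroup_plan"],
                n_decoys_per_species=s.get("n_decoys_per_species", 8),
                families=fams,
                decoy_inserts=[tuple(x) for x in s.get("decoy_inserts", [])],
            )
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"synthetic section: {exc}")
    elif "inputs" in raw:
        i = raw["inputs"]
        st_path = Path(i.get("species_table", ""))
        if not st_path.exists():
            errors.append(f"species table file not found: {st_path}")
        fasta = {}
        for sp, p in (i.get("fasta") or {}).items():
            p = Path(p)
            if not p.exists():
                errors.append(f"proteome FASTA for {sp!r} not found: {p}")
            fasta[sp] = p
        tree_path = i.get("species_tree")
        if tree_path is not None and not Path(tree_path).exists():
            errors.append(f"species tree file not found: {tree_path}")
        if st_path.exists():
            try:
                table = SpeciesTable.from_tsv(st_path)
                known_species = set(table.species)
                for sp in fasta:
                    if sp not in known_species:
                        errors.append(f"proteome species {sp!r} missing from species table")
            except ValueError as exc:
                errors.append(str(exc))
        inputs = InputConfig(
            species_table=st_path, fasta=fasta,
            species_tree=Path(tree_path) if tree_path else None,
        )
    else:
        errors.append("config needs either a 'synthetic' or an 'inputs' section")

    family_runs = []
    for fam, fr in (raw.get("families") or {}).items():
        fr = fr or {}
        policy = fr.get("policy", "default")
        if policy not in POLICY_TABLE:
            errors.append(
                f"family {fam!r}: unknown policy class {policy!r} "
                f"(expected one of {sorted(POLICY_TABLE)})"
            )
        seeds = fr.get("seeds", {}) or {}
        if known_species:
            for sp in seeds:
                if sp not in known_species:
                    errors.append(
                        f"family {fam!r}: seed species {sp!r} not in species metadata"
                    )
        family_runs.append(FamilyRun(fam, dict(seeds), policy))

    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        master_seed=master_seed,
        output_dir=output_dir,
        synthetic=synthetic,
        inputs=inputs,
        family_runs=family_runs,
        z_cutoff=raw.get("filter", {}).get("z_cutoff", -2.5),
        consensus_mode=raw.get("consensus_mode", "union"),
        use_domain_fallback=raw.get("use_domain_fallback", True),
        n_boot=raw.get("tree", {}).get("n_boot", 100),
        gap_fraction_max=raw.get("tree", {}).get("gap_fraction_max", 0.5),
        n_shuffles=raw.get("n_shuffles", 100),
        raw=raw,
    )


@dataclass
class RunReport:
    """All tables and artifacts of a completed run."""

    output_dir: Path
    provenance: dict
    assignments: pd.DataFrame
    presence: PresenceMatrix | None
    features: pd.DataFrame | None
    trees: dict[str, str]  # family -> newick
    duplications: pd.DataFrame | None
    dollo: pd.DataFrame | None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class Pipeline:
    """Staged, resumable execution of the full analysis."""

    def __init__(self, config: RunConfig, resume: bool = False):
        self.cfg = config
        self.resume = resume
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.scheme = blosum62_scheme()
        self.species_table: SpeciesTable | None = None
        self.species_tree: SpeciesTree | None = None
        self.proteomes: dict[str, Proteome] = {}
        self.truth_df: pd.DataFrame | None = None
        self.assignments: pd.DataFrame | None = None

    # --- stage 1 -------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.cfg
        pdir = self.out / "proteomes"
        if cfg.synthetic is not None:
            syn = cfg.synthetic
            if self.resume and (self.out / "truth.tsv").exists():
                log.info("simulate: resuming from persisted outputs")
                self._load_inputs_from_outdir()
                return
            tree = simulate_species_tree(syn.n_species, syn.supergroup_plan, cfg.master_seed)
            evolved = [
                evolve_family(tree, spec, cfg.master_seed) for spec in syn.families
            ]
            table = tree.species_table()
            proteomes, truth_df = emit_proteomes(
                evolved, table, syn.n_decoys_per_species, cfg.master_seed,
                out_dir=pdir, decoy_inserts=syn.decoy_inserts,
            )
            table.to_tsv(self.out / "species.tsv")
            tree.write_newick(self.out / "species_tree.nwk")
            truth_df.to_csv(self.out / "truth.tsv", sep="\t", index=False)
            self.species_table, self.species_tree = table, tree
            self.proteomes, self.truth_df = proteomes, truth_df
            # auto-seed family runs that declare no explicit seed
            truths = {t.family_id: t for _, t in evolved}
            from .benchmark import pick_seed_gene

            for fr in cfg.family_runs:
                if not fr.seeds and fr.family in truths:
                    try:
                        sp, gene = pick_seed_gene(truths[fr.family])
                        fr.seeds = {sp: gene}
                    except ValueError:
                        log.warning("family %s extinct in simulation; skipped", fr.family)
            log.info(
                "simulate: %d species, %d families, %d proteins total",
                len(table), len(syn.families),
                sum(len(p) for p in proteomes.values()),
            )
        else:
            inp = cfg.inputs
            self.species_table = SpeciesTable.from_tsv(inp.species_table)
            self.proteomes = {
                sp: Proteome.from_fasta(p, species=sp) for sp, p in inp.fasta.items()
            }
            if inp.species_tree is not None:
                self.species_tree = SpeciesTree.from_newick(
                    str(inp.species_tree), self.species_table
                )
            log.info(
                "load: %d species, %d proteins",
                len(self.species_table),
                sum(len(p) for p in self.proteomes.values()),
            )

    def _load_inputs_from_outdir(self) -> None:
        self.species_table = SpeciesTable.from_tsv(self.out / "species.tsv")
        self.species_tree = SpeciesTree.from_newick(
            str(self.out / "species_tree.nwk"), self.species_table
        )
        self.proteomes = {
            sp: Proteome.from_fasta(self.out / "proteomes" / f"{sp}.fasta")
            for sp in self.species_table.species
        }
        self.truth_df = pd.read_csv(self.out / "truth.tsv", sep="\t", keep_default_na=False)
        if self.cfg.synthetic is not None:
            fam_truth_genes = {}
            for _, row in self.truth_df.iterrows():
                if row["family"]:
                    fam_truth_genes.setdefault(row["family"], {}).setdefault(
                        row["species"], []
                    ).append(row["gene"])
            for fr in self.cfg.family_runs:
                if not fr.seeds and fr.family in fam_truth_genes:
                    by_sp = fam_truth_genes[fr.family]
                    for sp in ["OPI01"] + sorted(by_sp):
                        if by_sp.get(sp):
                            fr.seeds = {sp: sorted(by_sp[sp])[0]}
                            break

    # --- stage 2 -------------------------------------------------------
    def assign(self) -> None:
        path = self.out / "assignments.tsv"
        if self.resume and path.exists():
            self.assignments = pd.read_csv(path, sep="\t", keep_default_na=False)
            log.info("assign: resumed %d rows", len(self.assignments))
            return
        ctx = SearchContext(
            self.proteomes, self.scheme,
            master_seed=self.cfg.master_seed, n_shuffles=self.cfg.n_shuffles,
        )
        frames = []
        for fr in self.cfg.family_runs:
            if not fr.seeds:
                log.warning("assign: family %s has no seeds; skipped", fr.family)
                continue
            res = run_family(
                fr.family, fr.seeds, self.proteomes, get_policy(fr.policy), ctx,
                z_cutoff=self.cfg.z_cutoff,
                use_domain_fallback=self.cfg.use_domain_fallback,
                consensus_mode=self.cfg.consensus_mode,
            )
            d = assignments_to_frame(res)
            kept = (d["status"] == "kept").sum()
            log.info(
                "assign: %s — %d candidates, %d kept, %d removed",
                fr.family, len(d), kept, len(d) - kept,
            )
            frames.append(d)
        self.assignments = (
            pd.concat(frames, ignore_index=True)
            if frames
            else assignments_to_frame([])
        )
        _write_tsv(self.assignments, path)

    # --- stage 3 -------------------------------------------------------
    def features(self) -> pd.DataFrame:
        kept = self.assignments[self.assignments["status"] == "kept"]
        tracks = []
        for _, row in kept.iterrows():
            seq = self.proteomes[row["species"]][row["gene"]]
            tracks.append(annotate_protein(row["gene"], seq))
        feats = feature_table(tracks)
        feats.insert(0, "family", list(kept["family"]))
        feats.insert(2, "species", list(kept["species"]))
        _write_tsv(feats, self.out / "features.tsv")
        _write_tsv(intervals_bed(tracks), self.out / "feature_intervals.tsv")
        log.info("features: annotated %d proteins", len(tracks))
        return feats

    # --- stage 4 -------------------------------------------------------
    def profile(self):
        table = self.species_table
        presence = build_presence_matrix(self.assignments, table)
        presence.to_tsv(self.out / "presence_matrix.tsv")
        trees: dict[str, str] = {}
        dup_rows = []
        dollo_rows = []
        tdir = self.out / "trees"
        tdir.mkdir(exist_ok=True)
        kept = self.assignments[self.assignments["status"] == "kept"]
        sg = {i.species: i.supergroup for i in table}
        kd = {i.species: i.kingdom for i in table}
        for fam, grp in kept.groupby("family"):
            if len(grp) >= 3:
                seqs = {
                    r["gene"]: self.proteomes[r["species"]][r["gene"]]
                    for _, r in grp.iterrows()
                }
                species_of = dict(zip(grp["gene"], grp["species"]))
                gt, _ = build_gene_tree(
                    seqs, self.scheme, species_of,
                    {g: sg[s] for g, s in species_of.items()},
                    {g: kd[s] for g, s in species_of.items()},
                    gap_fraction_max=self.cfg.gap_fraction_max,
                    n_boot=self.cfg.n_boot,
                    seed=stable_seed(self.cfg.master_seed, "bootstrap", fam),
                )
                trees[fam] = gt.newick()
                with open(tdir / f"{fam}.nwk", "w") as fh:
                    fh.write(trees[fam] + "\n")
                for c in classify_paralogs(gt):
                    dup_rows.append(
                        {
                            "family": fam,
                            "classification": c.classification,
                            "implicated_clade": c.implicated_clade,
                            "n_genes": len(c.node_leaves),
                            "genes": ",".join(sorted(c.node_leaves)),
                        }
                    )
            if self.species_tree is not None:
                row = {
                    sp: bool(presence.data.loc[fam, sp]) for sp in presence.data.columns
                }
                if any(row.values()):
                    rec = dollo_ancestral(row, self.species_tree)
                    dollo_rows.append(
                        {
                            "family": fam,
                            "gain_node": rec.gain_node,
                            "n_losses": len(rec.loss_branches),
                            "loss_branches": ",".join(rec.loss_branches),
                        }
                    )
        dups = pd.DataFrame(
            dup_rows,
            columns=["family", "classification", "implicated_clade", "n_genes", "genes"],
        )
        dollo = pd.DataFrame(
            dollo_rows, columns=["family", "gain_node", "n_losses", "loss_branches"]
        )
        _write_tsv(dups, self.out / "duplications.tsv")
        _write_tsv(dollo, self.out / "dollo.tsv")
        log.info(
            "profile: %d families, %d trees, %d duplication calls",
            presence.data.shape[0], len(trees), len(dups),
        )
        return presence, trees, dups, dollo

    # --- stage 5 -------------------------------------------------------
    def report(self, presence, trees, feats, dups, dollo) -> RunReport:
        provenance = {
            "config_hash": self.cfg.config_hash(),
            "master_seed": self.cfg.master_seed,
            "version": __version__,
            "n_species": len(self.species_table) if self.species_table else 0,
            "n_families": len(self.cfg.family_runs),
            "n_assignments_kept": int((self.assignments["status"] == "kept").sum()),
        }
        with open(self.out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        if presence is not None:
            render_coulson(presence, self.out / "coulson")
        return RunReport(
            output_dir=self.out,
            provenance=provenance,
            assignments=self.assignments,
            presence=presence,
            features=feats,
            trees=trees,
            duplications=dups,
            dollo=dollo,
        )


def run_pipeline(config: RunConfig, resume: bool = False) -> RunReport:
    """Execute all stages in order; outputs are persisted under the output dir."""
    pipe = Pipeline(config, resume=resume)
    pipe.simulate()
    pipe.assign()
    feats = pipe.features()
    presence, trees, dups, dollo = pipe.profile()
    return pipe.report(presence, trees, feats, dups, dollo)


def render_coulson(matrix: PresenceMatrix, out_prefix: str | Path) -> Path:
    """Write the presence matrix as TSV (the contract) and, when matplotlib is
    available, a wedge-grid figure (best effort)."""
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    matrix.to_tsv(tsv_path)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        data = matrix.data
        n_fam, n_sp = data.shape
        if n_fam and n_sp:
            fig, ax = plt.subplots(
                figsize=(max(4, 0.45 * n_sp), max(3, 0.4 * n_fam))
            )
            for yi, fam in enumerate(data.index):
                for xi, sp in enumerate(data.columns):
                    filled = bool(data.loc[fam, sp])
                    circ = plt.Circle(
                        (xi, n_fam - 1 - yi), 0.38,
                        facecolor="#2c6fbb" if filled else "white",
                        edgecolor="black", linewidth=0.6,
                    )
                    ax.add_patch(circ)
            ax.set_xlim(-0.8, n_sp - 0.2)
            ax.set_ylim(-0.8, n_fam - 0.2)
            ax.set_xticks(range(n_sp))
            ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
            ax.set_yticks(range(n_fam))
            ax.set_yticklabels(
                [f"{f} ({matrix.labels[f]})" for f in reversed(list(data.index))],
                fontsize=7,
            )
            ax.set_aspect("equal")
            ax.tick_params(length=0)
            for side in ax.spines.values():
                side.set_visible(False)
            fig.tight_layout()
            fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
            plt.close(fig)
    except Exception:  # pragma: no cover - plotting is best-effort
        log.info("coulson figure skipped (matplotlib unavailable or failed)")
    return tsv_path
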