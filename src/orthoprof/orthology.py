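"""Ortholog assignment by dual reciprocal searches with consensus and filtering.

Approach A: reciprocal single-sequence searches, with a best-domain fallback —
when full-sequence reciprocity fails (typical for multidomain fusions), the
best-domain segment of the forward hit is searched back instead, so orthologs
with alternative domain architectures are still recovered.

Approach B: reciprocal iterative profile searches. Family-class threshold
policies control iterations and E-value cutoffs: transmembrane/repeat families
use two iterations with a relaxed 1e-2 E-value; families built around common,
promiscuous domains use two iterations with a constrained 1e-20 E-value.

The per-species candidates of both approaches are merged into a consensus,
screened by an automated multiple-alignment outlier filter (a reproducible
surrogate for manual inspection), and missing orthologs are recovered by a
one-directional profile search into the suspect proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import MSA, align_multiple
from .core import Proteome, stable_seed
from .searchcore import (
    EvalueCalibration,
    Profile,
    ScoringScheme,
    SearchHit,
    blosum62_scheme,
    build_profile,
    calibrate_evalues,
    calibrate_profile_evalues,
    iterate_profile_search,
    search_profile,
    search_sequence,
)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Search-stringency class for a family."""

    label: str
    rounds: int
    inclusion_E: float
    acceptance_E: float

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.inclusion_E < 0 or self.acceptance_E <= 0:
            raise ValueError("E-value thresholds must be positive")


#: Stated policy table: TM/tandem-repeat families run two iterations at a
#: relaxed 1e-2; common-domain families two iterations at a constrained 1e-20.
#: "default" covers everything else (exposed in config).
POLICY_TABLE: dict[str, ThresholdPolicy] = {
    "tm_or_repeat": ThresholdPolicy("tm_or_repeat", rounds=2, inclusion_E=1e-2, acceptance_E=1e-2),
    "common_domain": ThresholdPolicy("common_domain", rounds=2, inclusion_E=1e-20, acceptance_E=1e-20),
    "default": ThresholdPolicy("default", rounds=2, inclusion_E=1e-3, acceptance_E=1e-3),
}


def get_policy(label: str) -> ThresholdPolicy:
    try:
        return POLICY_TABLE[label]
    except KeyError:
        raise ValueError(
            f"unknown policy class {label!r}; expected one of {sorted(POLICY_TABLE)}"
        ) from None


@dataclass
class ReciprocalResult:
    """Outcome of one reciprocal search from a query gene into a target species."""

    query: str
    target_species: str
    candidate: str | None
    status: str  # "full_hit" | "domain_fallback" | "failed"
    forward: SearchHit | None = None
    reverse: SearchHit | None = None

    def __post_init__(self):
        if (self.candidate is not None) != (self.status != "failed"):
            raise ValueError("candidate must be present iff status != failed")


@dataclass
class OrthologAssignment:
    """(family, species, gene) with provenance through the pipeline."""

    family: str
    species: str
    gene: str
    sources: set[str] = field(default_factory=set)  # subset of {"A","B","recovery"}
    confidence: str = "single_method"  # "consensus" | "single_method" | "recovered"
    status: str = "kept"  # "kept" | "removed"
    removal_reason: str | None = None
    conflict: bool = False
    forward_evalue: float | None = None
    reverse_evalue: float | None = None
    domain_fallback: bool = False

    def __post_init__(self):
        if self.confidence == "consensus" and not {"A", "B"} <= self.sources:
            raise ValueError("consensus requires both approaches among sources")
        if self.status == "removed" and not self.removal_reason:
            raise ValueError("removed assignments must carry a removal reason")


class SearchContext:
    """Caches calibrations and iterated profiles across a run.

    All per-call randomness (shuffle calibrations) is seeded from the master
    seed via stable hashing, so results do not depend on evaluation order.
    """

    def __init__(
        self,
        proteomes: dict[str, Proteome],
        scheme: ScoringScheme | None = None,
        master_seed: int = 0,
        n_shuffles: int = 100,
    ):
        self.proteomes = proteomes
        self.scheme = scheme or blosum62_scheme()
        self.master_seed = master_seed
        self.n_shuffles = max(100, n_shuffles)
        self._seq_calib: dict[str, EvalueCalibration] = {}
        self._profiles: dict[tuple, Profile] = {}
        self._prof_calib: dict[tuple, EvalueCalibration] = {}

    def seq_calib(self, species: str) -> EvalueCalibration:
        if species not in self._seq_calib:
            self._seq_calib[species] = calibrate_evalues(
                self.scheme,
                self.proteomes[species],
                n_shuffles=max(200, self.n_shuffles),
                seed=stable_seed(self.master_seed, "seq-calib", species),
            )
        return self._seq_calib[species]

    def iterated_profile(
        self, species: str, gene: str, rounds: int, inclusion_E: float
    ) -> tuple[tuple, Profile]:
        key = (species, gene, rounds, inclusion_E)
        if key not in self._profiles:
            self._profiles[key] = iterate_profile_search(
                self.proteomes[species][gene],
                self.proteomes[species],
                rounds,
                inclusion_E,
                self.scheme,
                seed_id=gene,
                calib_seed=stable_seed(self.master_seed, "iter-calib", species, gene),
            )
        return key, self._profiles[key]

    def family_profile(self, family: str, msa: MSA) -> tuple[tuple, Profile]:
        key = ("family", family, tuple(msa.names))
        if key not in self._profiles:
            self._profiles[key] = build_profile(msa, scheme=self.scheme)
        return key, self._profiles[key]

    def profile_calib(self, profile_key: tuple, species: str) -> EvalueCalibration:
        key = (profile_key, species)
        if key not in self._prof_calib:
            self._prof_calib[key] = calibrate_profile_evalues(
                self._profiles[profile_key],
                self.proteomes[species],
                n_shuffles=self.n_shuffles,
                seed=stable_seed(self.master_seed, "prof-calib", species, *profile_key[:2]),
            )
        return self._prof_calib[key]


def reciprocal_sequence_search(
    query: str,
    source: Proteome,
    target: Proteome,
    policy: ThresholdPolicy,
    ctx: SearchContext,
    use_domain_fallback: bool = True,
) -> ReciprocalResult:
    """Approach A: reciprocal single-sequence search with best-domain fallback.

    The forward best hit must find the query back in the source proteome at the
    acceptance E-value. If that fails, the target protein with the best
    *domain* E-value is taken and its domain segment alone is searched back;
    success there is reported as ``domain_fallback``.
    """
    if query not in source:
        raise ValueError(f"query {query!r} not in source proteome {source.species!r}")
    scheme = ctx.scheme
    fwd_hits = search_sequence(
        source[query], target, scheme, ctx.seq_calib(target.species), query_id=query
    )
    acc = policy.acceptance_E
    fail = ReciprocalResult(query, target.species, None, "failed")
    if not fwd_hits:
        return fail
    best = fwd_hits[0]
    if best.full_evalue <= acc:
        rev_hits = search_sequence(
            target[best.target_id], source, scheme, ctx.seq_calib(source.species),
            query_id=best.target_id,
        )
        if rev_hits and rev_hits[0].target_id == query and rev_hits[0].full_evalue <= acc:
            return ReciprocalResult(
                query, target.species, best.target_id, "full_hit", best, rev_hits[0]
            )
    if not use_domain_fallback:
        return fail
    # best domain-E hit from the target proteome (may differ from the best full hit)
    dom_best = min(fwd_hits, key=lambda h: (h.best_domain.evalue, h.target_id))
    if dom_best.best_domain.evalue > acc:
        return fail
    seg = target[dom_best.target_id][dom_best.best_domain.start - 1 : dom_best.best_domain.end]
    rev_hits = search_sequence(
        seg, source, scheme, ctx.seq_calib(source.species), query_id=dom_best.target_id
    )
    if rev_hits and rev_hits[0].target_id == query and rev_hits[0].full_evalue <= acc:
        return ReciprocalResult(
            query, target.species, dom_best.target_id, "domain_fallback", dom_best, rev_hits[0]
        )
    return fail


def reciprocal_profile_search(
    query: str,
    source: Proteome,
    target: Proteome,
    policy: ThresholdPolicy,
    ctx: SearchContext,
) -> ReciprocalResult:
    """Approach B: reciprocal iterative profile search (class-dependent thresholds)."""
    if query not in source:
        raise ValueError(f"query {query!r} not in source proteome {source.species!r}")
    fkey, fprof = ctx.iterated_profile(
        source.species, query, policy.rounds, policy.inclusion_E
    )
    fwd_hits = search_profile(
        fprof, target, ctx.profile_calib(fkey, target.species), query_id=query
    )
    acc = policy.acceptance_E
    fail = ReciprocalResult(query, target.species, None, "failed")
    if not fwd_hits or fwd_hits[0].full_evalue > acc:
        return fail
    best = fwd_hits[0]
    rkey, rprof = ctx.iterated_profile(
        target.species, best.target_id, policy.rounds, policy.inclusion_E
    )
    rev_hits = search_profile(
        rprof, source, ctx.profile_calib(rkey, source.species), query_id=best.target_id
    )
    if rev_hits and rev_hits[0].target_id == query and rev_hits[0].full_evalue <= acc:
        return ReciprocalResult(
            query, target.species, best.target_id, "full_hit", best, rev_hits[0]
        )
    return fail


def consensus_assign(
    family: str,
    a: dict[str, ReciprocalResult],
    b: dict[str, ReciprocalResult],
) -> list[OrthologAssignment]:
    """Merge per-species candidates of approaches A and B.

    Agreement yields a consensus assignment; a single successful method yields
    a provisional single-method assignment; disagreement emits both candidates
    flagged for the alignment filter.
    """
    if set(a) != set(b):
        raise ValueError("approaches A and B must cover the same species universe")
    out: list[OrthologAssignment] = []
    for species in a:
        ra, rb = a[species], b[species]

        def _mk(gene, sources, confidence, conflict=False):
            res = ra if "A" in sources else rb
            return OrthologAssignment(
                family=family,
                species=species,
                gene=gene,
                sources=set(sources),
                confidence=confidence,
                conflict=conflict,
                forward_evalue=res.forward.full_evalue if res.forward else None,
                reverse_evalue=res.reverse.full_evalue if res.reverse else None,
                domain_fallback=(ra.status == "domain_fallback" and "A" in sources),
            )

        if ra.candidate is not None and rb.candidate is not None:
            if ra.candidate == rb.candidate:
                out.append(_mk(ra.candidate, {"A", "B"}, "consensus"))
            else:
                out.append(_mk(ra.candidate, {"A"}, "single_method", conflict=True))
                out.append(_mk(rb.candidate, {"B"}, "single_method", conflict=True))
        elif ra.candidate is not None:
            out.append(_mk(ra.candidate, {"A"}, "single_method"))
        elif rb.candidate is not None:
            out.append(_mk(rb.candidate, {"B"}, "single_method"))
    return out


def _median_identities(msa: MSA) -> dict[str, float]:
    n = msa.n_rows
    out = {}
    for i in range(n):
        pids = [msa.percent_identity(i, j) for j in range(n) if j != i]
        out[msa.names[i]] = float(np.median(pids)) if pids else 1.0
    return out


def filter_by_msa(
    assignments: list[OrthologAssignment],
    proteomes: dict[str, Proteome],
    scheme: ScoringScheme,
    z_cutoff: float = -2.5,
    protected: set[str] | None = None,
) -> list[OrthologAssignment]:
    """Automated surrogate for manual alignment inspection.

    Aligns all kept candidates of one family, computes each sequence's median
    pairwise identity to the rest, and removes robust-z outliers (median/MAD,
    z < ``z_cutoff``), then re-aligns once and re-tests. Conflicting duplicate
    assignments for a species are resolved toward the higher-identity
    candidate. Seed genes (``protected``) are never removed.
    """
    protected = protected or set()
    kept = [x for x in assignments if x.status == "kept"]
    if len(kept) < 3:
        return assignments

    def gene_seq(x: OrthologAssignment) -> str:
        return proteomes[x.species][x.gene]

    for _pass in range(2):
        kept = [x for x in assignments if x.status == "kept"]
        if len(kept) < 3:
            break
        msa = align_multiple({x.gene: gene_seq(x) for x in kept}, scheme)
        med = _median_identities(msa)
        vals = np.array([med[x.gene] for x in kept])
        center = float(np.median(vals))
        mad = float(np.median(np.abs(vals - center)))
        # floor the robust scale at 5 identity points: in a tight family the
        # MAD collapses and mild divergence must not look like an outlier
        scale = max(1.4826 * mad, 0.05)
        if mad <= 1e-12 and np.allclose(vals, center):
            break
        removed_any = False
        for x in kept:
            z = (med[x.gene] - center) / scale
            if z < z_cutoff and x.gene not in protected:
                x.status = "removed"
                x.removal_reason = "msa_outlier"
                removed_any = True
        if not removed_any:
            break

    # resolve flagged duplicate candidates per species by identity
    kept = [x for x in assignments if x.status == "kept"]
    if len(kept) >= 3:
        msa = align_multiple({x.gene: gene_seq(x) for x in kept}, scheme)
        med = _median_identities(msa)
        by_species: dict[str, list[OrthologAssignment]] = {}
        for x in kept:
            if x.conflict:
                by_species.setdefault(x.species, []).append(x)
        for species, group in by_species.items():
            if len(group) < 2:
                continue
            group.sort(key=lambda x: (-med[x.gene], x.gene))
            for x in group[1:]:
                if x.gene not in protected:
                    x.status = "removed"
                    x.removal_reason = "conflict_lower_identity"
    return assignments


def recover_missing(
    family: str,
    assignments: list[OrthologAssignment],
    suspect: Proteome,
    policy: ThresholdPolicy,
    ctx: SearchContext,
) -> OrthologAssignment | None:
    """One-directional profile recovery into a proteome with no kept assignment.

    Builds a profile from the alignment of kept family members and accepts the
    best hit at the policy's acceptance E-value; reciprocity is deliberately
    not required for this sensitivity pass, and the result is flagged
    ``recovered``.
    """
    kept = [x for x in assignments if x.status == "kept"]
    if len(kept) < 2:
        return None
    if any(x.species == suspect.species for x in kept):
        return None
    seqs = {x.gene: ctx.proteomes[x.species][x.gene] for x in kept}
    msa = align_multiple(seqs, ctx.scheme)
    pkey, prof = ctx.family_profile(family, msa)
    hits = search_profile(prof, suspect, ctx.profile_calib(pkey, suspect.species),
                          query_id=f"{family}-recovery")
    if not hits or hits[0].full_evalue > policy.acceptance_E:
        return None
    return OrthologAssignment(
        family=family,
        species=suspect.species,
        gene=hits[0].target_id,
        sources={"recovery"},
        confidence="recovered",
        forward_evalue=hits[0].full_evalue,
    )


def run_family(
    family: str,
    seeds: dict[str, str],
    proteomes: dict[str, Proteome],
    policy: ThresholdPolicy,
    ctx: SearchContext,
    z_cutoff: float = -2.5,
    use_domain_fallback: bool = True,
    consensus_mode: str = "union",
) -> list[OrthologAssignment]:
    """Full assignment procedure for one family from one or more seed organisms.

    Runs approaches A and B from every seed, consensuses per seed, unions
    across seeds (``consensus_mode="agreement"`` instead keeps only
    cross-method consensus assignments), filters by alignment, then attempts
    recovery in species left without a kept assignment.
    """
    if not seeds:
        raise ValueError("at least one seed gene required")
    if consensus_mode not in ("union", "agreement"):
        raise ValueError("consensus_mode must be 'union' or 'agreement'")
    merged: dict[tuple[str, str], OrthologAssignment] = {}
    for src_species in sorted(seeds):
        gene = seeds[src_species]
        source = proteomes[src_species]
        if gene not in source:
            raise ValueError(f"seed gene {gene!r} not in proteome {src_species!r}")
        res_a: dict[str, ReciprocalResult] = {}
        res_b: dict[str, ReciprocalResult] = {}
        for sp in sorted(proteomes):
            if sp == src_species:
                continue
            res_a[sp] = reciprocal_sequence_search(
                gene, source, proteomes[sp], policy, ctx, use_domain_fallback
            )
            res_b[sp] = reciprocal_profile_search(gene, source, proteomes[sp], policy, ctx)
        per_seed = consensus_assign(family, res_a, res_b)
        per_seed.append(
            OrthologAssignment(
                family=family, species=src_species, gene=gene,
                sources={"A", "B"}, confidence="consensus",
            )
        )
        for x in per_seed:
            key = (x.species, x.gene)
            if key in merged:
                prev = merged[key]
                prev.sources |= x.sources
                if {"A", "B"} <= prev.sources and not (prev.conflict and x.conflict):
                    prev.confidence = "consensus"
                    prev.conflict = False
                prev.domain_fallback = prev.domain_fallback or x.domain_fallback
            else:
                merged[key] = x
    assignments = list(merged.values())
    if consensus_mode == "agreement":
        for x in assignments:
            if x.confidence != "consensus":
                x.status = "removed"
                x.removal_reason = "no_cross_method_agreement"
    assignments = filter_by_msa(
        assignments, proteomes, ctx.scheme, z_cutoff, protected=set(seeds.values())
    )
    covered = {x.species for x in assignments if x.status == "kept"}
    for sp in sorted(proteomes):
        if sp in covered:
            continue
        rec = recover_missing(family, assignments, proteomes[sp], policy, ctx)
        if rec is not None:
            assignments.append(rec)
    assignments.sort(key=lambda x: (x.species, x.gene))
    return assignments


def assignments_to_frame(assignments: list[OrthologAssignment]) -> pd.DataFrame:
    """Flatten assignments into the pipeline's TSV-ready table."""
    rows = []
    for x in assignments:
        rows.append(
            {
                "family": x.family,
                "species": x.species,
                "gene": x.gene,
                "sources": "+".join(sorted(x.sources)),
                "confidence": x.confidence,
                "status": x.status,
                "removal_reason": x.removal_reason or "",
                "conflict": int(x.conflict),
                "forward_E": "" if x.forward_evalue is None else f"{x.forward_evalue:.3g}",
                "reverse_E": "" if x.reverse_evalue is None else f"{x.reverse_evalue:.3g}",
                "domain_fallback": int(x.domain_fallback),
            }
        )
    cols = [
        "family", "species", "gene", "sources", "confidence", "status",
        "removal_reason", "conflict", "forward_E", "reverse_E", "domain_fallback",
    ]
    return pd.DataFrame(rows, columns=cols)
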