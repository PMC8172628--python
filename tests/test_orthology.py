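"""Ortholog-assignment tests: policies, reciprocity, consensus, filter, recovery."""

from __future__ import annotations

import numpy as np
import pytest

from orthoprof.core import Proteome, encode_seq, decode_seq
from orthoprof.orthology import (
    POLICY_TABLE,
    OrthologAssignment,
    ReciprocalResult,
    SearchContext,
    ThresholdPolicy,
    assignments_to_frame,
    consensus_assign,
    filter_by_msa,
    get_policy,
    reciprocal_profile_search,
    reciprocal_sequence_search,
    recover_missing,
    run_family,
)
from orthoprof.seqsim import FamilySpec, _mutate, evolve_family


class TestThresholdPolicies:
    def test_stated_policy_table(self):
        """TM/repeat: two iterations, relaxed 1e-2; common domain: two
        iterations, constrained 1e-20."""
        tm = get_policy("tm_or_repeat")
        assert (tm.rounds, tm.inclusion_E) == (2, 1e-2)
        cd = get_policy("common_domain")
        assert (cd.rounds, cd.inclusion_E) == (2, 1e-20)
        assert get_policy("default").rounds == 2

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="unknown policy"):
            get_policy("nonsense")

    def test_invalid_policy_values_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPolicy("x", rounds=0, inclusion_E=1e-3, acceptance_E=1e-3)
        with pytest.raises(ValueError):
            ThresholdPolicy("x", rounds=2, inclusion_E=1e-3, acceptance_E=0.0)


class TestReciprocalSequenceSearch:
    def test_exact_copy_full_hit(self, small_world):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        src_sp = sorted(truth.genes_by_species)[0]
        gene = truth.genes_by_species[src_sp][0]
        # target proteome containing an exact copy of the query
        target = Proteome("COPY", dict(prot[src_sp].sequences))
        target.sequences["copy_of_query"] = prot[src_sp][gene]
        del target.sequences[gene]
        ctx = SearchContext({**prot, "COPY": target}, master_seed=7)
        res = reciprocal_sequence_search(
            gene, prot[src_sp], target, get_policy("default"), ctx
        )
        assert res.status == "full_hit" and res.candidate == "copy_of_query"

    def test_decoy_only_target_fails(self, small_world):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        src_sp = sorted(truth.genes_by_species)[0]
        gene = truth.genes_by_species[src_sp][0]
        sp2 = sorted(p for p in prot if p != src_sp)[0]
        decoys = {
            g: s for g, s in prot[sp2].sequences.items() if "decoy" in g
        }
        target = Proteome("DEC", decoys)
        ctx = SearchContext({**prot, "DEC": target}, master_seed=7)
        res = reciprocal_sequence_search(
            gene, prot[src_sp], target, get_policy("default"), ctx
        )
        assert res.status == "failed" and res.candidate is None

    def test_query_missing_from_source_rejected(self, small_world):
        prot = small_world["proteomes"]
        sps = sorted(prot)
        ctx = small_world["ctx"]
        with pytest.raises(ValueError, match="not in source"):
            reciprocal_sequence_search(
                "no_such_gene", prot[sps[0]], prot[sps[1]], get_policy("default"), ctx
            )

    def test_reciprocity_symmetry(self, small_world):
        """A full-hit pair reciprocates when the search is started from the
        other side."""
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        q = truth.genes_by_species[sps[0]][0]
        res = reciprocal_sequence_search(
            q, prot[sps[0]], prot[sps[1]], get_policy("default"), ctx
        )
        assert res.status == "full_hit"
        back = reciprocal_sequence_search(
            res.candidate, prot[sps[1]], prot[sps[0]], get_policy("default"), ctx
        )
        assert back.status == "full_hit" and back.candidate == q


class TestFusionFallback:
    def test_fusion_detected_via_domain_fallback(self, fusion_world):
        prot = fusion_world["proteomes"]
        truth = fusion_world["truth"]
        ctx = fusion_world["ctx"]
        src_sp = "OPI01"
        sar_sp = "SAR01"
        gene = truth.genes_by_species[src_sp][0]
        res = reciprocal_sequence_search(
            gene, prot[src_sp], prot[sar_sp], get_policy("default"), ctx
        )
        assert res.status == "domain_fallback"
        assert res.candidate == truth.genes_by_species[sar_sp][0]

    def test_fallback_ablation_fails(self, fusion_world):
        prot = fusion_world["proteomes"]
        truth = fusion_world["truth"]
        ctx = fusion_world["ctx"]
        gene = truth.genes_by_species["OPI01"][0]
        res = reciprocal_sequence_search(
            gene, prot["OPI01"], prot["SAR01"], get_policy("default"), ctx,
            use_domain_fallback=False,
        )
        assert res.status == "failed"


class TestReciprocalProfileSearch:
    def test_profile_search_finds_ortholog(self, small_world):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        q = truth.genes_by_species[sps[0]][0]
        res = reciprocal_profile_search(
            q, prot[sps[0]], prot[sps[1]], get_policy("default"), ctx
        )
        assert res.status == "full_hit"
        assert res.candidate == truth.genes_by_species[sps[1]][0]

    def test_common_domain_policy_blocks_promiscuous_decoys(self, benchmark_run):
        """With the promiscuous-domain family, distant decoy relatives carrying
        the common block are rejected at the constrained 1e-20 threshold but
        accepted by the relaxed 1e-2 forward search (where reciprocity then
        has to sort them out)."""
        prot = benchmark_run["proteomes"]
        truth = benchmark_run["truths"]["fam09_common"]
        ctx = benchmark_run["ctx"]
        src_sp = "OPI01"
        gene = truth.genes_by_species[src_sp][0]
        sp2 = "SAR01"
        strict = reciprocal_profile_search(
            gene, prot[src_sp], prot[sp2], get_policy("common_domain"), ctx
        )
        assert strict.status == "full_hit"
        assert strict.candidate == truth.genes_by_species[sp2][0]
        # the relaxed threshold admits decoy relatives of the common domain
        # that the constrained threshold excludes
        from orthoprof.searchcore import search_profile

        fkey, fprof = ctx.iterated_profile(src_sp, gene, 2, 1e-20)
        hits = search_profile(fprof, prot[sp2], ctx.profile_calib(fkey, sp2))
        relaxed = [
            h for h in hits if "decoy" in h.target_id and h.full_evalue <= 1e-2
        ]
        strict_set = [h for h in relaxed if h.full_evalue <= 1e-20]
        assert relaxed, "expected promiscuous decoy relatives at the relaxed threshold"
        assert len(strict_set) < len(relaxed)


class TestConsensus:
    @staticmethod
    def _res(q, sp, gene, status="full_hit"):
        return ReciprocalResult(q, sp, gene, status)

    def test_agreement_gives_consensus(self):
        a = {"S1": self._res("q", "S1", "g1")}
        b = {"S1": self._res("q", "S1", "g1")}
        out = consensus_assign("fam", a, b)
        assert len(out) == 1
        assert out[0].confidence == "consensus" and out[0].sources == {"A", "B"}

    def test_single_method_kept_provisionally(self):
        a = {"S1": self._res("q", "S1", "g1")}
        b = {"S1": self._res("q", "S1", None, "failed")}
        out = consensus_assign("fam", a, b)
        assert len(out) == 1
        assert out[0].confidence == "single_method" and out[0].sources == {"A"}

    def test_disagreement_emits_both_flagged(self):
        a = {"S1": self._res("q", "S1", "g1")}
        b = {"S1": self._res("q", "S1", "g2")}
        out = consensus_assign("fam", a, b)
        assert len(out) == 2
        assert all(x.conflict and x.confidence == "single_method" for x in out)
        assert {x.gene for x in out} == {"g1", "g2"}

    def test_both_fail_no_assignment(self):
        a = {"S1": self._res("q", "S1", None, "failed")}
        b = {"S1": self._res("q", "S1", None, "failed")}
        assert consensus_assign("fam", a, b) == []

    def test_species_universe_mismatch_rejected(self):
        a = {"S1": self._res("q", "S1", "g1")}
        with pytest.raises(ValueError):
            consensus_assign("fam", a, {})

    def test_consensus_requires_both_sources(self):
        with pytest.raises(ValueError):
            OrthologAssignment("f", "S1", "g", sources={"A"}, confidence="consensus")


def _mk_assign(family, species, gene, **kw):
    return OrthologAssignment(family=family, species=species, gene=gene,
                              sources={"A"}, **kw)


class TestMsaFilter:
    def test_decoy_outlier_removed(self, small_world, scheme):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        assigns = [
            _mk_assign("famA", sp, g)
            for sp, gs in sorted(truth.genes_by_species.items())
            for g in gs
        ]
        decoy_sp = sorted(prot)[0]
        decoy = next(g for g in prot[decoy_sp].gene_ids if "decoy" in g)
        assigns.append(_mk_assign("famA", decoy_sp, decoy))
        out = filter_by_msa(assigns, prot, scheme)
        status = {x.gene: x.status for x in out}
        assert status[decoy] == "removed"
        for sp, gs in truth.genes_by_species.items():
            for g in gs:
                assert status[g] == "kept"
        removed = next(x for x in out if x.gene == decoy)
        assert removed.removal_reason == "msa_outlier"

    def test_all_identical_none_removed(self, scheme):
        prot = {"S": Proteome("S", {f"g{i}": "MKTAYIAKQRQISFVKSHFSRQ" for i in range(4)})}
        assigns = [_mk_assign("f", "S", f"g{i}") for i in range(4)]
        out = filter_by_msa(assigns, prot, scheme)
        assert all(x.status == "kept" for x in out)

    def test_two_candidates_filter_skipped(self, scheme):
        prot = {"S": Proteome("S", {"g1": "MKTAYIAKQRQIS", "g2": "WWWWPPPPGGGG"})}
        assigns = [_mk_assign("f", "S", "g1"), _mk_assign("f", "S", "g2")]
        out = filter_by_msa(assigns, prot, scheme)
        assert all(x.status == "kept" for x in out)

    def test_seed_gene_never_removed(self, small_world, scheme):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        decoy_sp = sorted(prot)[0]
        decoy = next(g for g in prot[decoy_sp].gene_ids if "decoy" in g)
        assigns = [
            _mk_assign("famA", sp, g)
            for sp, gs in sorted(truth.genes_by_species.items())
            for g in gs
        ] + [_mk_assign("famA", decoy_sp, decoy)]
        out = filter_by_msa(assigns, prot, scheme, protected={decoy})
        assert next(x for x in out if x.gene == decoy).status == "kept"


class TestRecovery:
    def test_divergent_member_recovered(self, small_world):
        """A species' assignments are withheld; the family profile still finds
        its true member one-directionally."""
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        suspect = sps[-1]
        assigns = [
            _mk_assign("famA", sp, g)
            for sp in sps[:-1]
            for g in truth.genes_by_species[sp]
        ]
        rec = recover_missing("famA", assigns, prot[suspect], get_policy("default"), ctx)
        assert rec is not None
        assert rec.gene == truth.genes_by_species[suspect][0]
        assert rec.confidence == "recovered" and rec.sources == {"recovery"}

    def test_truly_lost_species_not_recovered(self, small_world, rng):
        """A proteome of unrelated decoys yields no recovery hit."""
        prot = dict(small_world["proteomes"])
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        from orthoprof.core import AMINO_ACIDS, BACKGROUND_FREQS

        lost = Proteome(
            "LOST",
            {
                f"x{i}": "".join(
                    AMINO_ACIDS[j] for j in rng.choice(20, 200, p=BACKGROUND_FREQS)
                )
                for i in range(6)
            },
        )
        ctx2 = SearchContext({**prot, "LOST": lost}, master_seed=7)
        assigns = [
            _mk_assign("famA", sp, g)
            for sp in sps
            for g in truth.genes_by_species[sp]
        ]
        assert recover_missing("famA", assigns, lost, get_policy("default"), ctx2) is None

    def test_single_member_family_skipped(self, small_world):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        assigns = [_mk_assign("famA", sps[0], truth.genes_by_species[sps[0]][0])]
        assert recover_missing("famA", assigns, prot[sps[1]], get_policy("default"), ctx) is None


class TestRunFamily:
    def test_clean_family_all_consensus(self, small_world):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        seed_sp = sps[0]
        res = run_family(
            "famA", {seed_sp: truth.genes_by_species[seed_sp][0]}, prot,
            get_policy("default"), ctx,
        )
        kept = [x for x in res if x.status == "kept"]
        by_sp = {x.species: x for x in kept}
        for sp in sps:
            assert by_sp[sp].gene in truth.genes_by_species[sp]

    def test_two_identical_seeds_idempotent(self, small_world):
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        one = run_family(
            "famA", {sps[0]: truth.genes_by_species[sps[0]][0]}, prot,
            get_policy("default"), ctx,
        )
        two = run_family(
            "famA",
            {
                sps[0]: truth.genes_by_species[sps[0]][0],
                sps[1]: truth.genes_by_species[sps[1]][0],
            },
            prot, get_policy("default"), ctx,
        )
        kept1 = {(x.species, x.gene) for x in one if x.status == "kept"}
        kept2 = {(x.species, x.gene) for x in two if x.status == "kept"}
        assert kept1 == kept2

    def test_no_seeds_rejected(self, small_world):
        with pytest.raises(ValueError):
            run_family("famA", {}, small_world["proteomes"],
                       get_policy("default"), small_world["ctx"])

    def test_no_invented_assignments(self, small_world):
        """Every output gene exists in the proteome of its species."""
        prot = small_world["proteomes"]
        truth = small_world["truth"]
        ctx = small_world["ctx"]
        sps = sorted(s for s in truth.genes_by_species if truth.genes_by_species[s])
        res = run_family(
            "famA", {sps[0]: truth.genes_by_species[sps[0]][0]}, prot,
            get_policy("default"), ctx,
        )
        for x in res:
            assert x.gene in prot[x.species]

    def test_frame_columns(self, small_world):
        df = assignments_to_frame(
            [_mk_assign("f", "S", "g", forward_evalue=1e-5)]
        )
        assert list(df.columns[:6]) == [
            "family", "species", "gene", "sources", "confidence", "status"
        ]
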