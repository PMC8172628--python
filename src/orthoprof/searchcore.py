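"""Homology-search engine: local alignment, E-value calibration, profiles.

This is the engine underlying both ortholog-search approaches. It provides
affine-gap Smith–Waterman alignment with a full-sequence vs best-domain score
decomposition, empirical E-value calibration (seeded shuffles + Gumbel fit),
position-specific scoring profiles built from alignments, and iterative profile
search with an E-value inclusion threshold.

Scores are reported in bits; E-values follow ``E(S) = kappa * m * n *
exp(-lambda * S_raw)`` with ``m`` the query (or profile) length and ``n`` the
database residue count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from . import _kernels
from .alignment import MSA, align_multiple  # noqa: F401  (re-exported surface)
from .core import ALPHABET, AMINO_ACIDS, BACKGROUND_FREQS, Proteome, encode_seq

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix (21x21, X row/column zero) with affine gap penalties."""

    matrix: np.ndarray
    gap_open: int = -11
    gap_extend: int = -1
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_FREQS.copy())

    def __post_init__(self):
        m = self.matrix
        if m.shape != (21, 21):
            raise ValueError("matrix must be 21x21 (20 residues + X)")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        p = self.background
        exp_score = float(p @ m[:20, :20] @ p)
        if exp_score >= 0:
            raise ValueError(
                "expected substitution score under background must be negative "
                f"for local alignment (got {exp_score:.3f})"
            )

    def replace(self, **kw) -> "ScoringScheme":
        from dataclasses import replace

        return replace(self, **kw)


def blosum62_scheme(gap_open: int = -11, gap_extend: int = -1) -> ScoringScheme:
    """Community-default scoring: BLOSUM62 with affine gaps -11/-1."""
    bl = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = bl[a, b]
    return ScoringScheme(matrix=m, gap_open=gap_open, gap_extend=gap_extend)


@dataclass
class LocalAlignment:
    """One optimal local segment pair; coordinates 1-based inclusive, 0 if empty."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def empty(self) -> bool:
        return self.score <= 0.0


def local_align(a: str, b: str, scheme: ScoringScheme) -> LocalAlignment:
    """Maximal affine-gap local alignment of two protein sequences."""
    ea, eb = encode_seq(a), encode_seq(b)
    mask = np.ones(len(eb), dtype=np.uint8)
    score, a1, a2, b1, b2 = _kernels.sw_best_segment(
        ea, eb, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend), mask
    )
    return LocalAlignment(float(score), a1, a2, b1, b2)


def _segment_decomposition(
    ea: np.ndarray,
    eb: np.ndarray,
    mat: np.ndarray,
    gap_open: float,
    gap_extend: float,
    max_segments: int = 3,
    min_extra_score: float = 30.0,
):
    """Greedy disjoint-segment decomposition of the local similarity.

    The first (best) segment is always reported if positive; further segments
    are found by masking already-claimed target positions and re-aligning, and
    are kept while their raw score is at least ``min_extra_score``. Mirrors the
    full-sequence vs best-domain split of profile search tools.
    """
    mask = np.ones(len(eb), dtype=np.uint8)
    segments = []
    for k in range(max_segments):
        score, a1, a2, b1, b2 = _kernels.sw_best_segment(
            ea, eb, mat, gap_open, gap_extend, mask
        )
        if score <= 0.0 or (k > 0 and score < min_extra_score):
            break
        segments.append((float(score), a1, a2, b1, b2))
        mask[b1 - 1 : b2] = 0
        if not mask.any():
            break
    return segments


#: an extra disjoint segment contributes to the full-sequence score only if it
#: is individually significant at this E-value (prevents noise-segment stacking)
EXTRA_DOMAIN_MAX_E = 0.1


def _full_and_domain(segs, calib, m, n_db):
    """Full-sequence raw score (significant segments only) and the best domain."""
    raw_dom = segs[0][0]
    raw_full = raw_dom
    for s in segs[1:]:
        if calib.evalue(s[0], m, n_db) <= EXTRA_DOMAIN_MAX_E:
            raw_full += s[0]
    return raw_full, segs[0]


@dataclass
class EvalueCalibration:
    """Gumbel tail parameters for converting raw scores to E-values."""

    lam: float
    kappa: float
    db_residues: int
    method: str = "shuffle-gumbel"

    def __post_init__(self):
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")

    def evalue(self, raw_score: float, m: int, n: int | None = None) -> float:
        n = self.db_residues if n is None else n
        return float(self.kappa * m * n * np.exp(-self.lam * raw_score))

    def bits(self, raw_score: float) -> float:
        return float((self.lam * raw_score - np.log(self.kappa)) / _LN2)


def _fit_gumbel(scores: np.ndarray, mn: np.ndarray, db_residues: int, method: str):
    if np.allclose(scores, scores[0]):
        raise ValueError(
            "degenerate score distribution: all shuffled-pair scores equal "
            f"({scores[0]:.1f}); cannot fit an extreme-value tail"
        )
    mu, beta = gumbel_r.fit(scores)
    lam = 1.0 / beta
    # E(S) = kappa*m*n*exp(-lam*S); Gumbel location mu satisfies kappa*mn = exp(lam*mu)
    log_kappa = lam * mu - float(np.mean(np.log(mn)))
    kappa = float(np.exp(log_kappa))
    return EvalueCalibration(lam=lam, kappa=kappa, db_residues=db_residues, method=method)


def calibrate_evalues(
    scheme: ScoringScheme,
    database: Proteome,
    n_shuffles: int = 200,
    seed: int = 0,
) -> EvalueCalibration:
    """Fit Gumbel E-value parameters from shuffled query/target pairs."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a usable tail fit")
    if len(database) < 2:
        raise ValueError("database must contain at least 2 sequences")
    rng = np.random.default_rng(seed)
    enc = [database.encoded()[g] for g in sorted(database.gene_ids)]
    scores = np.empty(n_shuffles)
    mn = np.empty(n_shuffles)
    mask_cache: dict[int, np.ndarray] = {}
    for k in range(n_shuffles):
        i, j = rng.integers(0, len(enc), size=2)
        a = rng.permutation(enc[i])
        b = rng.permutation(enc[j])
        mask = mask_cache.setdefault(len(b), np.ones(len(b), dtype=np.uint8))
        s, *_ = _kernels.sw_best_segment(
            a, b, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend), mask
        )
        scores[k] = s
        mn[k] = len(a) * len(b)
    return _fit_gumbel(scores, mn, database.total_residues, "shuffle-gumbel")


@dataclass
class DomainHit:
    """Best single local segment on the target; 1-based inclusive coordinates."""

    start: int
    end: int
    score: float
    evalue: float


@dataclass
class SearchHit:
    """One query-vs-target result with full-sequence and best-domain scores (bits)."""

    query_id: str
    target_id: str
    full_score: float
    full_evalue: float
    best_domain: DomainHit
    rank: int = 0

    def __post_init__(self):
        if self.full_score < self.best_domain.score - 1e-9:
            raise ValueError("full_score must be >= best-domain score")
        if self.full_evalue < 0 or self.best_domain.evalue < 0:
            raise ValueError("E-values must be non-negative")
        if not (1 <= self.best_domain.start <= self.best_domain.end):
            raise ValueError("domain coordinates must satisfy 1 <= start <= end")


def _rank_hits(hits: list[SearchHit]) -> list[SearchHit]:
    hits.sort(key=lambda h: (h.full_evalue, -h.full_score, h.target_id))
    for r, h in enumerate(hits, start=1):
        h.rank = r
    return hits


def search_sequence(
    query: str,
    target: Proteome,
    scheme: ScoringScheme,
    calib: EvalueCalibration,
    query_id: str = "query",
) -> list[SearchHit]:
    """Score a query against every protein of a target proteome.

    One hit per target protein with positive score, ranked by ascending
    full-sequence E-value (ties: descending score, then target id).
    """
    ea = encode_seq(query)
    n_db = target.total_residues
    hits: list[SearchHit] = []
    for gene, eb in target.encoded().items():
        segs = _segment_decomposition(
            ea, eb, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)
        )
        if not segs:
            continue
        raw_full, (raw_dom, _, _, b1, b2) = _full_and_domain(segs, calib, len(ea), n_db)
        dom = DomainHit(
            start=b1,
            end=b2,
            score=calib.bits(raw_dom),
            evalue=calib.evalue(raw_dom, len(ea), n_db),
        )
        hits.append(
            SearchHit(
                query_id=query_id,
                target_id=gene,
                full_score=calib.bits(raw_full),
                full_evalue=calib.evalue(raw_full, len(ea), n_db),
                best_domain=dom,
            )
        )
    return _rank_hits(hits)


@dataclass
class Profile:
    """Position-specific scoring profile (log-odds in half-bit units).

    Columns correspond to the consensus columns (<= 50% gaps) of the seed
    alignment. ``scores`` has shape (n_columns, 21); the X column is zero.
    """

    scores: np.ndarray
    occupancy: np.ndarray
    seed_names: list[str]
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.scores.ndim != 2 or self.scores.shape[1] != 21:
            raise ValueError("profile scores must have shape (n_columns, 21)")
        if not np.isfinite(self.scores).all():
            raise ValueError("profile scores must be finite (pseudocounts missing?)")
        if len(self.occupancy) != self.scores.shape[0]:
            raise ValueError("occupancy length must equal column count")

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.scores[:, :20], axis=1))


def _conditional_substitution_probs(scheme: ScoringScheme) -> np.ndarray:
    """P(b | a) derived from the scoring matrix: ~ bg_b * 2^(S_ab/2), row-normalized."""
    bg = scheme.background
    q = bg[None, :] * np.exp2(scheme.matrix[:20, :20] / 2.0)
    return q / q.sum(axis=1, keepdims=True)


def build_profile(
    msa: MSA,
    pseudocount_weight: float = 2.0,
    scheme: ScoringScheme | None = None,
    gap_open: float | None = None,
    gap_extend: float | None = None,
) -> Profile:
    """Build a log-odds profile from an alignment with matrix-informed pseudocounts.

    Per consensus column c with observed residue frequencies f and non-gap count
    n, the estimated residue distribution is ``(n*f + alpha*g) / (n + alpha)``
    where ``g = f @ P(b|a)`` redistributes observations through the substitution
    matrix (so even a single sequence yields the matrix's preference order).
    Scores are ``2*log2(p/background)`` — half-bit units, matching BLOSUM62.
    """
    if msa.n_rows < 1:
        raise ValueError("profile requires at least one sequence")
    scheme = scheme or blosum62_scheme()
    cols = msa.consensus_columns(0.5)
    if len(cols) == 0:
        raise ValueError("alignment has zero consensus columns (<=50% gaps)")
    alpha = float(pseudocount_weight)
    if alpha <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = scheme.background
    cond = _conditional_substitution_probs(scheme)
    n_cols = len(cols)
    scores = np.zeros((n_cols, 21))
    occupancy = np.zeros(n_cols)
    for k, c in enumerate(cols):
        col = msa.column(c)
        counts = np.zeros(20)
        for ch in col:
            if ch != "-" and ch != "X":
                counts[AA_INDEX20[ch]] += 1
        n = counts.sum()
        occupancy[k] = n / msa.n_rows
        if n == 0:
            p = bg.copy()
        else:
            f = counts / n
            g = f @ cond
            p = (n * f + alpha * g) / (n + alpha)
        scores[k, :20] = 2.0 * np.log2(p / bg)
    return Profile(
        scores=scores,
        occupancy=occupancy,
        seed_names=list(msa.names),
        gap_open=float(gap_open if gap_open is not None else scheme.gap_open),
        gap_extend=float(gap_extend if gap_extend is not None else scheme.gap_extend),
    )


AA_INDEX20 = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def calibrate_profile_evalues(
    profile: Profile,
    database: Proteome,
    n_shuffles: int = 100,
    seed: int = 0,
) -> EvalueCalibration:
    """Gumbel calibration for profile scores against shuffled database sequences."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a usable tail fit")
    rng = np.random.default_rng(seed)
    enc = [database.encoded()[g] for g in sorted(database.gene_ids)]
    prof_idx = np.arange(profile.n_columns, dtype=np.int64)
    scores = np.empty(n_shuffles)
    mn = np.empty(n_shuffles)
    for k in range(n_shuffles):
        b = rng.permutation(enc[rng.integers(0, len(enc))])
        mask = np.ones(len(b), dtype=np.uint8)
        s, *_ = _kernels.sw_best_segment(
            prof_idx, b, profile.scores, profile.gap_open, profile.gap_extend, mask
        )
        scores[k] = s
        mn[k] = profile.n_columns * len(b)
    return _fit_gumbel(scores, mn, database.total_residues, "profile-shuffle-gumbel")


def search_profile(
    profile: Profile,
    target: Proteome,
    calib: EvalueCalibration,
    query_id: str = "profile",
) -> list[SearchHit]:
    """Scan a target proteome with a profile; ranking rules as in search_sequence."""
    prof_idx = np.arange(profile.n_columns, dtype=np.int64)
    n_db = target.total_residues
    hits: list[SearchHit] = []
    for gene, eb in target.encoded().items():
        segs = _segment_decomposition(
            prof_idx, eb, profile.scores, profile.gap_open, profile.gap_extend
        )
        if not segs:
            continue
        raw_full, (raw_dom, _, _, b1, b2) = _full_and_domain(
            segs, calib, profile.n_columns, n_db
        )
        dom = DomainHit(
            start=b1,
            end=b2,
            score=calib.bits(raw_dom),
            evalue=calib.evalue(raw_dom, profile.n_columns, n_db),
        )
        hits.append(
            SearchHit(
                query_id=query_id,
                target_id=gene,
                full_score=calib.bits(raw_full),
                full_evalue=calib.evalue(raw_full, profile.n_columns, n_db),
                best_domain=dom,
            )
        )
    return _rank_hits(hits)


def align_to_profile(profile: Profile, seq: str) -> tuple[float, dict[int, str]]:
    """Locally align a sequence to profile columns.

    Returns the raw score and a map ``{column_index: residue}`` for matched
    columns (insertions relative to the profile are dropped; the profile's
    column count is fixed by its seed alignment).
    """
    prof_idx = np.arange(profile.n_columns, dtype=np.int64)
    eb = encode_seq(seq)
    score, bi, bj, ptrH, ptrE, ptrF = _kernels.sw_fill(
        prof_idx, eb, profile.scores, profile.gap_open, profile.gap_extend
    )
    if score <= 0:
        return 0.0, {}
    cols_a, cols_b = _kernels.traceback_local(bi, bj, ptrH, ptrE, ptrF)
    mapping = {
        ca: seq[cb] for ca, cb in zip(cols_a, cols_b) if ca != -1 and cb != -1
    }
    return float(score), mapping


def profile_msa(profile: Profile, members: dict[str, str]) -> MSA:
    """Stack sequences aligned to a profile's columns into an MSA."""
    names = sorted(members)
    rows = []
    for n in names:
        _, mapping = align_to_profile(profile, members[n])
        rows.append("".join(mapping.get(c, "-") for c in range(profile.n_columns)))
    return MSA(names, rows)


def iterate_profile_search(
    seed_query: str,
    source: Proteome,
    rounds: int,
    inclusion_E: float,
    scheme: ScoringScheme | None = None,
    pseudocount_weight: float = 2.0,
    seed_id: str = "seed",
    calib_seed: int = 0,
) -> Profile:
    """Iterative profile search within a source proteome (jackhmmer-style).

    Round 1 builds a profile from the seed alone; each subsequent round scans
    the source proteome, includes hits with full E-value <= ``inclusion_E``
    into the alignment (aligned to the profile's consensus columns), and
    rebuilds the profile. Stops after ``rounds`` rounds or when the included
    set stops changing.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    scheme = scheme or blosum62_scheme()
    seed_msa = MSA([seed_id], [seed_query])
    profile = build_profile(seed_msa, pseudocount_weight, scheme)
    included: set[str] = set()
    for _ in range(1, rounds):
        calib = calibrate_profile_evalues(profile, source, seed=calib_seed)
        hits = search_profile(profile, source, calib, query_id=seed_id)
        new_included = {h.target_id for h in hits if h.full_evalue <= inclusion_E}
        if new_included == included:
            break
        included = new_included
        members = {g: source[g] for g in included}
        if seed_id not in members:
            members = dict(members)
            members[f"__seed__{seed_id}"] = seed_query
        msa = profile_msa(profile, members)
        try:
            # keep the seed's own columns as the coordinate system
            profile = build_profile(msa, pseudocount_weight, scheme,
                                    gap_open=profile.gap_open, gap_extend=profile.gap_extend)
        except ValueError:
            # pathological inclusion set aligned to almost nothing: stop iterating
            break
    return profile
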