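"""Per-protein feature annotation: TM segments, disorder, domains, motifs.

The transmembrane and disorder predictors are deliberately transparent windowed
heuristics (sliding-window hydropathy and a logistic combination of charge,
flexibility and hydropathy), not reimplementations of dedicated topology or
disorder tools: the downstream use is presence/absence summaries and planted-
segment benchmarks, where an auditable predictor is preferable. All parameters
are exposed.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .alignment import MSA
from .searchcore import EvalueCalibration, Profile, _segment_decomposition
from .core import encode_seq

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

#: Eisenberg consensus hydrophobicity (used for helical-moment calculations).
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08, "X": 0.0,
}

#: Backbone flexibility propensity, normalized to [0, 1] (high = flexible).
FLEXIBILITY = {
    "G": 0.90, "S": 0.85, "P": 0.80, "D": 0.75, "E": 0.75, "K": 0.70,
    "N": 0.70, "Q": 0.65, "T": 0.60, "R": 0.60, "A": 0.50, "H": 0.45,
    "C": 0.35, "M": 0.35, "V": 0.30, "L": 0.25, "I": 0.25, "F": 0.20,
    "Y": 0.20, "W": 0.15, "X": 0.50,
}

CHARGED = set("DEKR")
POSITIVE = set("KR")
#: Aliphatic residues accepted at the 'a' positions of the CaaX box.
CAAX_ALIPHATIC = "AVIL"
#: Residues commonly found at the CaaX 'X' position.
CAAX_X = "STQAM"


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of each full window; out[i] is the window starting at position i."""
    if len(values) < window:
        return np.zeros(0)
    c = np.concatenate([[0.0], np.cumsum(values)])
    return (c[window:] - c[:-window]) / window


def predict_tm(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    min_length: int = 15,
) -> list[tuple[int, int]]:
    """Transmembrane segments from sliding-window Kyte–Doolittle hydropathy.

    Maximal runs of windows whose mean hydropathy exceeds ``threshold`` are
    merged into segments (first window start to last window end); segments
    shorter than ``min_length`` are dropped. Sequences shorter than the window
    yield no segments.
    """
    vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq.upper()])
    means = _window_means(vals, window)
    if len(means) == 0:
        return []
    above = means > threshold
    spans = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            spans.append((i + 1, j + window))  # 1-based inclusive residue span
            i = j + 1
        else:
            i += 1
    # nearby window runs can cover overlapping residue ranges; merge them
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s + 1 >= min_length]


def predict_disorder(
    seq: str,
    window: int = 21,
    steepness: float = 6.0,
    center: float = 0.5,
    call_cutoff: float = 0.5,
    min_run: int = 10,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-residue disorder scores in [0, 1] plus binary disordered runs.

    The raw signal per window is ``charged fraction + mean flexibility - mean
    normalized hydropathy``; the score is a logistic transform of it. Runs of
    at least ``min_run`` residues with score above ``call_cutoff`` are called
    disordered.
    """
    s = seq.upper()
    n = len(s)
    charge = np.array([1.0 if c in CHARGED else 0.0 for c in s])
    flex = np.array([FLEXIBILITY.get(c, 0.5) for c in s])
    hyd = np.array([(KYTE_DOOLITTLE.get(c, 0.0) + 4.5) / 9.0 for c in s])
    half = window // 2
    scores = np.empty(n)
    c_charge = np.concatenate([[0.0], np.cumsum(charge)])
    c_flex = np.concatenate([[0.0], np.cumsum(flex)])
    c_hyd = np.concatenate([[0.0], np.cumsum(hyd)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = hi - lo
        raw = (
            (c_charge[hi] - c_charge[lo]) / w
            + (c_flex[hi] - c_flex[lo]) / w
            - (c_hyd[hi] - c_hyd[lo]) / w
        )
        scores[i] = 1.0 / (1.0 + math.exp(-steepness * (raw - center)))
    calls = []
    i = 0
    while i < n:
        if scores[i] > call_cutoff:
            j = i
            while j + 1 < n and scores[j + 1] > call_cutoff:
                j += 1
            if j - i + 1 >= min_run:
                calls.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return scores, calls


@dataclass
class DomainAnnotation:
    profile_id: str
    start: int
    end: int
    score: float
    evalue: float


def annotate_domains(
    seq: str,
    profile_library: dict[str, Profile],
    calibrations: dict[str, EvalueCalibration],
    max_evalue: float = 1e-3,
) -> list[DomainAnnotation]:
    """Scan profiles over a sequence and report the domain architecture.

    Hits at E <= ``max_evalue`` are collected from every profile (disjoint
    segments per profile); overlapping hits are resolved greedily by score.
    The result is ordered along the sequence.
    """
    if not profile_library:
        return []
    eb = encode_seq(seq)
    candidates: list[DomainAnnotation] = []
    for pid in sorted(profile_library):
        prof = profile_library[pid]
        calib = calibrations[pid]
        idx = np.arange(prof.n_columns, dtype=np.int64)
        segs = _segment_decomposition(
            idx, eb, prof.scores, prof.gap_open, prof.gap_extend, max_segments=4
        )
        for raw, _, _, b1, b2 in segs:
            ev = calib.evalue(raw, prof.n_columns, len(seq))
            if ev <= max_evalue:
                candidates.append(DomainAnnotation(pid, b1, b2, calib.bits(raw), ev))
    candidates.sort(key=lambda d: (-d.score, d.profile_id, d.start))
    kept: list[DomainAnnotation] = []
    for cand in candidates:
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda d: d.start)
    return kept


@dataclass
class MotifMatch:
    kind: str
    start: int
    end: int
    text: str


_CAAX_RE = re.compile(rf"C[{CAAX_ALIPHATIC}][{CAAX_ALIPHATIC}][{CAAX_X}]\Z")
_WXXXFY_RE = re.compile(r"(?=(W...[FY]))")


def detect_caax(seq: str) -> MotifMatch | None:
    """C-terminal prenylation box: Cys, two aliphatic residues, then S/T/Q/A/M.

    Only the final four residues are examined; an internal match does not count.
    """
    s = seq.upper()
    if len(s) < 4:
        return None
    m = _CAAX_RE.search(s[-4:])
    if m is None:
        return None
    return MotifMatch("caax", len(s) - 3, len(s), s[-4:])


def detect_wxxxfy(seq: str) -> list[MotifMatch]:
    """All (possibly overlapping) WxxxF/Y motif occurrences, 1-based starts."""
    s = seq.upper()
    return [
        MotifMatch("wxxxfy", m.start() + 1, m.start() + 5, m.group(1))
        for m in _WXXXFY_RE.finditer(s)
    ]


def detect_conserved_cysteine(
    msa: MSA,
    region_length: int = 60,
    conservation_min: float = 0.9,
) -> int | None:
    """Most-conserved cysteine column within the N-terminal alignment region.

    Looks at the first ``region_length`` consensus columns (<= 50% gaps) and
    returns the column index (0-based, in original MSA coordinates) with the
    highest Cys occupancy if that occupancy reaches ``conservation_min``; ties
    go to the leftmost column.
    """
    if msa.n_rows < 3:
        raise ValueError("conserved-cysteine scan needs >= 3 sequences")
    cols = msa.consensus_columns(0.5)[:region_length]
    best_col, best_occ = None, 0.0
    for c in cols:
        occ = sum(1 for ch in msa.column(c) if ch == "C") / msa.n_rows
        if occ > best_occ:
            best_col, best_occ = int(c), occ
    if best_col is None or best_occ < conservation_min:
        return None
    return best_col


def hydrophobic_moment(window_seq: str, angle_deg: float = 100.0) -> float:
    """Mean helical hydrophobic moment of a window (Eisenberg scale)."""
    re_part = im_part = 0.0
    for k, c in enumerate(window_seq.upper()):
        h = EISENBERG.get(c, 0.0)
        ang = math.radians(angle_deg * k)
        re_part += h * math.cos(ang)
        im_part += h * math.sin(ang)
    return math.hypot(re_part, im_part) / len(window_seq)


def amphipathic_scan(
    seq: str,
    window: int = 18,
    moment_min: float = 0.35,
) -> list[tuple[int, float, float]]:
    """Windows with high helical hydrophobic moment (candidate amphipathic helices).

    Returns ``(start, mean hydrophobicity, moment)`` for each window whose
    per-residue moment exceeds ``moment_min``. Empty when the sequence is
    shorter than the window.
    """
    s = seq.upper()
    if len(s) < window:
        return []
    out = []
    for i in range(len(s) - window + 1):
        w = s[i : i + window]
        mu = hydrophobic_moment(w)
        if mu > moment_min:
            mean_h = sum(EISENBERG.get(c, 0.0) for c in w) / window
            out.append((i + 1, mean_h, mu))
    return out


def charged_position_conservation(
    msa: MSA,
    reference_positions: list[int],
    subgroups: dict[str, list[str]],
    margin: float = 0.3,
) -> tuple[dict[str, dict[int, float | None]], list[int]]:
    """Positive-charge (K/R) conservation at reference columns per subgroup.

    ``reference_positions`` are 0-based MSA columns; ``subgroups`` maps a
    subgroup name to the row names it contains. Returns per-subgroup fractions
    (``None`` for empty subgroups — missing, not zero) and the list of
    positions whose conservation differs between subgroups by more than
    ``margin``.
    """
    name_to_row = {n: i for i, n in enumerate(msa.names)}
    for pos in reference_positions:
        if not (0 <= pos < msa.n_cols):
            raise ValueError(f"reference position {pos} outside alignment (0..{msa.n_cols - 1})")
    fractions: dict[str, dict[int, float | None]] = {}
    for sg, members in subgroups.items():
        rows = [name_to_row[m] for m in members if m in name_to_row]
        fractions[sg] = {}
        for pos in reference_positions:
            if not rows:
                fractions[sg][pos] = None
                continue
            hits = sum(1 for r in rows if msa.rows[r][pos] in POSITIVE)
            fractions[sg][pos] = hits / len(rows)
    flagged = []
    for pos in reference_positions:
        vals = [fractions[sg][pos] for sg in fractions if fractions[sg][pos] is not None]
        if len(vals) >= 2 and max(vals) - min(vals) > margin:
            flagged.append(pos)
    return fractions, flagged


@dataclass
class FeatureTrack:
    """All predicted features of one protein."""

    gene: str
    length: int
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    disorder_scores: np.ndarray | None = None
    disorder_calls: list[tuple[int, int]] = field(default_factory=list)
    domains: list[DomainAnnotation] = field(default_factory=list)
    motifs: list[MotifMatch] = field(default_factory=list)

    def __post_init__(self):
        for s, e in self.tm_segments:
            if not (1 <= s <= e <= self.length):
                raise ValueError("TM segment outside sequence bounds")
        for a, b in zip(self.tm_segments, self.tm_segments[1:]):
            if a[1] >= b[0]:
                raise ValueError("TM segments must be non-overlapping and sorted")

    @property
    def architecture(self) -> str:
        return "-".join(d.profile_id for d in self.domains)


def annotate_protein(
    gene: str,
    seq: str,
    profile_library: dict[str, Profile] | None = None,
    calibrations: dict[str, EvalueCalibration] | None = None,
) -> FeatureTrack:
    """Run all single-sequence feature predictors on one protein."""
    scores, calls = predict_disorder(seq)
    motifs = []
    caax = detect_caax(seq)
    if caax:
        motifs.append(caax)
    motifs.extend(detect_wxxxfy(seq))
    domains = (
        annotate_domains(seq, profile_library, calibrations)
        if profile_library
        else []
    )
    return FeatureTrack(
        gene=gene,
        length=len(seq),
        tm_segments=predict_tm(seq),
        disorder_scores=scores,
        disorder_calls=calls,
        domains=domains,
        motifs=motifs,
    )


def feature_table(tracks: list[FeatureTrack]):
    """Summarize tracks into a per-protein table (TSV-ready)."""
    import pandas as pd

    rows = []
    for t in tracks:
        rows.append(
            {
                "gene": t.gene,
                "length": t.length,
                "tm": "+" if t.tm_segments else "-",
                "n_tm_segments": len(t.tm_segments),
                "disorder": "+" if t.disorder_calls else "-",
                "disorder_fraction": (
                    round(
                        sum(e - s + 1 for s, e in t.disorder_calls) / t.length, 3
                    )
                    if t.length
                    else 0.0
                ),
                "architecture": t.architecture,
                "caax": "+" if any(m.kind == "caax" for m in t.motifs) else "-",
                "n_wxxxfy": sum(1 for m in t.motifs if m.kind == "wxxxfy"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "length", "tm", "n_tm_segments", "disorder",
            "disorder_fraction", "architecture", "caax", "n_wxxxfy",
        ],
    )


def intervals_bed(tracks: list[FeatureTrack]):
    """Feature intervals as a BED-like table (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for t in tracks:
        for s, e in t.tm_segments:
            rows.append({"gene": t.gene, "start": s, "end": e, "feature": "tm", "score": ""})
        for s, e in t.disorder_calls:
            rows.append({"gene": t.gene, "start": s, "end": e, "feature": "disorder", "score": ""})
        for d in t.domains:
            rows.append(
                {"gene": t.gene, "start": d.start, "end": d.end,
                 "feature": f"domain:{d.profile_id}", "score": f"{d.score:.1f}"}
            )
        for m in t.motifs:
            rows.append(
                {"gene": t.gene, "start": m.start, "end": m.end,
                 "feature": f"motif:{m.kind}", "score": ""}
            )
    return pd.DataFrame(rows, columns=["gene", "start", "end", "feature", "score"])
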