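"""Multiple sequence alignment container and center-star progressive aligner.

The aligner is a classic center-star construction: the center sequence is the
one maximizing the sum of global pairwise alignment scores to all others; every
other sequence is aligned to the center with affine-gap Needleman–Wunsch and the
pairwise gap patterns are merged under "once a gap, always a gap".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .core import AA_INDEX, encode_seq

GAP = "-"


@dataclass
class MSA:
    """An alignment as parallel rows of equal length."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("ragged alignment rows")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, c: int) -> str:
        return "".join(r[c] for r in self.rows)

    def gap_fractions(self) -> np.ndarray:
        if not self.rows:
            return np.zeros(0)
        arr = np.array([[ch == GAP for ch in r] for r in self.rows])
        return arr.mean(axis=0)

    def consensus_columns(self, max_gap_fraction: float = 0.5) -> np.ndarray:
        """Indices of columns with gap fraction <= ``max_gap_fraction``."""
        return np.nonzero(self.gap_fractions() <= max_gap_fraction)[0]

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def select_columns(self, cols) -> "MSA":
        cols = list(cols)
        return MSA(list(self.names), ["".join(r[c] for c in cols) for r in self.rows])

    def percent_identity(self, i: int, j: int) -> float:
        """Identity over mutually ungapped columns; 0 if none are shared."""
        a, b = self.rows[i], self.rows[j]
        shared = ident = 0
        for x, y in zip(a, b):
            if x != GAP and y != GAP:
                shared += 1
                if x == y:
                    ident += 1
        return ident / shared if shared else 0.0

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.rows):
                fh.write(f">{name}\n{row}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "MSA":
        names: list[str] = []
        rows: list[str] = []
        cur: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if names:
                        rows.append("".join(cur))
                    names.append(line[1:].split()[0])
                    cur = []
                elif line:
                    cur.append(line)
        if names:
            rows.append("".join(cur))
        return cls(names, rows)

    def write_stockholm(self, path: str | Path) -> None:
        """Minimal Stockholm-like output (one line per row, ``//`` terminator)."""
        width = max(len(n) for n in self.names) + 2 if self.names else 0
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for name, row in zip(self.names, self.rows):
                fh.write(f"{name:<{width}}{row}\n")
            fh.write("//\n")


def global_align_score(a: str, b: str, scheme) -> float:
    ea, eb = encode_seq(a), encode_seq(b)
    score, _, _, _ = _kernels.nw_fill(
        ea, eb, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)
    )
    return float(score)


def _global_path(a: str, b: str, scheme):
    ea, eb = encode_seq(a), encode_seq(b)
    score, ptrH, ptrE, ptrF = _kernels.nw_fill(
        ea, eb, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)
    )
    cols_a, cols_b = _kernels.traceback_global(len(ea), len(eb), ptrH, ptrE, ptrF)
    return float(score), cols_a, cols_b


def align_multiple(sequences: dict[str, str], scheme, center: str | None = None) -> MSA:
    """Center-star multiple alignment of ``{name: sequence}``.

    The center is the sequence with the highest summed global pairwise score
    (ties broken by lexicographic name) unless ``center`` names one explicitly.
    Every input residue appears exactly once in its row.
    """
    if len(sequences) < 2:
        raise ValueError("align_multiple needs at least 2 sequences")
    names = sorted(sequences)
    if center is None:
        totals = {n: 0.0 for n in names}
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                s = global_align_score(sequences[ni], sequences[nj], scheme)
                totals[ni] += s
                totals[nj] += s
        center = min(names, key=lambda n: (-totals[n], n))
    elif center not in sequences:
        raise ValueError(f"center {center!r} not among input sequences")

    c_seq = sequences[center]
    others = [n for n in names if n != center]
    lc = len(c_seq)
    # ins[k] = width of the insertion slot before center position k (k = lc → after end)
    ins = np.zeros(lc + 1, dtype=int)
    paths = {}
    for n in others:
        _, cols_c, cols_s = _global_path(c_seq, sequences[n], scheme)
        paths[n] = (cols_c, cols_s)
        k = 0
        run = 0
        for cc in cols_c:
            if cc == -1:
                run += 1
            else:
                ins[k] = max(ins[k], run)
                run = 0
                k = cc + 1
        ins[lc] = max(ins[lc], run)

    def build_row(seq: str, cols_c, cols_s) -> str:
        slots: list[list[str]] = [[] for _ in range(lc + 1)]
        matched = [GAP] * lc
        k = 0
        for cc, cs in zip(cols_c, cols_s):
            if cc == -1:
                slots[k].append(seq[cs])
            else:
                if cs != -1:
                    matched[cc] = seq[cs]
                k = cc + 1
        parts = []
        for k in range(lc):
            parts.append("".join(slots[k]).ljust(ins[k], GAP))
            parts.append(matched[k])
        parts.append("".join(slots[lc]).ljust(ins[lc], GAP))
        return "".join(parts)

    out_names = [center] + others
    center_cols = list(range(lc))
    out_rows = [build_row(c_seq, center_cols, center_cols)]
    for n in others:
        cols_c, cols_s = paths[n]
        out_rows.append(build_row(sequences[n], cols_c, cols_s))
    # restore deterministic (sorted) row order
    order = np.argsort(out_names, kind="stable")
    return MSA([out_names[i] for i in order], [out_rows[i] for i in order])


def sum_of_pairs_score(msa: MSA, scheme, gap_col: float | None = None) -> float:
    """Sum-of-pairs column score with linear gap cost (used as a test oracle aid).

    A residue against a gap costs ``gap_col`` (defaults to the scheme's open
    penalty); gap-gap pairs score 0.
    """
    if gap_col is None:
        gap_col = float(scheme.gap_open)
    total = 0.0
    for c in range(msa.n_cols):
        col = msa.column(c)
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                x, y = col[i], col[j]
                if x == GAP and y == GAP:
                    continue
                if x == GAP or y == GAP:
                    total += gap_col
                else:
                    total += scheme.matrix[AA_INDEX[x], AA_INDEX[y]]
    return total
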