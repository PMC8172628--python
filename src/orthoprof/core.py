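"""Shared containers and constants: amino-acid alphabet, taxonomy labels, proteomes.

The pipeline operates on per-species protein sets ("proteomes") annotated with a
eukaryotic supergroup (and, for Opisthokonta, a kingdom sublabel). Sequences are
plain strings over the 20 canonical residues; ``X`` is tolerated as an unknown
residue that scores zero in every alignment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: index 20 is the unknown residue X (scores 0 against everything)
ALPHABET = AMINO_ACIDS + "X"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Robinson & Robinson style background amino-acid frequencies, ordered as AMINO_ACIDS.
BACKGROUND_FREQS = np.array(
    [
        0.0787, 0.0151, 0.0535, 0.0668, 0.0397, 0.0695, 0.0229, 0.0590,
        0.0595, 0.0963, 0.0238, 0.0414, 0.0484, 0.0395, 0.0540, 0.0683,
        0.0541, 0.0673, 0.0114, 0.0308,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: Closed enumeration of eukaryotic supergroups used for distribution labels.
SUPERGROUPS = ("Opisthokonta", "Amoebozoa", "Archaeplastida", "SAR", "Excavata")
#: Kingdom sublabels (only Opisthokonta is subdivided).
KINGDOMS = {"Opisthokonta": ("Metazoa", "Fungi")}


def encode_seq(seq: str) -> np.ndarray:
    """Encode a protein string as uint8 indices into :data:`ALPHABET`.

    Raises ``ValueError`` on empty input or letters outside the alphabet.
    """
    if not seq:
        raise ValueError("empty sequence")
    try:
        return np.fromiter((AA_INDEX[c] for c in seq.upper()), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from exc


def decode_seq(idx: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in idx)


def stable_seed(master_seed: int, *tokens) -> int:
    """Derive a reproducible child seed from a master seed and string tokens.

    Uses SHA-256 so the stream assigned to e.g. a family does not depend on the
    order in which families are processed. Result is < 2**31.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"\x00" + str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class SpeciesInfo:
    """Taxonomic metadata for one species."""

    species: str
    supergroup: str
    kingdom: str | None = None

    def __post_init__(self):
        if self.supergroup not in SUPERGROUPS:
            raise ValueError(
                f"unknown supergroup {self.supergroup!r}; expected one of {SUPERGROUPS}"
            )
        allowed = KINGDOMS.get(self.supergroup)
        if self.kingdom is not None and (allowed is None or self.kingdom not in allowed):
            raise ValueError(
                f"kingdom {self.kingdom!r} not valid for supergroup {self.supergroup!r}"
            )

    @property
    def clade_labels(self) -> tuple[str, ...]:
        """Named clades containing this species, smallest first (species excluded)."""
        labels = []
        if self.kingdom:
            labels.append(self.kingdom)
        labels.append(self.supergroup)
        labels.append("Eukaryotes")
        return tuple(labels)


class SpeciesTable:
    """Ordered collection of :class:`SpeciesInfo`, the run's species universe.

    Column order of presence matrices follows this table's order (species grouped
    by supergroup, as in a Coulson plot).
    """

    def __init__(self, infos: list[SpeciesInfo]):
        seen = set()
        for info in infos:
            if info.species in seen:
                raise ValueError(f"duplicate species {info.species!r}")
            seen.add(info.species)
        self._infos = {i.species: i for i in infos}
        self._order = [i.species for i in infos]

    def __iter__(self):
        return (self._infos[s] for s in self._order)

    def __len__(self):
        return len(self._order)

    def __contains__(self, species: str) -> bool:
        return species in self._infos

    def __getitem__(self, species: str) -> SpeciesInfo:
        return self._infos[species]

    @property
    def species(self) -> list[str]:
        return list(self._order)

    def supergroup_of(self, species: str) -> str:
        return self._infos[species].supergroup

    def members_of(self, clade: str) -> list[str]:
        """Species belonging to a named clade (supergroup, kingdom or 'Eukaryotes')."""
        if clade == "Eukaryotes":
            return list(self._order)
        out = []
        for s in self._order:
            info = self._infos[s]
            if info.supergroup == clade or info.kingdom == clade or s == clade:
                out.append(s)
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tsupergroup\tkingdom\n")
            for info in self:
                fh.write(f"{info.species}\t{info.supergroup}\t{info.kingdom or ''}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesTable":
        infos = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["species", "supergroup"]:
                raise ValueError(f"unexpected species table header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                species, supergroup = parts[0], parts[1]
                kingdom = parts[2] if len(parts) > 2 and parts[2] else None
                infos.append(SpeciesInfo(species, supergroup, kingdom))
        return cls(infos)


@dataclass
class Proteome:
    """One species' protein set — the search universe on the target side."""

    species: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._encoded: dict[str, np.ndarray] | None = None

    def __len__(self):
        return len(self.sequences)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def encoded(self) -> dict[str, np.ndarray]:
        """Cached uint8-encoded sequences (search engine input)."""
        if self._encoded is None or len(self._encoded) != len(self.sequences):
            self._encoded = {g: encode_seq(s) for g, s in self.sequences.items()}
        return self._encoded

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=f"{self.species}|{gene}", description="")
            for gene, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, species: str | None = None) -> "Proteome":
        """Read a per-species FASTA with ``species|gene_id`` headers.

        If headers carry no species prefix, ``species`` must be given.
        """
        sequences: dict[str, str] = {}
        sp = species
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" in rec.id:
                rec_sp, gene = rec.id.split("|", 1)
                if sp is None:
                    sp = rec_sp
                elif rec_sp != sp and species is None:
                    raise ValueError(f"mixed species in {path}: {sp} vs {rec_sp}")
                if species is not None:
                    sp = species
            else:
                if sp is None:
                    raise ValueError("FASTA headers carry no species| prefix; pass species=")
                gene = rec.id
            if gene in sequences:
                raise ValueError(f"duplicate gene id {gene!r} in {path}")
            sequences[gene] = str(rec.seq)
        if sp is None:
            raise ValueError(f"empty FASTA {path} and no species given")
        return cls(species=sp, sequences=sequences)
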