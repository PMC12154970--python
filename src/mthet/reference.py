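"""Circular mtDNA reference genomes.

The human mtDNA reference (rCRS) is a 16,569 bp circular sequence written as
the light strand, with a single placeholder base ``N`` at position 3107 kept
for historical numbering.  Everything downstream — trinucleotide contexts,
possible-variant denominators, the all-possible-SNV table — is defined over
the non-placeholder ("informative") positions of such a genome.

Coordinates are 1-based and circular throughout: the 5' neighbour of
position 1 is the last position and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.array(["A", "C", "G", "T"])
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular reference sequence with optional placeholder positions.

    Parameters
    ----------
    sequence
        Upper-case bases over ``{A, C, G, T, N}``; index 0 is position 1.
    name
        Contig name used when writing FASTA/VCF (default ``chrM``).
    """

    sequence: str
    name: str = "chrM"
    placeholder_positions: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - {"A", "C", "G", "T", "N"}
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        ph = frozenset(i + 1 for i, b in enumerate(self.sequence) if b == "N")
        object.__setattr__(self, "placeholder_positions", ph)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_informative(self) -> int:
        """Number of non-placeholder positions."""
        return self.length - len(self.placeholder_positions)

    def base(self, position: int) -> str:
        """Base at a 1-based position, with circular wrap-around."""
        return self.sequence[(position - 1) % self.length]

    def informative_positions(self) -> np.ndarray:
        """Sorted array of 1-based non-placeholder positions."""
        pos = np.arange(1, self.length + 1)
        if not self.placeholder_positions:
            return pos
        mask = np.ones(self.length, dtype=bool)
        mask[[p - 1 for p in self.placeholder_positions]] = False
        return pos[mask]

    def context(self, position: int) -> str:
        """Light-strand trinucleotide context (5' base, ref base, 3' base).

        Neighbours wrap around the circular origin.  The result may contain
        ``N`` if a neighbour (or the position itself) is a placeholder.
        """
        return self.base(position - 1) + self.base(position) + self.base(position + 1)


def generate_reference(
    length: int,
    placeholder_positions: set[int] | frozenset[int] = frozenset(),
    seed: int | np.random.Generator = 0,
    name: str = "chrM",
) -> ReferenceGenome:
    """Draw a uniform-random circular genome with fixed placeholder sites.

    Deterministic for a given ``(length, placeholder_positions, seed)``.
    """
    if length < 100:
        raise ValueError(f"length must be >= 100, got {length}")
    placeholder_positions = set(placeholder_positions)
    out_of_range = {p for p in placeholder_positions if not 1 <= p <= length}
    if out_of_range:
        raise ValueError(f"placeholder positions out of range: {sorted(out_of_range)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bases = rng.choice(BASES, size=length)
    for p in sorted(placeholder_positions):
        bases[p - 1] = "N"
    return ReferenceGenome("".join(bases), name=name)


def write_fasta(reference: ReferenceGenome, path) -> None:
    rec = SeqRecord(Seq(reference.sequence), id=reference.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> ReferenceGenome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceGenome(str(rec.seq).upper(), name=rec.id)
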