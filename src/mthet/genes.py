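"""Synthetic gene models for a circular mtDNA-like genome.

Human mtDNA packs 13 protein-coding genes onto its two strands; all but one
(ND6) are read off the reference sequence as written, while ND6 is read as
the reverse complement.  We keep that convention: a *heavy*-strand gene's
coding sequence is the reference span read forward, a *light*-strand gene's
is the reverse complement of its span.

Spans are 1-based inclusive and may wrap the circular origin
(``start > end`` means the gene runs through position ``length`` to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import ReferenceGenome, revcomp


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; < start means the span wraps the origin
    strand: str  # "heavy" | "light"
    coding: bool = True
    frame: int = 0  # bases to skip at the 5' end of the coding sequence

    def positions(self, genome_length: int) -> np.ndarray:
        """All 1-based positions covered, in reference order along the span."""
        if self.start <= self.end:
            return np.arange(self.start, self.end + 1)
        return np.concatenate(
            [np.arange(self.start, genome_length + 1), np.arange(1, self.end + 1)]
        )

    def span_length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


class GeneModel:
    """An ordered collection of non-overlapping genes on one genome."""

    def __init__(self, genes: list[Gene], genome_length: int):
        self.genes = list(genes)
        self.genome_length = genome_length
        covered: set[int] = set()
        for g in self.genes:
            pos = set(g.positions(genome_length).tolist())
            if pos & covered:
                raise ValueError(f"gene {g.name} overlaps another gene")
            covered |= pos
            if g.coding and (g.span_length(genome_length) - g.frame) % 3 != 0:
                raise ValueError(f"coding gene {g.name} span not a codon multiple")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def gene_at(self, position: int) -> Gene | None:
        """Gene covering a position, or None (genes are non-overlapping)."""
        for g in self.genes:
            if g.start <= g.end:
                if g.start <= position <= g.end:
                    return g
            elif position >= g.start or position <= g.end:
                return g
        return None

    def coding_sequence(self, gene: Gene, reference: ReferenceGenome) -> str:
        """The gene's coding sequence on its own strand, frame applied."""
        span = "".join(reference.base(int(p)) for p in gene.positions(reference.length))
        if gene.strand == "light":
            span = revcomp(span)
        return span[gene.frame :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": g.name,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "coding": int(g.coding),
                    "frame": g.frame,
                }
                for g in self.genes
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome_length: int) -> "GeneModel":
        df = pd.read_csv(path, sep="\t")
        genes = [
            Gene(
                name=str(r["name"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r["strand"]),
                coding=bool(r["coding"]),
                frame=int(r["frame"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(genes, genome_length)


def generate_gene_model(
    reference: ReferenceGenome,
    n_genes: int,
    strand_mix: dict[str, int] | None = None,
    seed: int | np.random.Generator = 0,
    min_length: int = 120,
    max_length: int = 402,
) -> GeneModel:
    """Pack non-overlapping coding genes into placeholder-free territory.

    ``strand_mix`` maps strand -> gene count (default: one light-strand gene,
    the ND6 analogue, and the rest heavy).  Gene lengths are random codon
    multiples in ``[min_length, max_length]``.  Deterministic under ``seed``.
    Raises if the requested genes cannot be packed.
    """
    if strand_mix is None:
        strand_mix = {"heavy": n_genes - 1, "light": 1} if n_genes > 1 else {"heavy": 1}
    if sum(strand_mix.values()) != n_genes:
        raise ValueError("strand_mix counts must sum to n_genes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # Linear free segments between placeholders (no wrap-around genes emitted).
    blocked = sorted(reference.placeholder_positions)
    segments: list[tuple[int, int]] = []
    lo = 1
    for p in blocked + [reference.length + 1]:
        if p - 1 >= lo:
            segments.append((lo, p - 1))
        lo = p + 1

    strands = [s for s, k in strand_mix.items() for _ in range(k)]
    rng.shuffle(strands)
    genes: list[Gene] = []
    for i, strand in enumerate(strands):
        length = 3 * int(rng.integers(min_length // 3, max_length // 3 + 1))
        fitting = [(a, b) for a, b in segments if b - a + 1 >= length]
        if not fitting:
            raise ValueError(
                f"cannot pack gene {i + 1}/{n_genes} of length {length}: no free segment"
            )
        a, b = fitting[int(rng.integers(len(fitting)))]
        start = int(rng.integers(a, b - length + 2))
        end = start + length - 1
        genes.append(Gene(name=f"GENE{i + 1}", start=start, end=end, strand=strand))
        segments.remove((a, b))
        if start > a:
            segments.append((a, start - 1))
        if end < b:
            segments.append((end + 1, b))
        segments.sort()
    genes.sort(key=lambda g: g.start)
    return GeneModel(genes, reference.length)
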