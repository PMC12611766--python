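"""Reference bundle: toy chromosome, gene models and a CpG methylation track.

The downstream analysis only needs a minimal gene model: one transcript per
gene, exons on a single chromosome, a CDS whose length is a multiple of
three and a strand.  Coordinates are 1-based inclusive everywhere in memory;
BED files on disk use the conventional 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .context import (
    C,
    G,
    decode,
    COMP_CODE,
    penta_codes,
    trinuc_codes,
)


class ConfigurationError(ValueError):
    """Raised when requested geometry or parameters are impossible."""


@dataclass
class GeneModel:
    """Single-transcript gene model.

    Parameters
    ----------
    gene_id : str
    strand : str
        "+" or "-".
    exons : list of (start, end)
        1-based inclusive, ordered, non-overlapping.
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ConfigurationError(f"bad strand {self.strand!r}")
        last_end = 0
        for start, end in self.exons:
            if start <= last_end:
                raise ConfigurationError(
                    f"{self.gene_id}: exons overlap or are unordered"
                )
            if end < start:
                raise ConfigurationError(f"{self.gene_id}: exon end < start")
            last_end = end
        if self.cds_length % 3 != 0:
            raise ConfigurationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @cached_property
    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases, ascending (1-based)."""
        return np.concatenate(
            [np.arange(start, end + 1) for start, end in self.exons]
        )

    @cached_property
    def splice_positions(self) -> np.ndarray:
        """Essential splice-site positions: first/last 2 bases of each intron."""
        pos = []
        for (s1, e1), (s2, e2) in zip(self.exons[:-1], self.exons[1:]):
            pos.extend([e1 + 1, e1 + 2, s2 - 2, s2 - 1])
        return np.array(sorted(set(pos)), dtype=np.int64)

    def coding_sequence(self, seq_codes: np.ndarray) -> np.ndarray:
        """CDS base codes in coding (5'->3') order."""
        genomic = seq_codes[self.cds_positions - 1]
        if self.strand == "-":
            return COMP_CODE[genomic][::-1]
        return genomic


@dataclass
class ReferenceBundle:
    """One toy chromosome with gene models and per-CpG methylation."""

    chrom: str
    seq_codes: np.ndarray
    genes: list[GeneModel]
    cpg_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    methylation: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self):
        if len(self.cpg_positions) != len(self.methylation):
            raise ConfigurationError("every CpG site needs a methylation value")
        for gene in self.genes:
            if gene.end > self.length:
                raise ConfigurationError(
                    f"{gene.gene_id} extends past the chromosome end"
                )

    @property
    def length(self) -> int:
        return int(self.seq_codes.shape[0])

    @property
    def sequence(self) -> str:
        return decode(self.seq_codes)

    @cached_property
    def trinuc64(self) -> np.ndarray:
        """Per-position trinucleotide code (index 0 == position 1)."""
        return trinuc_codes(self.seq_codes)

    @cached_property
    def penta1024(self) -> np.ndarray:
        return penta_codes(self.seq_codes)

    @cached_property
    def methylation_by_position(self) -> np.ndarray:
        """Full-length methylation array (index 0 == position 1).

        The methylation level of a CpG is attached to both the C and the G
        of the dinucleotide (CpG methylation is symmetric); non-CpG
        positions carry 0.
        """
        meth = np.zeros(self.length, dtype=float)
        if len(self.cpg_positions):
            idx = self.cpg_positions - 1
            meth[idx] = self.methylation
            meth[idx + 1] = self.methylation
        return meth

    def find_cpg_positions(self) -> np.ndarray:
        """Positions (1-based) of the C of every CpG dinucleotide."""
        s = self.seq_codes
        hits = np.flatnonzero((s[:-1] == C) & (s[1:] == G))
        return hits + 1

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)
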