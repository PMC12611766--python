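"""Per-base duplex coverage tracks.

Duplex coverage (dx) counts independent double-strand consensus molecules at
a site.  One dx corresponds to roughly one haploid genome sampled, so for
sperm the coverage at a site is the number of cells interrogated there, and
a variant allele fraction of 1/coverage is one mutant cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CoverageTrack:
    """Per-base integer duplex depth for a set of samples on one chromosome."""

    chrom: str
    length: int
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for sid, arr in self.depths.items():
            if arr.shape[0] != self.length:
                raise ValueError(f"coverage for {sid} has wrong length")
            if (arr < 0).any():
                raise ValueError(f"negative depth in {sid}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depths)

    def depth_at(self, sample_id: str, pos: int | np.ndarray) -> np.ndarray:
        """Depth at 1-based position(s)."""
        return self.depths[sample_id][np.asarray(pos) - 1]

    def total(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Cohort-summed depth per base (float64)."""
        ids = sample_ids if sample_ids is not None else self.sample_ids
        out = np.zeros(self.length, dtype=np.float64)
        for sid in ids:
            out += self.depths[sid]
        return out

    def weighted_total(self, weights: dict[str, float]) -> np.ndarray:
        """Per-base sum of depth x weight over samples (e.g. weight = age)."""
        out = np.zeros(self.length, dtype=np.float64)
        for sid, w in weights.items():
            out += w * self.depths[sid]
        return out

    def mean_depth(self, sample_ids: list[str] | None = None) -> float:
        ids = sample_ids if sample_ids is not None else self.sample_ids
        return float(np.mean([self.depths[sid].mean() for sid in ids]))

    def duplex_bp(self, sample_id: str) -> int:
        """Total duplex-covered base pairs (sum of depth) for one sample."""
        return int(self.depths[sample_id].sum())

    def masked(self, positions: np.ndarray) -> "CoverageTrack":
        """Return a copy with the given 1-based positions zeroed in all samples.

        Masked sites must leave both the mutation calls (numerator) and the
        coverage (denominator) of every downstream rate, hence masking acts
        on the track itself.
        """
        positions = np.asarray(positions, dtype=np.int64)
        new = {}
        for sid, arr in self.depths.items():
            a = arr.copy()
            if positions.size:
                a[positions - 1] = 0
            new[sid] = a
        return CoverageTrack(self.chrom, self.length, new)
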