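"""Sequence-context machinery shared across the package.

Mutation rates in the germline are strongly context dependent (most famously
the elevated C>T transition rate at methylated CpG dinucleotides), so every
module that counts or models mutations indexes them by their local sequence
context.  Two indexings are used:

* the **192-class** strand-specific model: one class per (trinucleotide,
  alternate allele) pair, 64 x 3 = 192.  This is the parameterization of the
  neutral rate model.
* the **96-channel** pyrimidine-collapsed spectrum: trinucleotides are
  reverse-complemented so the mutated base is a pyrimidine (C or T),
  16 x 6 = 96.  This is the conventional mutational-signature space.

All sequences are stored as ``uint8`` codes (A=0, C=1, G=2, T=3); genomic
coordinates exposed through public APIs are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

A, C, G, T = 0, 1, 2, 3

#: number of strand-specific (trinucleotide, alt) rate classes
N_CLASSES_192 = 192
#: number of pyrimidine-collapsed spectrum channels
N_CHANNELS_96 = 96

SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in BASE_CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in np.atleast_1d(codes))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP_CODE[codes][::-1]


def trinuc_codes(seq_codes: np.ndarray) -> np.ndarray:
    """Per-position trinucleotide code (16*left + 4*centre + right).

    The first and last positions have no full trinucleotide; they are set
    to -1.
    """
    n = seq_codes.shape[0]
    out = np.full(n, -1, dtype=np.int32)
    if n >= 3:
        out[1:-1] = (
            16 * seq_codes[:-2].astype(np.int32)
            + 4 * seq_codes[1:-1]
            + seq_codes[2:]
        )
    return out


def penta_codes(seq_codes: np.ndarray) -> np.ndarray:
    """Per-position pentanucleotide code in base 4 (-1 within 2 bp of an edge)."""
    n = seq_codes.shape[0]
    out = np.full(n, -1, dtype=np.int32)
    if n >= 5:
        s = seq_codes.astype(np.int32)
        out[2:-2] = 256 * s[:-4] + 64 * s[1:-3] + 16 * s[2:-2] + 4 * s[3:-1] + s[4:]
    return out


def alt_rank(ref_code: np.ndarray, alt_code: np.ndarray) -> np.ndarray:
    """Rank (0..2) of the alternate base among the three bases != ref.

    Ranks follow alphabetical base order with the reference base skipped,
    e.g. for ref=C the alts (A, G, T) have ranks (0, 1, 2).
    """
    ref_code = np.asarray(ref_code, dtype=np.int32)
    alt_code = np.asarray(alt_code, dtype=np.int32)
    if np.any(ref_code == alt_code):
        raise ValueError("alt equals ref")
    return np.where(alt_code > ref_code, alt_code - 1, alt_code)


def class192(trinuc: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """192-class index for (trinucleotide code, alternate base code) pairs."""
    trinuc = np.asarray(trinuc, dtype=np.int32)
    alt = np.asarray(alt, dtype=np.int32)
    ref = (trinuc // 4) % 4
    if np.any(alt == ref):
        raise ValueError("alt equals ref base of trinucleotide")
    # alt below ref keeps its own index as rank; above ref shifts down by one
    rank = np.where(alt > ref, alt - 1, alt)
    return trinuc * 3 + rank


def class192_decompose(cls: np.ndarray):
    """Return (trinuc code, ref code, alt code) for 192-class indices."""
    cls = np.asarray(cls, dtype=np.int32)
    trinuc = cls // 3
    rank = cls % 3
    ref = (trinuc // 4) % 4
    alt = np.where(rank >= ref, rank + 1, rank)
    return trinuc, ref, alt


def class192_labels() -> list[str]:
    """Human-readable labels like ``ACG>T`` for all 192 classes."""
    labels = []
    for cls in range(N_CLASSES_192):
        tri, _, alt = class192_decompose(np.array([cls]))
        t = int(tri[0])
        s = decode(np.array([(t // 16) % 4, (t // 4) % 4, t % 4], dtype=np.uint8))
        labels.append(f"{s}>{BASES[int(alt[0])]}")
    return labels


def cpg_transition_mask192() -> np.ndarray:
    """Boolean mask over the 192 classes for CpG transitions.

    Covers NCG with C>T (the methylated cytosine itself) and CGN with G>A
    (the same event read from the opposite strand); 8 classes in total.
    These are the classes whose rate is modulated by the methylation level.
    """
    mask = np.zeros(N_CLASSES_192, dtype=bool)
    for cls in range(N_CLASSES_192):
        tri, ref, alt = class192_decompose(np.array([cls]))
        t = int(tri[0])
        left, centre, right = (t // 16) % 4, (t // 4) % 4, t % 4
        if centre == C and right == G and int(alt[0]) == T:
            mask[cls] = True
        if centre == G and left == C and int(alt[0]) == A:
            mask[cls] = True
    return mask


def channel96(trinuc: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Pyrimidine-collapsed 96-channel index.

    Channel = 16 * subst_type + 4 * five_prime + three_prime, with
    subst_type ordered C>A, C>G, C>T, T>A, T>C, T>G and flanks on the
    pyrimidine strand.
    """
    trinuc = np.asarray(trinuc, dtype=np.int32)
    alt = np.asarray(alt, dtype=np.int32)
    left = (trinuc // 16) % 4
    centre = (trinuc // 4) % 4
    right = trinuc % 4
    purine = (centre == A) | (centre == G)
    comp = COMP_CODE.astype(np.int32)
    l2 = np.where(purine, comp[right], left)
    c2 = np.where(purine, comp[centre], centre)
    r2 = np.where(purine, comp[left], right)
    a2 = np.where(purine, comp[alt], alt)
    # subst type index among the six pyrimidine substitutions
    sub = np.where(c2 == C, np.where(a2 == A, 0, np.where(a2 == G, 1, 2)),
                   np.where(a2 == A, 3, np.where(a2 == C, 4, 5)))
    return sub * 16 + l2 * 4 + r2


def channel96_labels() -> list[str]:
    labels = []
    for sub in range(6):
        st = SUBSTITUTION_TYPES[sub]
        for l in range(4):
            for r in range(4):
                labels.append(f"{BASES[l]}[{st}]{BASES[r]}")
    return labels


def trinuc32_of_channel() -> np.ndarray:
    """Pyrimidine-strand trinucleotide index (0..31) of each 96 channel."""
    out = np.zeros(N_CHANNELS_96, dtype=np.int32)
    for ch in range(N_CHANNELS_96):
        sub, rest = divmod(ch, 16)
        l, r = divmod(rest, 4)
        centre = 0 if sub < 3 else 1  # 0 = C, 1 = T
        out[ch] = l * 8 + centre * 4 + r
    return out


def trinuc32_codes(trinuc64: np.ndarray) -> np.ndarray:
    """Collapse 64 trinucleotide codes to the 32 pyrimidine-centred classes.

    Index = 8 * five_prime + 4 * (centre == T) + three_prime on the
    pyrimidine strand.  Positions with code -1 propagate -1.
    """
    t = np.asarray(trinuc64, dtype=np.int32)
    left = (t // 16) % 4
    centre = (t // 4) % 4
    right = t % 4
    purine = (centre == A) | (centre == G)
    comp = COMP_CODE.astype(np.int32)
    l2 = np.where(purine, comp[right], left)
    c2 = np.where(purine, comp[centre], centre)
    r2 = np.where(purine, comp[left], right)
    out = l2 * 8 + (c2 == T).astype(np.int32) * 4 + r2
    return np.where(t < 0, -1, out)


# --- codon machinery ------------------------------------------------------

def _build_codon_table() -> np.ndarray:
    """Amino-acid (byte) per codon index, via the standard genetic code."""
    aas = np.zeros(64, dtype="U1")
    for i in range(64):
        codon = decode(np.array([(i // 16) % 4, (i // 4) % 4, i % 4], dtype=np.uint8))
        aas[i] = str(Seq(codon).translate())
    return aas


CODON_AA = _build_codon_table()
SENSE_CODONS = np.array([i for i in range(64) if CODON_AA[i] != "*"], dtype=np.int32)


def codon_index(codes: np.ndarray) -> int:
    return int(16 * codes[0] + 4 * codes[1] + codes[2])


@dataclass(frozen=True)
class ContextDescriptor:
    """Strand-collapsed local context of a single-base substitution."""

    trinucleotide: str
    pentanucleotide: str
    alt: str
    is_cpg: bool
    methylation_level: float | None = None

    def __post_init__(self):
        if self.trinucleotide[1] not in "CT":
            raise ValueError("context must be reported on the pyrimidine strand")
        if self.pentanucleotide[2] != self.trinucleotide[1]:
            raise ValueError("pentanucleotide centre must match trinucleotide centre")
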