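"""Uniquely-mappable position masks for mappability-sensitive profiles.

A forward mask entry m_f(i) = 1 means a length-R read whose 5' end is i
(occupying [i, i+R-1]) maps uniquely; a reverse mask entry m_r(j) = 1
means a reverse read whose 5' end is j (occupying [j-R+1, j]) maps
uniquely.  Real tracks (e.g. GEM-derived BigWigs) index mappability by
the leftmost base of the placement, so the reverse mask is the forward
style mask shifted right by R-1.

Binarisation rule for real-valued tracks: scores below 1 (including
missing data) become 0; only exactly-unique positions count.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeSpec

__all__ = [
    "MappabilityMask",
    "load_mappability_bigwig",
    "compute_exact_mappability",
    "derive_reverse_mask",
    "mask_from_intervals",
    "write_mask_bed",
    "load_mask_bed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def derive_reverse_mask(base_mask: np.ndarray, read_length: int) -> np.ndarray:
    """Reverse-strand mask from a leftmost-base (forward-style) mask.

    A reverse read with 5' end j occupies [j-R+1, j], so its placement
    is the one the base mask scores at j-R+1.  Positions with
    j-R+1 < 0 are unmappable.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    base_mask = np.asarray(base_mask, dtype=bool)
    out = np.zeros_like(base_mask)
    if read_length - 1 < base_mask.size:
        out[read_length - 1 :] = base_mask[: base_mask.size - read_length + 1]
    return out


class MappabilityMask:
    """Per-chromosome forward/reverse uniquely-mappable indicators."""

    def __init__(
        self,
        genome: GenomeSpec,
        read_length: int,
        forward: dict[str, np.ndarray],
        reverse: dict[str, np.ndarray] | None = None,
    ):
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        self.genome = genome
        self.read_length = int(read_length)
        self.forward: dict[str, np.ndarray] = {}
        self.reverse: dict[str, np.ndarray] = {}
        for chrom, fwd in forward.items():
            length = genome.length(chrom)
            fwd = np.asarray(fwd, dtype=bool).copy()
            if fwd.size != length:
                raise ValueError(f"mask length mismatch on {chrom}")
            # a forward placement must fit: i + R - 1 < L
            if read_length > 1:
                fwd[length - read_length + 1 :] = False
            self.forward[chrom] = fwd
            if reverse is None:
                self.reverse[chrom] = derive_reverse_mask(fwd, read_length)
        if reverse is not None:
            for chrom, rev in reverse.items():
                length = genome.length(chrom)
                rev = np.asarray(rev, dtype=bool).copy()
                if rev.size != length:
                    raise ValueError(f"mask length mismatch on {chrom}")
                if read_length > 1:
                    rev[: read_length - 1] = False
                self.reverse[chrom] = rev
            if set(self.reverse) != set(self.forward):
                raise ValueError("forward/reverse masks cover different chromosomes")

    @classmethod
    def all_mappable(cls, genome: GenomeSpec, read_length: int) -> "MappabilityMask":
        return cls(
            genome,
            read_length,
            {c: np.ones(l, dtype=bool) for c, l in genome.items()},
        )

    def mappable_fraction(self, chrom: str) -> float:
        return float(self.forward[chrom].mean())


def load_mappability_bigwig(
    path: str, genome: GenomeSpec, read_length: int
) -> MappabilityMask:
    """Binarise a BigWig mappability track into a mask.

    Track values equal to 1 are uniquely mappable; anything below 1,
    including regions with no data, becomes 0.  The track is assumed to
    score placements by their leftmost base.
    """
    import pyBigWig

    bw = pyBigWig.open(path)
    try:
        track_chroms = bw.chroms()
        missing = [c for c in genome.names if c not in track_chroms]
        if missing:
            raise ValueError(
                "mappability track lacks chromosomes: " + ", ".join(missing)
            )
        forward = {}
        for chrom, length in genome.items():
            vals = np.asarray(bw.values(chrom, 0, length), dtype=float)
            forward[chrom] = np.nan_to_num(vals, nan=0.0) >= 1.0
    finally:
        bw.close()
    return MappabilityMask(genome, read_length, forward)


def compute_exact_mappability(
    sequences: dict[str, str], read_length: int
) -> MappabilityMask:
    """Exact-match unique mappability of a small (synthetic) genome.

    A placement is uniquely mappable iff its R-mer contains no N and
    occurs exactly once among all R-mers of the genome and of its
    reverse complement.  This is a stricter criterion than
    mismatch-tolerant tools apply to real genomes; it exists so that
    masks for simulated genomes are computable from first principles.
    Enumeration is exhaustive and intended for genomes of ~1e5 bp or
    less.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    seqs = {c: s.upper() for c, s in sequences.items()}
    genome = GenomeSpec(tuple(seqs), tuple(len(s) for s in seqs.values()))
    if read_length > min(genome.lengths):
        raise ValueError("read_length exceeds the shortest chromosome")
    counts: dict[str, int] = {}
    for seq in seqs.values():
        for strand_seq in (seq, _revcomp(seq)):
            for i in range(len(strand_seq) - read_length + 1):
                kmer = strand_seq[i : i + read_length]
                counts[kmer] = counts.get(kmer, 0) + 1
    forward = {}
    for chrom, seq in seqs.items():
        mask = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - read_length + 1):
            kmer = seq[i : i + read_length]
            mask[i] = "N" not in kmer and counts[kmer] == 1
        forward[chrom] = mask
    return MappabilityMask(genome, read_length, forward)


def mask_from_intervals(
    genome: GenomeSpec,
    read_length: int,
    mappable: dict[str, list[tuple[int, int]]],
) -> MappabilityMask:
    """Mask from half-open mappable base intervals (leftmost-base style)."""
    forward = {}
    for chrom, length in genome.items():
        base = np.zeros(length, dtype=bool)
        for start, end in mappable.get(chrom, ()):
            base[max(0, start) : min(length, end)] = True
        forward[chrom] = base
    return MappabilityMask(genome, read_length, forward)


def write_mask_bed(mask: MappabilityMask, path: str) -> None:
    """Write the forward (leftmost-base) mask as BED3 mappable intervals."""
    with open(path, "w") as fh:
        for chrom in mask.genome.names:
            base = mask.forward[chrom]
            # recover runs of ones
            diff = np.diff(base.astype(np.int8), prepend=0, append=0)
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def load_mask_bed(path: str, genome: GenomeSpec, read_length: int) -> MappabilityMask:
    """Read BED3 mappable intervals into a mask (inverse of write_mask_bed)."""
    intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} not in genome")
            intervals[chrom].append((int(start), int(end)))
    return mask_from_intervals(genome, read_length, intervals)
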