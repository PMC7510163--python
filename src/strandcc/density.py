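"""Binarised strand-specific read-start densities.

A ChIP-seq alignment file is reduced to two indicator vectors per
chromosome: f(i) = 1 iff at least one forward read starts (5' end) at
position i, and g(j) = 1 iff at least one reverse read has its 5' end
(rightmost aligned base) at position j.  Duplicate read positions
collapse to a single set bit, which subsumes PCR-duplicate removal.
"""

from __future__ import annotations

import os
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from ._bitops import positions_to_bool
from .genome import GenomeSpec

__all__ = ["BinaryDensity", "read_alignments", "write_alignments"]


@dataclass
class BinaryDensity:
    """Per-chromosome, per-strand sets of binarised read 5' positions.

    ``forward[chrom]`` / ``reverse[chrom]`` are sorted, unique, 0-based
    position arrays.  ``n_records`` is the number of usable input reads
    before binarisation (the model's M); the set-bit totals give M_u.
    """

    genome: GenomeSpec
    read_length: int
    forward: dict[str, np.ndarray] = field(default_factory=dict)
    reverse: dict[str, np.ndarray] = field(default_factory=dict)
    n_records: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for strand in (self.forward, self.reverse):
            for chrom, pos in strand.items():
                length = self.genome.length(chrom)
                pos = np.unique(np.asarray(pos, dtype=np.int64))
                if pos.size and (pos[0] < 0 or pos[-1] >= length):
                    raise ValueError(
                        f"positions outside [0, {length}) on {chrom}"
                    )
                strand[chrom] = pos
        if self.n_records == 0:
            self.n_records = self.n_positions

    @property
    def counts(self) -> dict[str, tuple[int, int]]:
        """(forward, reverse) set-bit totals per chromosome."""
        chroms = set(self.forward) | set(self.reverse)
        return {
            c: (
                int(self.forward.get(c, np.empty(0)).size),
                int(self.reverse.get(c, np.empty(0)).size),
            )
            for c in sorted(chroms)
        }

    @property
    def n_positions(self) -> int:
        """M_u: total distinct read positions over both strands."""
        return int(
            sum(p.size for p in self.forward.values())
            + sum(p.size for p in self.reverse.values())
        )

    def chromosomes(self) -> list[str]:
        """Chromosomes carrying at least one read, in genome order."""
        present = set(self.forward) | set(self.reverse)
        return [c for c in self.genome.names if c in present]

    def bool_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Dense (f, g) indicator vectors for one chromosome."""
        length = self.genome.length(chrom)
        f = positions_to_bool(self.forward.get(chrom, np.empty(0, np.int64)), length)
        g = positions_to_bool(self.reverse.get(chrom, np.empty(0, np.int64)), length)
        return f, g


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower()
    if ext in (".bed", ".bed6"):
        return "bed"
    if ext in (".sam", ".bam", ".cram"):
        return "sam"
    raise ValueError(f"cannot infer alignment format from {path!r}; pass fmt=")


def _iter_sam(path: str, genome: GenomeSpec, mapq_min: int):
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for idx, rec in enumerate(fh):
            if rec.is_unmapped:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            chrom = rec.reference_name
            if chrom not in genome:
                continue
            length = rec.query_length or rec.infer_read_length()
            if not length:
                raise ValueError(f"record {idx}: cannot determine read length")
            yield idx, chrom, rec.reference_start, length, rec.is_reverse


def _iter_bed(path: str, genome: GenomeSpec, mapq_min: int):
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"unparseable BED file {path!r}: {exc}") from exc
    for idx, row in enumerate(table.itertuples(index=False)):
        if row.strand not in ("+", "-"):
            raise ValueError(f"record {idx}: invalid strand {row.strand!r}")
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise ValueError(f"record {idx}: empty interval")
        score = row.score
        try:
            score = float(score)
        except (TypeError, ValueError):
            score = mapq_min  # non-numeric score column: keep the read
        if score < mapq_min:
            continue
        if row.chrom not in genome:
            continue
        yield idx, row.chrom, start, end - start, row.strand == "-"


def read_alignments(
    path: str,
    genome: GenomeSpec,
    mapq_min: int = 0,
    read_length_override: int | None = None,
    fmt: str | None = None,
) -> BinaryDensity:
    """Binarise an alignment file into strand-specific 5'-position sets.

    Forward reads contribute their leftmost (0-based) coordinate to f;
    a reverse read with leftmost coordinate b and length R contributes
    b + R - 1 to g.  Unmapped reads, reads below ``mapq_min`` and reads
    on chromosomes absent from ``genome`` are skipped.  The density's
    read length is the mode of observed lengths unless overridden.
    """
    source = _iter_sam if _detect_format(path, fmt) == "sam" else _iter_bed
    fwd: dict[str, list] = {}
    rev: dict[str, list] = {}
    length_counts: Counter = Counter()
    n_records = 0
    for idx, chrom, start, length, is_reverse in source(path, genome, mapq_min):
        if read_length_override is not None:
            length = read_length_override
        chrom_len = genome.length(chrom)
        if is_reverse:
            pos = start + length - 1
        else:
            pos = start
        if pos < 0 or pos >= chrom_len:
            continue  # overhanging record: 5' end off the chromosome
        length_counts[length] += 1
        n_records += 1
        (rev if is_reverse else fwd).setdefault(chrom, []).append(pos)
    if n_records == 0:
        raise ValueError(f"zero usable reads in {path!r}")
    if read_length_override is not None:
        read_length = read_length_override
    else:
        if len(length_counts) > 1:
            warnings.warn(
                f"{len(length_counts)} distinct read lengths observed; "
                "using the modal length (the model assumes a single R)",
                stacklevel=2,
            )
        read_length = length_counts.most_common(1)[0][0]
    return BinaryDensity(
        genome=genome,
        read_length=int(read_length),
        forward={c: np.array(v, dtype=np.int64) for c, v in fwd.items()},
        reverse={c: np.array(v, dtype=np.int64) for c, v in rev.items()},
        n_records=n_records,
    )


def write_alignments(
    density: BinaryDensity,
    path: str,
    fmt: str = "sam",
) -> None:
    """Write one full-length read per set bit of ``density``.

    SAM records are minimal single-end alignments with a match-only
    CIGAR of length R; BED output is 6-column, 0-based half-open.
    Positions whose read would overhang the chromosome end are rejected
    (the round trip through :func:`read_alignments` must be exact).
    """
    genome = density.genome
    r_len = density.read_length
    rows: list[tuple[str, int, bool]] = []  # (chrom, leftmost, is_reverse)
    for chrom in density.chromosomes():
        length = genome.length(chrom)
        for pos in density.forward.get(chrom, ()):  # leftmost = 5' end
            if pos + r_len > length:
                raise ValueError(
                    f"forward read at {chrom}:{pos} overhangs the chromosome end"
                )
            rows.append((chrom, int(pos), False))
        for pos in density.reverse.get(chrom, ()):  # 5' end is rightmost base
            if pos - r_len + 1 < 0:
                raise ValueError(
                    f"reverse read ending at {chrom}:{pos} starts before position 0"
                )
            rows.append((chrom, int(pos) - r_len + 1, True))
    fmt = fmt.lower()
    if fmt == "bed":
        with open(path, "w") as fh:
            for i, (chrom, start, is_rev) in enumerate(rows):
                strand = "-" if is_rev else "+"
                fh.write(f"{chrom}\t{start}\t{start + r_len}\tread{i}\t255\t{strand}\n")
    elif fmt == "sam":
        header = pysam.AlignmentHeader.from_references(
            list(genome.names), list(genome.lengths)
        )
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for i, (chrom, start, is_rev) in enumerate(rows):
                rec = pysam.AlignedSegment(header)
                rec.query_name = f"read{i}"
                rec.reference_name = chrom
                rec.reference_start = start
                rec.flag = 16 if is_rev else 0
                rec.mapping_quality = 255
                rec.cigarstring = f"{r_len}M"
                rec.query_sequence = "N" * r_len
                rec.query_qualities = pysam.qualitystring_to_array("I" * r_len)
                fh.write(rec)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
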