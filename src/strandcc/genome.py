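"""Genome coordinate bookkeeping.

All internal coordinates are 0-based, half-open.  Input/output layers
(SAM, BED, BigWig) perform whatever conversion their format requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths.

    Parameters
    ----------
    names
        Chromosome identifiers, unique, in a fixed order.
    lengths
        Chromosome lengths in bp, one per name, each >= 1.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        lengths = tuple(int(x) for x in self.lengths)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lengths", lengths)
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if not names:
            raise ValueError("genome must contain at least one chromosome")
        if any(l < 1 for l in lengths):
            raise ValueError("chromosome lengths must be >= 1")
        object.__setattr__(self, "_index", dict(zip(names, lengths)))

    @property
    def total_length(self) -> int:
        """Total genome length G in bp."""
        return sum(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def length(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome") from None

    def items(self):
        return zip(self.names, self.lengths)

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeSpec":
        return cls(tuple(lengths), tuple(lengths.values()))

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSpec":
        """Build a spec from FASTA sequence lengths (small genomes)."""
        from .simulate import read_fasta

        seqs = read_fasta(path)
        return cls.from_dict({name: len(s) for name, s in seqs.items()})

    @classmethod
    def from_chrom_sizes(cls, path: str) -> "GenomeSpec":
        """Read a two-column ``chrom<TAB>length`` file (UCSC chrom.sizes)."""
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split()[:2]
                names.append(name)
                lengths.append(int(length))
        return cls(tuple(names), tuple(lengths))
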