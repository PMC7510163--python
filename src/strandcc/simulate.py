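"""Synthetic data generated exactly under the read-density model.

The generator realises the model the theory module analyses: n
disjoint pairs of enriched regions of width w separated by d, signal
read 5' ends uniform within the regions, noise 5' ends uniform over
the chromosome.  Within each component positions are drawn without
replacement — the model's binarised densities count distinct
positions, and its unsaturated regime is precisely the regime in which
the requested number of distinct positions exists.  Collisions between
the signal and noise components still collapse on binarisation, and
the post-collapse count is reported as M_u.

Defaults follow the reference simulation design: w = 100 bp,
d = 200 bp, R = 50 bp.
"""

from __future__ import annotations

import numpy as np

from .density import BinaryDensity
from .genome import GenomeSpec
from .mappability import MappabilityMask, derive_reverse_mask
from .theory import ModelParams

__all__ = [
    "SiteLayout",
    "simulate_sites",
    "simulate_reads",
    "simulate_experiment",
    "simulate_genome",
    "simulate_mappability",
    "apply_mappability",
    "read_fasta",
    "write_fasta",
]

DEFAULT_W = 100
DEFAULT_D = 200
DEFAULT_R = 50

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_without_replacement(
    rng: np.random.Generator, n: int, k: int
) -> np.ndarray:
    """k distinct uniform draws from [0, n), seeded and O(k) in memory.

    Uses rejection with top-up for sparse draws (k << n) to avoid the
    O(n) permutation numpy would build, falling back to numpy's own
    sampler when the draw is dense.
    """
    if k < 0 or k > n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k / n > 0.05:
        return np.sort(rng.choice(n, size=k, replace=False).astype(np.int64))
    chosen = np.unique(rng.integers(0, n, size=int(k * 1.05) + 16))
    while chosen.size < k:
        extra = rng.integers(0, n, size=k - chosen.size + 16)
        chosen = np.unique(np.concatenate([chosen, extra]))
    if chosen.size > k:
        drop = rng.choice(chosen.size, size=chosen.size - k, replace=False)
        chosen = np.delete(chosen, drop)
    return chosen


class SiteLayout:
    """Placement of n binding events on a genome.

    ``anchors[chrom]`` holds the start a of each forward enriched
    region E_f = [a, a + w); the paired reverse region (of reverse-read
    5' ends) is E_g = [a + w + d, a + 2w + d), so matching 5' ends sit
    d + w apart.
    """

    def __init__(self, genome: GenomeSpec, w: int, d: int, anchors: dict[str, np.ndarray]):
        self.genome = genome
        self.w = int(w)
        self.d = int(d)
        self.anchors = {c: np.sort(np.asarray(a, dtype=np.int64)) for c, a in anchors.items()}
        footprint = 2 * self.w + self.d
        for chrom, arr in self.anchors.items():
            length = genome.length(chrom)
            if arr.size and (arr[0] < 0 or arr[-1] + footprint > length):
                raise ValueError(f"enriched regions out of bounds on {chrom}")
            if arr.size > 1 and np.any(np.diff(arr) < footprint):
                raise ValueError(f"enriched regions overlap on {chrom}")

    @property
    def n(self) -> int:
        return int(sum(a.size for a in self.anchors.values()))

    def forward_positions(self, chrom: str) -> np.ndarray:
        """All E_f positions on one chromosome, sorted."""
        a = self.anchors.get(chrom, np.empty(0, np.int64))
        return (a[:, None] + np.arange(self.w, dtype=np.int64)).ravel()

    def reverse_positions(self, chrom: str) -> np.ndarray:
        """All E_g positions (reverse 5' coordinates), sorted."""
        return self.forward_positions(chrom) + self.d + self.w

    def peak_intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) half-open footprints [a, a + 2w + d) ("peak" regions)."""
        a = self.anchors.get(chrom, np.empty(0, np.int64))
        return np.stack([a, a + 2 * self.w + self.d], axis=1)


def simulate_sites(
    genome: GenomeSpec,
    n: int,
    w: int = DEFAULT_W,
    d: int = DEFAULT_D,
    seed=0,
    read_length: int = DEFAULT_R,
) -> SiteLayout:
    """Place n non-overlapping binding-event footprints uniformly.

    Seeded rejection sampling with a retry cap of 1000 * n; anchors are
    kept clear of the chromosome ends so full-length reads fit around
    every site.  Events are apportioned to chromosomes in proportion to
    length (largest-remainder rounding).
    """
    rng = _rng(seed)
    footprint = 2 * w + d
    if n < 0:
        raise ValueError("n must be >= 0")
    total = genome.total_length
    if n * footprint > 0.5 * total:
        raise ValueError("site footprints exceed half the genome; reduce n")
    # apportion events across chromosomes by length
    quotas = {}
    if n > 0:
        exact = np.array([l / total * n for l in genome.lengths])
        base = np.floor(exact).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(exact - base))
        base[order[:rem]] += 1
        quotas = dict(zip(genome.names, base))
    anchors: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        quota = int(quotas.get(chrom, 0))
        if quota == 0:
            continue
        lo = max(0, read_length - 1 - (w + d))  # reverse reads must fit
        hi = min(length - footprint, length - w - read_length + 1)
        if hi < lo:
            raise ValueError(f"chromosome {chrom} too short for the layout")
        accepted: list[int] = []
        starts = np.empty(0, dtype=np.int64)
        tries = 0
        while len(accepted) < quota:
            tries += 1
            if tries > 1000 * n:
                raise RuntimeError(
                    "site placement failed after bounded retries; reduce n"
                )
            a = int(rng.integers(lo, hi + 1))
            j = np.searchsorted(starts, a)
            if j > 0 and a < starts[j - 1] + footprint:
                continue
            if j < starts.size and starts[j] < a + footprint:
                continue
            accepted.append(a)
            starts = np.insert(starts, j, a)
        anchors[chrom] = starts
    return SiteLayout(genome, w, d, anchors)


def _split_counts(rng, totals: np.ndarray, k: int) -> np.ndarray:
    """Split k draws over bins proportionally to ``totals`` (multivariate
    hypergeometric), deterministic apportionment for a single bin."""
    if totals.size == 1:
        return np.array([k], dtype=np.int64)
    return rng.multivariate_hypergeometric(totals, k).astype(np.int64)


def simulate_reads(
    layout: SiteLayout,
    params: ModelParams,
    seed=0,
    allocation: str = "deterministic",
) -> BinaryDensity:
    """Draw a binarised read density under the model.

    Per strand, round(M * alpha / 2) signal 5' positions are drawn
    uniformly without replacement over the enriched regions and
    round(M * (1 - alpha) / 2) noise positions over the whole
    chromosome (clear of the ends so that full-length reads fit).
    ``allocation="deterministic"`` fixes those counts exactly;
    ``"multinomial"`` draws the signal count per strand from
    Binomial(M/2, alpha).  If the signal allocation exceeds the n*w
    available enriched positions (saturated regime) the regions fill
    completely and the surplus reads are duplicates.
    """
    if params.n != layout.n or params.w != layout.w or params.d != layout.d:
        raise ValueError("params (n, w, d) disagree with the site layout")
    if params.G != layout.genome.total_length:
        raise ValueError("params.G disagrees with the layout genome")
    if allocation not in ("deterministic", "multinomial"):
        raise ValueError(f"unknown allocation {allocation!r}")
    rng = _rng(seed)
    genome = layout.genome
    R = params.R
    half = params.M // 2
    if allocation == "deterministic":
        n_signal = int(round(half * params.alpha))
    else:
        n_signal = int(rng.binomial(half, params.alpha))
    n_noise = half - n_signal

    nw_total = params.n * params.w
    n_signal_distinct = min(n_signal, nw_total)

    chrom_lengths = np.array(genome.lengths, dtype=np.int64)
    # usable noise span per chromosome (reads must fit inside)
    noise_lo = R - 1  # reverse 5' >= R-1; forward noise uses mirrored span
    noise_span = np.maximum(chrom_lengths - R + 1, 0)
    site_counts = np.array(
        [layout.anchors.get(c, np.empty(0)).size * params.w for c in genome.names],
        dtype=np.int64,
    )

    forward: dict[str, np.ndarray] = {}
    reverse: dict[str, np.ndarray] = {}
    sig_split = (
        _split_counts(rng, site_counts, n_signal_distinct)
        if nw_total
        else np.zeros(len(genome.names), dtype=np.int64)
    )
    noise_split = _split_counts(rng, noise_span, n_noise) if n_noise else np.zeros(
        len(genome.names), dtype=np.int64
    )
    for ci, (chrom, length) in enumerate(genome.items()):
        parts_f, parts_g = [], []
        k_sig = int(sig_split[ci])
        if k_sig:
            ef = layout.forward_positions(chrom)
            eg = layout.reverse_positions(chrom)
            parts_f.append(ef[sample_without_replacement(rng, ef.size, k_sig)])
            parts_g.append(eg[sample_without_replacement(rng, eg.size, k_sig)])
        k_noise = int(noise_split[ci])
        if k_noise:
            span = int(noise_span[ci])
            # forward noise 5' in [0, L-R]; reverse noise 5' in [R-1, L-1]
            parts_f.append(sample_without_replacement(rng, span, k_noise))
            parts_g.append(
                sample_without_replacement(rng, span, k_noise) + noise_lo
            )
        if parts_f:
            forward[chrom] = np.unique(np.concatenate(parts_f))
        if parts_g:
            reverse[chrom] = np.unique(np.concatenate(parts_g))
    n_records = 2 * half
    density = BinaryDensity(
        genome=genome,
        read_length=R,
        forward=forward,
        reverse=reverse,
        n_records=n_records,
    )
    return density


def simulate_experiment(
    genome: GenomeSpec,
    params: ModelParams,
    seed=0,
    mask: MappabilityMask | None = None,
    allocation: str = "deterministic",
) -> tuple[SiteLayout, BinaryDensity]:
    """Sites + reads in one call; reads at unmappable positions drop.

    When a mask is given, reads whose 5' placement is not uniquely
    mappable are removed, emulating what alignment to a repetitive
    genome does to the observable density.
    """
    rng = np.random.default_rng(seed)
    layout = simulate_sites(
        genome, params.n, params.w, params.d, seed=rng, read_length=params.R
    )
    density = simulate_reads(layout, params, seed=rng, allocation=allocation)
    if mask is not None:
        density = apply_mappability(density, mask)
    return layout, density


def apply_mappability(
    density: BinaryDensity, mask: MappabilityMask
) -> BinaryDensity:
    """Drop read positions whose placement is not uniquely mappable."""
    if mask.read_length != density.read_length:
        raise ValueError("mask and density read lengths differ")
    forward = {
        c: pos[mask.forward[c][pos]] for c, pos in density.forward.items()
    }
    reverse = {
        c: pos[mask.reverse[c][pos]] for c, pos in density.reverse.items()
    }
    kept = sum(p.size for p in forward.values()) + sum(
        p.size for p in reverse.values()
    )
    dropped = density.n_positions - kept
    return BinaryDensity(
        genome=density.genome,
        read_length=density.read_length,
        forward=forward,
        reverse=reverse,
        n_records=max(density.n_records - dropped, kept),
    )


def simulate_genome(
    lengths: dict[str, int],
    repeat_fraction: float = 0.0,
    repeat_unit_length: int = 500,
    seed=0,
) -> dict[str, str]:
    """Random genome with a tunable fraction of repeated sequence.

    A single random repeat unit is copied into randomly chosen
    phase-aligned slots (multiples of the unit length) until
    ``repeat_fraction`` of each chromosome is covered.  Phase alignment
    makes neighbouring copies form seamless tandem arrays, so every
    read-length window inside repeat territory occurs elsewhere in the
    genome and exact mappability drops to ~0 there while staying ~1 in
    the random background.
    """
    if not 0.0 <= repeat_fraction <= 1.0:
        raise ValueError("repeat_fraction must lie in [0, 1]")
    rng = _rng(seed)
    unit = rng.choice(_BASES, size=repeat_unit_length)
    out = {}
    for chrom, length in lengths.items():
        seq = rng.choice(_BASES, size=length)
        if repeat_fraction > 0:
            if repeat_unit_length > length:
                raise ValueError("repeat unit longer than the chromosome")
            slots = length // repeat_unit_length
            n_slots = min(
                slots, int(np.ceil(repeat_fraction * length / repeat_unit_length))
            )
            for s in rng.choice(slots, size=n_slots, replace=False):
                start = int(s) * repeat_unit_length
                seq[start : start + repeat_unit_length] = unit
        out[chrom] = seq.tobytes().decode("ascii")
    return out


def simulate_mappability(
    genome: GenomeSpec,
    read_length: int = DEFAULT_R,
    unmappable_fraction: float = 0.2,
    mean_block: int = 1000,
    seed=0,
) -> MappabilityMask:
    """Synthetic mask: random unmappable blocks covering a set fraction.

    Stands in for an exact-mappability computation at chromosome scales
    where exhaustive k-mer enumeration is not practical; block lengths
    are geometric around ``mean_block`` bp.
    """
    if not 0.0 <= unmappable_fraction < 1.0:
        raise ValueError("unmappable_fraction must lie in [0, 1)")
    rng = _rng(seed)
    forward = {}
    for chrom, length in genome.items():
        base = np.ones(length, dtype=bool)
        target = int(unmappable_fraction * length)
        covered = 0
        while covered < target:
            block = max(1, int(rng.geometric(1.0 / mean_block)))
            start = int(rng.integers(0, max(length - block, 1)))
            seg = base[start : start + block]
            covered += int(seg.sum())
            seg[:] = False
        forward[chrom] = base
    return MappabilityMask(genome, read_length, forward)


# ----------------------------------------------------------------------
# plain-text FASTA helpers for the synthetic genomes


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA record before header")
                out[name].append(line.upper())
    return {n: "".join(parts) for n, parts in out.items()}
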