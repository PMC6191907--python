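"""Coverage-based detection of rRNA fragmentation regions.

Mature 23S rRNA in some bacteria is not a single molecule: RNase cleavage
(often excising an intervening sequence) splits it into stable fragments.
Sequencing RNA from purified ribosomes reveals such cleavage regions as
stretches of an rRNA gene with almost no read coverage. This module maps
reads to the rRNA gene copies with a deliberately strict, deliberately
simple mapper (full-length placement, at least 99% identity), builds
per-base coverage, calls maximal runs of positions whose depth is below 5%
of the locus-wide mean coverage, and compares the called regions across
near-identical gene copies.

The mapper is a brute-force scan of every offset on both strands; ties
between equally good placements are broken uniformly at random with a
seeded generator, so multi-mapping reads across identical copies are
placed once, reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_MAX_MISMATCH_FRAC = 0.01  # >= 99% identity over the full read length
DEFAULT_LOW_COVERAGE_FRACTION = 0.05
DEFAULT_POSITION_TOLERANCE = 2


@dataclass
class CoverageTrack:
    """Per-base read depth for one locus; position 1 is ``depths[0]``."""

    locus_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError("depths must be a non-empty 1-D array")
        if (self.depths < 0).any():
            raise ValueError("depths must be nonnegative")

    @property
    def length(self) -> int:
        return int(self.depths.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depths.mean())


@dataclass(frozen=True)
class FragmentRegion:
    """A maximal low-coverage run, 1-based inclusive coordinates."""

    locus_id: str
    start: int
    end: int
    mean_fraction_of_locus_mean: float
    degenerate: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Placement:
    locus_id: str
    start: int  # 1-based
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class MappingResult:
    tracks: dict[str, CoverageTrack]
    placements: list[Placement | None]
    n_unplaced: int = 0
    log: list[str] = field(default_factory=list)


_BASE_CODES = np.frombuffer(b"\x00" * 256, dtype=np.uint8).copy()
for _i, _b in enumerate(b"ACGTN"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lower case


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _windows(ref_codes: np.ndarray, read_len: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(ref_codes, read_len)


def _scan(read: str, encoded_refs: Mapping[str, np.ndarray],
          max_mismatch_frac: float, rng: np.random.Generator
          ) -> Placement | None:
    cutoff = int(np.floor(max_mismatch_frac * len(read)))
    candidates: list[Placement] = []
    best = cutoff
    fwd = _encode(read)
    rev = _encode(str(Seq(read).reverse_complement()))
    for locus_id, ref_codes in encoded_refs.items():
        if len(read) > ref_codes.size:
            continue
        win = _windows(ref_codes, len(read))
        for strand, codes in (("+", fwd), ("-", rev)):
            mism = (win != codes).sum(axis=1)
            for pos in np.nonzero(mism <= best)[0]:
                m = int(mism[pos])
                if m < best:
                    best = m
                    candidates = []
                candidates.append(Placement(locus_id, int(pos) + 1, strand, m))
    candidates = [c for c in candidates if c.mismatches == best]
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def naive_map(read: str, references: Mapping[str, str],
              max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
              rng: np.random.Generator | None = None) -> Placement | None:
    """Best full-length placement of one read, or None if unplaceable.

    Every offset of every reference is scanned on both strands; placements
    with at most floor(max_mismatch_frac * read_length) mismatches are
    acceptable, the minimum-mismatch ones are kept, and ties are broken
    uniformly at random with ``rng``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    encoded = {locus_id: _encode(ref) for locus_id, ref in references.items()}
    return _scan(read, encoded, max_mismatch_frac, rng)


def map_reads(reads: Iterable[str], references: Mapping[str, str],
              max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
              seed: int = 0) -> MappingResult:
    """Map reads one by one, accumulating per-base coverage per locus."""
    rng = np.random.default_rng(seed)
    encoded = {locus_id: _encode(ref) for locus_id, ref in references.items()}
    tracks = {
        locus_id: np.zeros(len(ref), dtype=np.int64)
        for locus_id, ref in references.items()
    }
    placements: list[Placement | None] = []
    n_unplaced = 0
    for read in reads:
        placement = _scan(read, encoded, max_mismatch_frac, rng)
        placements.append(placement)
        if placement is None:
            n_unplaced += 1
            continue
        depths = tracks[placement.locus_id]
        depths[placement.start - 1 : placement.start - 1 + len(read)] += 1
    result = MappingResult(
        tracks={k: CoverageTrack(k, v) for k, v in tracks.items()},
        placements=placements,
        n_unplaced=n_unplaced,
    )
    if n_unplaced:
        result.log.append(f"{n_unplaced} reads had no acceptable placement")
    return result


def call_low_coverage_regions(track: CoverageTrack,
                              fraction: float = DEFAULT_LOW_COVERAGE_FRACTION
                              ) -> list[FragmentRegion]:
    """Maximal runs of positions with depth strictly below fraction * mean.

    The locus mean includes the low-coverage positions themselves. A
    position exactly at the threshold is never called. An all-zero track
    (mean 0, threshold 0) is returned as a single degenerate region
    spanning the whole locus.
    """
    mean = track.mean_depth
    if mean == 0.0:
        return [FragmentRegion(track.locus_id, 1, track.length, 0.0,
                               degenerate=True)]
    threshold = fraction * mean
    low = track.depths < threshold
    regions = []
    padded = np.diff(np.concatenate(([0], low.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0] - 1
    for s, e in zip(starts, ends):
        region_mean = float(track.depths[s : e + 1].mean())
        regions.append(
            FragmentRegion(track.locus_id, int(s) + 1, int(e) + 1,
                           region_mean / mean)
        )
    return regions


@dataclass(frozen=True)
class RegionGroup:
    """Equivalent regions across loci; shared iff present in every locus."""

    members: tuple[FragmentRegion, ...]
    shared: bool


def compare_regions(regions_by_locus: Mapping[str, Sequence[FragmentRegion]],
                    tolerance: int = DEFAULT_POSITION_TOLERANCE
                    ) -> list[RegionGroup]:
    """Group regions from different loci that coincide within a tolerance.

    Two regions are equivalent when both their start and their end
    coordinates differ by at most ``tolerance`` nucleotides from the
    group's first member. A group is shared when every locus contributes
    a region to it, unique otherwise.
    """
    if len(regions_by_locus) < 2:
        raise ValueError("region comparison needs at least two loci")
    n_loci = len(regions_by_locus)
    groups: list[list[FragmentRegion]] = []
    for locus_id in sorted(regions_by_locus):
        for region in sorted(regions_by_locus[locus_id], key=lambda r: r.start):
            for group in groups:
                rep = group[0]
                if (abs(region.start - rep.start) <= tolerance
                        and abs(region.end - rep.end) <= tolerance
                        and all(m.locus_id != region.locus_id for m in group)):
                    group.append(region)
                    break
            else:
                groups.append([region])
    return [
        RegionGroup(tuple(g), shared=len({m.locus_id for m in g}) == n_loci)
        for g in groups
    ]


# --- I/O ---------------------------------------------------------------


def read_references(path: str | Path) -> dict[str, str]:
    """Reference sequences from a FASTA file, keyed by record id."""
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_fastq_sequences(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def read_bedgraph(path: str | Path, lengths: Mapping[str, int] | None = None
                  ) -> dict[str, CoverageTrack]:
    """Coverage tracks from a bedGraph-like file (locus, start, end, depth).

    Intervals are 0-based half-open, the usual bedGraph convention, and are
    converted to 1-based inclusive internally. Locus lengths default to the
    largest end coordinate seen.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["locus", "start", "end", "depth"])
    tracks = {}
    for locus, grp in df.groupby("locus", sort=True):
        length = (lengths or {}).get(str(locus), int(grp["end"].max()))
        depths = np.zeros(length, dtype=np.int64)
        for row in grp.itertuples(index=False):
            depths[int(row.start) : int(row.end)] = int(row.depth)
        tracks[str(locus)] = CoverageTrack(str(locus), depths)
    return tracks


def write_coverage_tsv(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"locus_id": t.locus_id,
                      "position": np.arange(1, t.length + 1),
                      "depth": t.depths})
        for t in tracks.values()
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def regions_to_frame(regions: Iterable[FragmentRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"locus_id": r.locus_id, "start": r.start, "end": r.end,
             "length": r.length,
             "mean_fraction_of_locus_mean": r.mean_fraction_of_locus_mean,
             "degenerate": r.degenerate}
            for r in regions
        ]
    )


def groups_to_frame(groups: Iterable[RegionGroup]) -> pd.DataFrame:
    rows = []
    for i, group in enumerate(groups):
        for member in group.members:
            rows.append(
                {"group": i, "shared": group.shared, "locus_id": member.locus_id,
                 "start": member.start, "end": member.end,
                 "length": member.length}
            )
    return pd.DataFrame(rows)
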