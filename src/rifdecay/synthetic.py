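"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate a rifampicin-chase microarray study and a
ribosome-RNA sequencing run: per-gene exponential decay 2**(-t/h) sampled
at 2, 5, 10 and 15 min against the pre-rifampicin reference, three
replicate two-color hybridizations with dye swap, multiplicative channel
noise, per-array scale factors, flagged bad spots and 1:1 spike-in control
spots; and rRNA read sets drawn from a reference with planted zero-coverage
intervals standing in for fragmentation regions. Every generator is fully
determined by its seed and returns the ground truth next to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arrays import (
    DEFAULT_SPIKE_IDS,
    Hybridization,
    ORIENT_T0_IN_CY3,
    ORIENT_T0_IN_CY5,
)
from .fragmentation import CoverageTrack

DEFAULT_TIMEPOINTS = (2.0, 5.0, 10.0, 15.0)
DEFAULT_REPLICATES = 3
DEFAULT_SPOTS_PER_CONTROL = 32
#: spike-in hybridization signal in the same arbitrary units as gene spots
SPIKE_BASE_LEVEL = 1000.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    true_half_life: float  # minutes
    baseline_abundance: float  # linear intensity units at t0

    def __post_init__(self) -> None:
        if self.true_half_life <= 0:
            raise ValueError("half-life must be positive")
        if self.baseline_abundance <= 0:
            raise ValueError("baseline abundance must be positive")


@dataclass(frozen=True)
class SpikeInSpec:
    """One spike-in control series present on every array."""

    control_id: str
    spots_per_array: int = DEFAULT_SPOTS_PER_CONTROL
    nominal_ratio_a_to_b: float = 1.0

    def __post_init__(self) -> None:
        if self.spots_per_array < 1:
            raise ValueError("need at least one spot per array")
        if self.nominal_ratio_a_to_b <= 0:
            raise ValueError("nominal ratio must be positive")


def default_spikes() -> list[SpikeInSpec]:
    return [SpikeInSpec(cid) for cid in DEFAULT_SPIKE_IDS]


@dataclass(frozen=True)
class GapPlan:
    """Planted zero-coverage intervals (1-based inclusive) for one locus."""

    locus_id: str
    reference_length: int
    excluded_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in sorted(self.excluded_intervals):
            if start > end:
                raise ValueError(f"interval start {start} after end {end}")
            if start < 1 or end > self.reference_length:
                raise ValueError("interval outside the reference")
            if start <= prev_end:
                raise ValueError("intervals overlap")
            prev_end = end


def gen_decay_truth(n_genes: int, log_mean: float = 5.7, log_sd: float = 0.4,
                    seed: int = 0, abundance_log_mean: float = 2000.0,
                    abundance_log_sd: float = 1.0) -> list[SyntheticTruth]:
    """Log-normal half-lives (median ``log_mean`` minutes) and abundances.

    ``log_mean`` is the median of the half-life distribution in minutes and
    ``log_sd`` the standard deviation on the natural-log scale; with
    ``log_sd=0`` every gene gets exactly ``log_mean``.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if log_sd < 0 or abundance_log_sd < 0:
        raise ValueError("spread parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    half_lives = rng.lognormal(np.log(log_mean), log_sd, size=n_genes)
    abundances = rng.lognormal(np.log(abundance_log_mean), abundance_log_sd,
                               size=n_genes)
    width = max(4, len(str(n_genes)))
    return [
        SyntheticTruth(f"GENE{i:0{width}d}", float(h), float(a))
        for i, (h, a) in enumerate(zip(half_lives, abundances), start=1)
    ]


def gen_hybridizations(
    truth: Sequence[SyntheticTruth],
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd_log2: float = 0.15,
    bad_spot_prob: float = 0.01,
    spikes: Sequence[SpikeInSpec] | None = None,
    seed: int = 0,
    background_mean: float = 50.0,
    background_sd: float = 10.0,
    array_scale_sd_log2: float = 0.25,
) -> list[Hybridization]:
    """One spot table per (timepoint, replicate) with known decay truth.

    For gene g at time t the underlying ratio of the tx channel to the t0
    channel is 2**(-t/h_g); each spot additionally carries independent
    log-normal noise (sd ``noise_sd_log2`` on the log2 ratio) and every
    array a global scale factor (log-normal, sd ``array_scale_sd_log2`` on
    log2) that the spike-in normalization must remove. Dye orientation
    alternates across replicates (replicate 1 hybridizes t0 in Cy3).
    Foregrounds are level + background, with backgrounds drawn around
    ``background_mean``, so the signal-to-noise filter is exercisable;
    spots turn bad (Flags = -50) with probability ``bad_spot_prob``.
    """
    if not truth:
        raise ValueError("truth table is empty")
    if noise_sd_log2 < 0:
        raise ValueError("noise must be nonnegative")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if any(t <= 0 for t in timepoints):
        raise ValueError("timepoints must be positive minutes")
    spikes = list(spikes) if spikes is not None else default_spikes()
    rng = np.random.default_rng(seed)
    hybs = []
    for replicate in range(1, replicates + 1):
        orientation = ORIENT_T0_IN_CY3 if replicate % 2 == 1 else ORIENT_T0_IN_CY5
        for t in timepoints:
            scale = float(2.0 ** rng.normal(0.0, array_scale_sd_log2))
            hybs.append(
                _make_array(truth, t, replicate, orientation, scale,
                            noise_sd_log2, bad_spot_prob, spikes,
                            background_mean, background_sd, rng)
            )
    return hybs


def _make_array(truth, timepoint, replicate, orientation, scale,
                noise_sd_log2, bad_spot_prob, spikes,
                background_mean, background_sd,
                rng: np.random.Generator) -> Hybridization:
    gene_ids, t0_levels, tx_levels = [], [], []
    for g in truth:
        decay = 2.0 ** (-timepoint / g.true_half_life)
        noise = 2.0 ** rng.normal(0.0, noise_sd_log2) if noise_sd_log2 else 1.0
        gene_ids.append(g.gene_id)
        t0_levels.append(g.baseline_abundance)
        tx_levels.append(g.baseline_abundance * decay * noise)
    for spike in spikes:
        # mix A accompanies the t0 sample, mix B the tx sample
        for _ in range(spike.spots_per_array):
            noise = 2.0 ** rng.normal(0.0, noise_sd_log2) if noise_sd_log2 else 1.0
            gene_ids.append(spike.control_id)
            t0_levels.append(SPIKE_BASE_LEVEL * spike.nominal_ratio_a_to_b)
            tx_levels.append(SPIKE_BASE_LEVEL * noise)
    n = len(gene_ids)
    t0_levels = np.asarray(t0_levels)
    tx_levels = np.asarray(tx_levels)
    if orientation == ORIENT_T0_IN_CY3:
        cy5, cy3 = tx_levels, t0_levels
    else:
        cy5, cy3 = t0_levels, tx_levels
    cy5 = cy5 * scale  # the array scale acts on the Cy5/Cy3 ratio
    b635 = np.clip(rng.normal(background_mean, background_sd, n), 0.0, None)
    b532 = np.clip(rng.normal(background_mean, background_sd, n), 0.0, None)
    flags = np.where(rng.random(n) < bad_spot_prob, -50, 0)
    spots = pd.DataFrame(
        {
            "spot_id": [f"spot{i:05d}" for i in range(n)],
            "gene_id": gene_ids,
            "flags": flags,
            "f635": cy5 + b635,
            "b635": b635,
            "f532": cy3 + b532,
            "b532": b532,
            "ratio": cy5 / cy3,
        }
    )
    return Hybridization(
        array_id=f"t{timepoint:g}_rep{replicate}",
        timepoint=timepoint,
        replicate=replicate,
        dye_orientation=orientation,
        spots=spots,
    )


@dataclass
class RrnaReadSet:
    """Simulated reads for one rRNA locus plus exact placement truth."""

    plan: GapPlan
    reference: str
    reads: list[str]
    read_starts: list[int]  # 1-based
    read_strands: list[str]
    truth_coverage: CoverageTrack


def gen_rrna_reads(plan: GapPlan, read_length: int = 100, n_reads: int = 2000,
                   per_base_error: float = 0.0, seed: int = 0,
                   sequence: str | None = None,
                   both_strands: bool = True) -> RrnaReadSet:
    """Uniform read sampling that avoids every excluded interval.

    Reads start uniformly among positions whose full span stays clear of
    all planted intervals, so the truth coverage is exactly zero inside
    them. Substitution errors (rate ``per_base_error`` per base) are
    applied after the truth coverage is recorded. A random reference is
    generated unless ``sequence`` is supplied (e.g. to share sequence
    between near-identical gene copies).
    """
    rng = np.random.default_rng(seed)
    L = plan.reference_length
    if read_length > L:
        raise ValueError("read length exceeds the reference")
    if sequence is None:
        sequence = "".join(rng.choice(list("ACGT"), size=L))
    elif len(sequence) != L:
        raise ValueError("sequence length does not match the plan")
    forbidden = np.zeros(L, dtype=bool)
    for start, end in plan.excluded_intervals:
        forbidden[start - 1 : end] = True
    # a start s (1-based) is valid iff no forbidden base in [s, s+read_length-1]
    window_hits = np.convolve(forbidden.astype(int),
                              np.ones(read_length, dtype=int), mode="valid")
    valid_starts = np.nonzero(window_hits == 0)[0] + 1
    if valid_starts.size == 0:
        raise ValueError("excluded intervals leave no valid read start")
    starts = rng.choice(valid_starts, size=n_reads, replace=True)
    depths = np.zeros(L, dtype=np.int64)
    reads, strands = [], []
    bases = np.array(list("ACGT"))
    for s in starts:
        frag = sequence[s - 1 : s - 1 + read_length]
        depths[s - 1 : s - 1 + read_length] += 1
        strand = "-" if both_strands and rng.random() < 0.5 else "+"
        if strand == "-":
            frag = str(Seq(frag).reverse_complement())
        if per_base_error > 0:
            arr = np.array(list(frag))
            hit = rng.random(read_length) < per_base_error
            for i in np.nonzero(hit)[0]:
                arr[i] = rng.choice(bases[bases != arr[i]])
            frag = "".join(arr)
        reads.append(frag)
        strands.append(strand)
    return RrnaReadSet(
        plan=plan,
        reference=sequence,
        reads=reads,
        read_starts=[int(s) for s in starts],
        read_strands=strands,
        truth_coverage=CoverageTrack(plan.locus_id, depths),
    )


def gen_count_table(n_genes: int, lengths: Sequence[int], seed: int = 0,
                    mean_rate: float = 500.0, rate_log_sd: float = 1.0
                    ) -> pd.DataFrame:
    """Reproducible fragment counts per gene (Poisson around log-normal rates).

    The returned frame carries the library size (sum of counts) in
    ``attrs['library_size']``.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    lengths = list(lengths)
    if len(lengths) != n_genes:
        raise ValueError("lengths must match n_genes")
    if any(l <= 0 for l in lengths):
        raise ValueError("gene lengths must be positive")
    rng = np.random.default_rng(seed)
    rates = rng.lognormal(np.log(mean_rate), rate_log_sd, size=n_genes)
    counts = rng.poisson(rates)
    width = max(4, len(str(n_genes)))
    df = pd.DataFrame(
        {
            "gene_id": [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)],
            "length": lengths,
            "fragment_count": counts.astype(int),
        }
    )
    df.attrs["library_size"] = int(counts.sum())
    return df


# --- disk output -------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=locus_id, description="")
               for locus_id, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Sequence[str], path: str | Path, phred: int = 40) -> None:
    records = []
    for i, read in enumerate(reads):
        rec = SeqRecord(Seq(read), id=f"read{i:06d}", description="")
        rec.letter_annotations["phred_quality"] = [phred] * len(read)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_truth_table(truth: Sequence[SyntheticTruth], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in truth]).to_csv(path, sep="\t", index=False)


def write_params_sidecar(params: dict, path: str | Path) -> None:
    """Echo generation parameters to JSON for provenance."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_truth_table(path: str | Path) -> list[SyntheticTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        SyntheticTruth(str(r.gene_id), float(r.true_half_life),
                       float(r.baseline_abundance))
        for r in df.itertuples(index=False)
    ]
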