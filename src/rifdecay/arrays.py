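"""Two-color microarray normalization for rifampicin-chase experiments.

Each hybridization compares cDNA from a post-rifampicin time point (tx) with
the pre-rifampicin reference (t0) on one two-color array. Spots are quality
filtered (flags and signal-to-noise), every ratio on an array is rescaled by
a single factor derived from 1:1 spike-in control spots so that the controls'
mean log2 ratio is zero, and replicate log2 ratios are averaged per gene and
time point into decay profiles ready for log-linear fitting.

Spot tables are tab-delimited in the GenePix results (GPR) dialect: a header
row naming at least the ID, Flags and per-channel foreground/background
median columns, preceded by optional ``#`` comment lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Spike-in control IDs printed on the arrays; both are present 1:1 in the
#: A and B spike mixes and anchor the per-hybridization normalization.
DEFAULT_SPIKE_IDS = ("(+)E1A_r60_1", "(+)E1A_r60_a20")

#: Column names of the GPR dialect, overridable via ``GprColumns``.
DEFAULT_COLUMNS = {
    "id": "ID",
    "flags": "Flags",
    "f635": "F635 Median",
    "b635": "B635 Median",
    "f532": "F532 Median",
    "b532": "B532 Median",
    "ratio": "Ratio of Medians",
}

SN_THRESHOLD = 3.0

ORIENT_T0_IN_CY3 = "t0_in_cy3"  # tx in Cy5 -> ratio of medians is tx/t0
ORIENT_T0_IN_CY5 = "t0_in_cy5"  # tx in Cy3 -> ratio of medians is t0/tx


@dataclass(frozen=True)
class SpotMeasurement:
    """One array spot: identifiers, flags and channel median intensities."""

    spot_id: str
    gene_id: str
    flags: int
    f635_median: float
    b635_median: float
    f532_median: float
    b532_median: float
    ratio_of_medians: float | None = None


@dataclass
class Hybridization:
    """One array: spot table plus design metadata.

    ``spots`` is a DataFrame with canonical columns ``spot_id``, ``gene_id``,
    ``flags``, ``f635``, ``b635``, ``f532``, ``b532``, ``ratio``.
    """

    array_id: str
    timepoint: float
    replicate: int
    dye_orientation: str
    spots: pd.DataFrame
    normalization_factor: float | None = None

    def __post_init__(self) -> None:
        if self.dye_orientation not in (ORIENT_T0_IN_CY3, ORIENT_T0_IN_CY5):
            raise ValueError(f"unknown dye orientation {self.dye_orientation!r}")


@dataclass
class DecayProfile:
    """Per-gene averaged log2(tx/t0) ratios at the sampled time points."""

    gene_id: str
    mean_log2_ratio: dict[float, float] = field(default_factory=dict)
    n_replicates_used: dict[float, int] = field(default_factory=dict)


class NormalizationError(ValueError):
    """Raised when a hybridization has no usable spike-in control spots."""


def read_gpr(path: str | Path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a GPR-dialect spot table into the canonical spot DataFrame.

    Lines before the header starting with ``#`` are ignored. The ratio of
    medians column is optional; missing ratios are recomputed from the
    background-subtracted channel medians where both are positive.
    """
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["id", "flags", "f635", "b635", "f532", "b532"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing GPR columns {missing}")
    out = pd.DataFrame(
        {
            "gene_id": df[cols["id"]].astype(str),
            "flags": df[cols["flags"]].astype(int),
            "f635": df[cols["f635"]].astype(float),
            "b635": df[cols["b635"]].astype(float),
            "f532": df[cols["f532"]].astype(float),
            "b532": df[cols["b532"]].astype(float),
        }
    )
    out.insert(0, "spot_id", [f"spot{i:05d}" for i in range(len(out))])
    if cols["ratio"] in df.columns:
        out["ratio"] = df[cols["ratio"]].astype(float)
    else:
        out["ratio"] = np.nan
    need = out["ratio"].isna()
    num = out["f635"] - out["b635"]
    den = out["f532"] - out["b532"]
    computable = need & (num > 0) & (den > 0)
    out.loc[computable, "ratio"] = num[computable] / den[computable]
    return out


def write_gpr(spots: pd.DataFrame, path: str | Path,
              comment_lines: Sequence[str] = ()) -> None:
    """Write a canonical spot DataFrame as a GPR-dialect TSV."""
    cols = DEFAULT_COLUMNS
    df = pd.DataFrame(
        {
            cols["id"]: spots["gene_id"],
            cols["flags"]: spots["flags"],
            cols["f635"]: spots["f635"],
            cols["b635"]: spots["b635"],
            cols["f532"]: spots["f532"],
            cols["b532"]: spots["b532"],
            cols["ratio"]: spots["ratio"],
        }
    )
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Read the array metadata TSV: array_id, path, timepoint, replicate,
    dye_orientation."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"array_id", "path", "timepoint", "replicate", "dye_orientation"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"samplesheet missing columns {sorted(missing)}")
    return sheet


def load_hybridizations(samplesheet: str | Path,
                        columns: Mapping[str, str] | None = None) -> list[Hybridization]:
    sheet = read_samplesheet(samplesheet)
    base = Path(samplesheet).parent
    hybs = []
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        hybs.append(
            Hybridization(
                array_id=str(row.array_id),
                timepoint=float(row.timepoint),
                replicate=int(row.replicate),
                dye_orientation=str(row.dye_orientation),
                spots=read_gpr(p, columns),
            )
        )
    return hybs


def passes_quality(spot: SpotMeasurement) -> bool:
    """Spot-level quality filter: flags >= 0 and S/N >= 3 in either channel.

    Signal-to-noise is foreground median over background median per channel;
    a zero background with positive foreground counts as passing that
    channel (infinite S/N). Total function: never raises.
    """
    if spot.flags < 0:
        return False
    return _sn_pass(spot.f635_median, spot.b635_median) or _sn_pass(
        spot.f532_median, spot.b532_median
    )


def _sn_pass(fg: float, bg: float) -> bool:
    if bg == 0:
        return fg > 0
    return fg / bg >= SN_THRESHOLD


def quality_mask(spots: pd.DataFrame) -> pd.Series:
    """Vectorized `passes_quality` over a canonical spot DataFrame."""
    with np.errstate(divide="ignore", invalid="ignore"):
        sn635 = np.where(spots["b635"] == 0,
                         np.where(spots["f635"] > 0, np.inf, 0.0),
                         spots["f635"] / spots["b635"])
        sn532 = np.where(spots["b532"] == 0,
                         np.where(spots["f532"] > 0, np.inf, 0.0),
                         spots["f532"] / spots["b532"])
    return (spots["flags"] >= 0) & (
        (sn635 >= SN_THRESHOLD) | (sn532 >= SN_THRESHOLD)
    )


def compute_normalization_factor(hyb: Hybridization,
                                 spike_ids: Iterable[str] = DEFAULT_SPIKE_IDS) -> float:
    """Per-hybridization scale factor from the 1:1 spike-in control spots.

    The factor f = 2**(-mean(log2 r_i)) over quality-passing control spots
    with positive ratios; multiplying every ratio on the array by f centers
    the controls' mean log2 ratio at zero.

    Raises
    ------
    NormalizationError
        If no control spot passes the quality filter with a positive ratio.
    """
    ids = set(spike_ids)
    spots = hyb.spots
    ok = quality_mask(spots) & spots["gene_id"].isin(ids) & (spots["ratio"] > 0)
    ratios = spots.loc[ok, "ratio"].to_numpy()
    if ratios.size == 0:
        raise NormalizationError(
            f"array {hyb.array_id}: no passing 1:1 control spots among {sorted(ids)}"
        )
    factor = float(2.0 ** (-np.mean(np.log2(ratios))))
    hyb.normalization_factor = factor
    return factor


def normalize_and_orient(hyb: Hybridization, factor: float,
                         spike_ids: Iterable[str] = DEFAULT_SPIKE_IDS) -> pd.DataFrame:
    """Normalized, orientation-corrected log2(tx/t0) per passing gene spot.

    Each passing spot contributes log2(ratio * factor); arrays hybridized
    with t0 in the Cy5 channel store t0/tx ratios, so their log ratios are
    sign-flipped to the canonical tx/t0 orientation. Spike-in control spots
    are excluded from the output. Spots with nonpositive ratios are dropped
    (counted in the ``n_dropped_nonpositive`` attribute of the result).
    """
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    ids = set(spike_ids)
    spots = hyb.spots
    ok = quality_mask(spots) & ~spots["gene_id"].isin(ids)
    positive = spots["ratio"] > 0
    n_dropped = int((ok & ~positive).sum())
    use = spots.loc[ok & positive, ["gene_id", "ratio"]].copy()
    log2r = np.log2(use["ratio"].to_numpy() * factor)
    if hyb.dye_orientation == ORIENT_T0_IN_CY5:
        log2r = -log2r
    out = pd.DataFrame({"gene_id": use["gene_id"].to_numpy(), "log2_ratio": log2r})
    out.attrs["n_dropped_nonpositive"] = n_dropped
    out.attrs["array_id"] = hyb.array_id
    return out


def average_replicates(
    per_replicate: Mapping[str, Mapping[float, Sequence[float]]]
) -> list[DecayProfile]:
    """Average per-replicate log2 ratios into per-gene decay profiles.

    A (gene, timepoint) appears in the profile if at least one replicate
    value survived filtering; the replicate count is recorded alongside the
    arithmetic mean (a geometric mean on the ratio scale).
    """
    profiles = []
    for gene_id in sorted(per_replicate):
        by_t = per_replicate[gene_id]
        prof = DecayProfile(gene_id=gene_id)
        for t in sorted(by_t):
            values = [v for v in by_t[t] if math.isfinite(v)]
            if values:
                prof.mean_log2_ratio[t] = float(np.mean(values))
                prof.n_replicates_used[t] = len(values)
        if prof.mean_log2_ratio:
            profiles.append(prof)
    return profiles


def build_decay_profiles(
    hybridizations: Sequence[Hybridization],
    spike_ids: Iterable[str] = DEFAULT_SPIKE_IDS,
) -> tuple[list[DecayProfile], pd.DataFrame]:
    """Full normalization pipeline: factor, orientation, replicate averaging.

    Returns the decay profiles and a per-array diagnostics table
    (normalization factor, passing spot counts, dropped-ratio counts).
    Arrays whose spike-in controls all fail quality are rejected and appear
    in the diagnostics with status ``rejected``.
    """
    collected: dict[str, dict[float, list[float]]] = {}
    diag_rows = []
    for hyb in hybridizations:
        try:
            factor = compute_normalization_factor(hyb, spike_ids)
        except NormalizationError as exc:
            diag_rows.append(
                {"array_id": hyb.array_id, "timepoint": hyb.timepoint,
                 "replicate": hyb.replicate, "status": "rejected",
                 "normalization_factor": np.nan, "n_gene_values": 0,
                 "n_dropped_nonpositive": 0, "detail": str(exc)}
            )
            continue
        table = normalize_and_orient(hyb, factor, spike_ids)
        for gene_id, value in zip(table["gene_id"], table["log2_ratio"]):
            collected.setdefault(gene_id, {}).setdefault(hyb.timepoint, []).append(value)
        diag_rows.append(
            {"array_id": hyb.array_id, "timepoint": hyb.timepoint,
             "replicate": hyb.replicate, "status": "ok",
             "normalization_factor": factor, "n_gene_values": len(table),
             "n_dropped_nonpositive": table.attrs["n_dropped_nonpositive"],
             "detail": ""}
        )
    return average_replicates(collected), pd.DataFrame(diag_rows)


def profiles_to_frame(profiles: Sequence[DecayProfile]) -> pd.DataFrame:
    """Long-format table of decay profiles (gene_id, timepoint, mean_log2_ratio, n)."""
    rows = [
        (p.gene_id, t, p.mean_log2_ratio[t], p.n_replicates_used[t])
        for p in profiles
        for t in sorted(p.mean_log2_ratio)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "timepoint", "mean_log2_ratio",
                                       "n_replicates_used"])


def frame_to_profiles(frame: pd.DataFrame) -> list[DecayProfile]:
    profiles = []
    for gene_id, grp in frame.groupby("gene_id", sort=True):
        prof = DecayProfile(gene_id=str(gene_id))
        for row in grp.itertuples(index=False):
            t = float(row.timepoint)
            prof.mean_log2_ratio[t] = float(row.mean_log2_ratio)
            prof.n_replicates_used[t] = int(row.n_replicates_used)
        profiles.append(prof)
    return profiles
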