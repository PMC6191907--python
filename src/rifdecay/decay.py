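"""Log-linear mRNA decay fitting with an R-squared gate.

After rifampicin blocks transcription initiation, each transcript decays
exponentially, so its level obeys N(t) = N(0) * 2**(-t/h) with half-life h.
On the log2 scale the averaged ratios y_t = log2(N(t)/N(0)) fall on a line
of slope -1/h through the origin; here the line is fitted by ordinary least
squares with a free intercept, using only the measured time points.

A fit is accepted when R² > 0.7 on all four time points (2, 5, 10, 15 min).
Genes failing that gate are refitted on the first three time points only:
short-lived transcripts can reach the array's detection floor before 15 min,
flattening the last point and spoiling an otherwise clean decay line.
Accepted slopes convert to half-lives as h = -1/slope; nonnegative slopes
are censored (no decay observed), not reported as infinite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import DecayProfile

R2_GATE = 0.7
CANONICAL_TIMEPOINTS = (2.0, 5.0, 10.0, 15.0)
FALLBACK_TIMEPOINTS = (2.0, 5.0, 10.0)

STATUS_OK_4PT = "ok_4pt"
STATUS_OK_3PT = "ok_3pt"
STATUS_UNRESOLVED = "unresolved"
STATUS_CENSORED = "censored"
OK_STATUSES = frozenset({STATUS_OK_4PT, STATUS_OK_3PT})


@dataclass(frozen=True)
class HalfLifeEstimate:
    gene_id: str
    slope: float | None
    intercept: float | None
    r_squared: float | None
    n_points: int
    half_life: float | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status in OK_STATUSES


@dataclass(frozen=True)
class OperonEstimate:
    operon_id: str
    member_genes: tuple[str, ...]
    mean_half_life: float
    n_members_estimated: int

    @property
    def mean_half_life_rounded(self) -> float:
        """Half-life to one decimal, the precision used in reports."""
        return round(self.mean_half_life, 1)


def ols_fit(times: Sequence[float], log2_ratios: Sequence[float]
            ) -> tuple[float, float, float | None]:
    """Ordinary least squares line through (t, y): (slope, intercept, R²).

    R² = 1 - SSres/SStot; when SStot is zero (constant y) R² is undefined
    and returned as None. Requires at least three distinct time points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(log2_ratios, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points for a decay fit")
    if np.unique(t).size != t.size:
        raise ValueError("time points must be distinct")
    if np.ptp(y) == 0.0:
        # degenerate: flat response, slope 0, R² undefined
        return 0.0, float(y[0]), None
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def half_life_from_slope(slope: float) -> float | None:
    """Half-life in minutes from a log2-scale decay slope; None if censored.

    y(t) = log2(N(t)/N(0)) = -t/h, so h = -1/slope for decaying (negative)
    slopes. Nonnegative slopes mean no observable decay and are censored.
    """
    if slope < 0:
        return -1.0 / slope
    return None


def estimate_half_life(profile: DecayProfile, gate: float = R2_GATE,
                       timepoints: Sequence[float] = CANONICAL_TIMEPOINTS,
                       fallback: Sequence[float] = FALLBACK_TIMEPOINTS
                       ) -> HalfLifeEstimate:
    """Gated per-gene half-life estimate with the three-point fallback.

    All available canonical time points are fitted first; if R² > gate and
    the slope is negative the four-point fit is accepted. Otherwise the fit
    is repeated on the early time points only. Profiles missing any of the
    early time points are unresolved; flat profiles (undefined R²) are
    censored as non-decaying.
    """
    have = profile.mean_log2_ratio
    if not all(t in have for t in fallback):
        return HalfLifeEstimate(profile.gene_id, None, None, None,
                                len(have), None, STATUS_UNRESOLVED)

    full = [t for t in timepoints if t in have]
    windows = [full] if len(full) < len(timepoints) else [full, list(fallback)]

    last = None
    for window in windows:
        y = [have[t] for t in window]
        slope, intercept, r2 = ols_fit(window, y)
        last = (slope, intercept, r2, len(window))
        if r2 is not None and r2 > gate and slope < 0:
            status = STATUS_OK_4PT if len(window) == 4 else STATUS_OK_3PT
            return HalfLifeEstimate(profile.gene_id, slope, intercept, r2,
                                    len(window), half_life_from_slope(slope),
                                    status)

    slope, intercept, r2, n = last
    # a flat profile (undefined R²) or a clean non-decreasing one is censored
    # as non-decaying; a noisy one that merely fails the gate is unresolved
    status = (STATUS_CENSORED if r2 is None or (slope >= 0 and r2 > gate)
              else STATUS_UNRESOLVED)
    return HalfLifeEstimate(profile.gene_id, slope, intercept, r2, n, None, status)


def estimate_all(profiles: Iterable[DecayProfile], gate: float = R2_GATE
                 ) -> list[HalfLifeEstimate]:
    return [estimate_half_life(p, gate) for p in profiles]


def operon_mean(operon_map: Mapping[str, Sequence[str]],
                estimates: Iterable[HalfLifeEstimate]
                ) -> tuple[list[OperonEstimate], list[str]]:
    """Arithmetic mean half-life per operon over members with accepted fits.

    Operons whose members all lack accepted estimates are omitted and listed
    in the returned diagnostics. Means are computed on unrounded member
    half-lives; ``mean_half_life_rounded`` gives the one-decimal report value.
    """
    by_gene = {e.gene_id: e for e in estimates if e.ok}
    out, omitted = [], []
    for operon_id in sorted(operon_map):
        members = operon_map[operon_id]
        values = [by_gene[g].half_life for g in members if g in by_gene]
        if not values:
            omitted.append(operon_id)
            continue
        out.append(OperonEstimate(operon_id, tuple(members),
                                  float(np.mean(values)), len(values)))
    return out, omitted


def summarize(estimates: Iterable[HalfLifeEstimate]
              ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Global mean, median and a 1-minute-binned histogram of accepted fits.

    Histogram bin edges run [k, k+1) in whole minutes spanning the data.
    """
    values = np.array([e.half_life for e in estimates if e.ok], dtype=float)
    if values.size == 0:
        raise ValueError("no accepted half-life estimates to summarize")
    lo = np.floor(values.min())
    hi = np.floor(values.max()) + 1
    edges = np.arange(lo, hi + 1)
    counts, edges = np.histogram(values, bins=edges)
    return float(values.mean()), float(np.median(values)), (counts, edges)


def estimates_to_frame(estimates: Sequence[HalfLifeEstimate]) -> pd.DataFrame:
    """Tabular output; half-lives reported to 0.1 min, math stays full precision."""
    rows = []
    for e in estimates:
        rows.append(
            {"gene_id": e.gene_id, "slope": e.slope, "intercept": e.intercept,
             "r_squared": e.r_squared, "n_points": e.n_points,
             "half_life_min": None if e.half_life is None else round(e.half_life, 1),
             "status": e.status}
        )
    return pd.DataFrame(rows)


def read_operon_map(path) -> dict[str, list[str]]:
    """Operon membership TSV (operon_id, gene_id) to a membership dict."""
    df = pd.read_csv(path, sep="\t")
    if not {"operon_id", "gene_id"} <= set(df.columns):
        raise ValueError("operon map needs columns operon_id, gene_id")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.operon_id), []).append(str(row.gene_id))
    return out
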