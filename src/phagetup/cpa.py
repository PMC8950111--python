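"""Competitive propagation assay (CPA) summaries.

In a CPA, two phage pools — here the white, fast-propagating clone
displaying WSLGYTG and the naive library — are inoculated at equal titer
into one growing E. coli culture. Sampling the culture over time and
measuring the focal clone's share of the pool (by white/blue plaque
counts, or by NGS peptide frequencies) reads out its propagation
advantage. This module computes the per-time-point summaries plus a
convenience per-interval log-odds growth-rate statistic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from ._util import DomainError, round1
from .ngs_pipeline import FrequencyTable, relative_abundance


@dataclass(frozen=True)
class PlaqueObservation:
    """White and blue plaque titers at one sampling time."""

    time_min: float
    white_titer: float
    blue_titer: float

    def __post_init__(self) -> None:
        if self.time_min < 0 or self.white_titer < 0 or self.blue_titer < 0:
            raise DomainError("time and titers must be non-negative")


@dataclass(frozen=True)
class CPASummaryRow:
    """White/blue ratio and white share, rounded to 1 decimal each."""

    time_min: float
    white_blue_ratio: Optional[float]  # None when no blue plaques
    white_percent: float


@dataclass
class CPATimeCourse:
    """Focal-clone percentage over strictly increasing time points."""

    rows: list[tuple[float, float]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.rows]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("time points must be strictly increasing")


def plaque_cpa_row(obs: PlaqueObservation) -> CPASummaryRow:
    """Ratio = white/blue; percent = 100*white/(white+blue); both to 1 dp."""
    total = obs.white_titer + obs.blue_titer
    if total <= 0:
        raise DomainError("both titers are zero")
    ratio = round1(obs.white_titer / obs.blue_titer) if obs.blue_titer > 0 else None
    return CPASummaryRow(
        time_min=obs.time_min,
        white_blue_ratio=ratio,
        white_percent=round1(100.0 * obs.white_titer / total),
    )


def sanger_pick_frequency(picks: Sequence[str]) -> dict[str, tuple[int, float]]:
    """Clone frequencies from a list of Sanger-sequenced plaque picks.

    Returns peptide -> (count, percent of picks to 1 decimal).
    """
    if not picks:
        raise DomainError("empty pick list")
    n = len(picks)
    return {pep: (c, round1(100.0 * c / n)) for pep, c in Counter(picks).items()}


def ngs_cpa_timecourse(
    tables: Sequence[tuple[float, FrequencyTable]], focal: str
) -> CPATimeCourse:
    """Per-time-point relative abundance of the focal peptide from NGS tables."""
    if len(tables) < 2:
        raise DomainError("need at least 2 time points")
    times = [t for t, _ in tables]
    if len(set(times)) != len(times):
        raise DomainError("duplicate time points")
    rows = [(t, relative_abundance(tab, focal)) for t, tab in sorted(tables)]
    return CPATimeCourse(rows=rows)


def relative_fitness(course: CPATimeCourse) -> list[Optional[float]]:
    """Per-interval log-odds growth advantage, in 1/min.

    For consecutive points with focal fractions f1, f2 at t1 < t2:
    s = [ln(f2/(1-f2)) - ln(f1/(1-f1))] / (t2 - t1). Positive s means the
    focal clone is outgrowing the rest of the pool. Intervals with an
    endpoint at exactly 0% or 100% yield ``None`` (log-odds undefined).

    This is a convenience summary, not a quantity printed by the study.
    """
    out: list[Optional[float]] = []
    for (t1, p1), (t2, p2) in zip(course.rows, course.rows[1:]):
        if not (0.0 < p1 < 100.0) or not (0.0 < p2 < 100.0):
            out.append(None)
            continue
        f1, f2 = p1 / 100.0, p2 / 100.0
        s = (math.log(f2 / (1 - f2)) - math.log(f1 / (1 - f1))) / (t2 - t1)
        out.append(s)
    return out


def read_plaque_tsv(path: str | Path) -> list[PlaqueObservation]:
    """Read a TSV with columns time_min, white_titer, blue_titer."""
    obs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["time_min", "white_titer", "blue_titer"]:
            raise DomainError(f"{path}: expected columns time_min/white_titer/blue_titer")
        for line in fh:
            if not line.strip():
                continue
            t, w, b, *_ = line.rstrip("\n").split("\t")
            obs.append(PlaqueObservation(float(t), float(w), float(b)))
    return obs


def write_cpa_rows_tsv(rows: Sequence[CPASummaryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_min\twhite_blue_ratio\twhite_percent\n")
        for r in rows:
            ratio = "NA" if r.white_blue_ratio is None else r.white_blue_ratio
            fh.write(f"{r.time_min:g}\t{ratio}\t{r.white_percent}\n")


def write_timecourse_tsv(course: CPATimeCourse, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_min\tfocal_percent\n")
        for t, p in course.rows:
            fh.write(f"{t:g}\t{p}\n")
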