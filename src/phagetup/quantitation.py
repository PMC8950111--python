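"""Phage quantitation arithmetic: qPCR copies, plaque titers, ELISA ratios.

Three independent bits of bookkeeping used around the assay:

* absolute qPCR quantification — converting a dsDNA mass concentration to
  genome copies/uL via the molar mass of double-stranded DNA
  (607.4 g/mol per bp plus a 157.9 g/mol end correction) and Avogadro's
  number, and a standard curve of Ct against log10 copies;
* plaque-assay titers from serial 10-fold dilutions, in pfu/mL, with the
  usual 50-300 plaques-per-plate countable range flagged;
* ELISA binding ratios — reference-subtracted (540 nm) absorbance at
  450 nm of target-coated over PBS-coated wells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from ._util import DomainError

AVOGADRO = 6.02e23
BP_MOLAR_MASS = 607.4  # g/mol per base pair, dsDNA
END_MASS = 157.9  # g/mol end-group correction

COUNTABLE_RANGE = (50, 300)


def genome_copies_per_ul(
    dsdna_g_per_ul: float, dna_size_bp: float, dilution_factor: float = 1.0
) -> float:
    """Genome copies per microliter from a dsDNA mass concentration.

    gc/uL = [g/uL] / (size_bp * 607.4 + 157.9) * 6.02e23, then multiplied
    by ``dilution_factor`` (applied after the formula).
    """
    if dsdna_g_per_ul <= 0 or dna_size_bp <= 0:
        raise DomainError("concentration and DNA size must be positive")
    if dilution_factor < 1:
        raise DomainError("dilution_factor must be >= 1")
    return dsdna_g_per_ul / (dna_size_bp * BP_MOLAR_MASS + END_MASS) * AVOGADRO * dilution_factor


@dataclass(frozen=True)
class TiterMeasurement:
    plaque_count: int
    dilution_factor: float
    plated_volume_ml: float = 0.01  # 10 uL plated by default

    def __post_init__(self) -> None:
        if self.plaque_count < 0:
            raise DomainError("plaque count must be >= 0")
        if self.dilution_factor < 1:
            raise DomainError("dilution factor must be >= 1")
        if self.plated_volume_ml <= 0:
            raise DomainError("plated volume must be positive")


@dataclass(frozen=True)
class TiterResult:
    pfu_per_ml: float
    in_countable_range: bool


def titer_pfu_per_ml(m: TiterMeasurement) -> TiterResult:
    """pfu/mL = count * dilution / plated volume; flags counts outside 50-300."""
    value = m.plaque_count * m.dilution_factor / m.plated_volume_ml
    lo, hi = COUNTABLE_RANGE
    return TiterResult(pfu_per_ml=value, in_countable_range=lo <= m.plaque_count <= hi)


def elisa_binding_ratio(
    od450_target: float, od540_target: float, od450_pbs: float, od540_pbs: float
) -> float:
    """(OD450 - OD540) of target-coated wells over the same for PBS wells."""
    denom = od450_pbs - od540_pbs
    if denom <= 0:
        raise DomainError("reference-subtracted PBS signal must be positive")
    return (od450_target - od540_target) / denom


@dataclass(frozen=True)
class QPCRStandard:
    """Fitted standard curve: Ct = slope * log10(copies) + intercept."""

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> QPCRStandard:
    """OLS fit of Ct on log10 copies over (log10_copies, Ct) points."""
    if len(points) < 2:
        raise DomainError("need at least 2 standard points")
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if len(set(xs)) < 2:
        raise DomainError("standard points must span at least 2 distinct copy numbers")
    fit = stats.linregress(xs, ys)
    return QPCRStandard(points=tuple((x, y) for x, y in points), slope=fit.slope, intercept=fit.intercept)


def ct_to_copies(std: QPCRStandard, ct: float) -> float:
    """Invert the standard curve: copies = 10**((ct - intercept)/slope)."""
    if std.slope == 0:
        raise DomainError("degenerate standard curve (zero slope)")
    return 10.0 ** ((ct - std.intercept) / std.slope)
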