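"""Colloid stability analysis across conditions.

The central observable is the relationship between particle size (DLS-type
mean) and particle number-concentration (NTA-type count) across a series of
conditions: destabilization by fusion/aggregation shows up as a strong
negative size–concentration correlation, while particle degradation shows
up as a concentration drop with no size increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats

from .stoichiometry import molecules_per_particle


@dataclass(frozen=True)
class MeasurementRecord:
    """One condition's (size, concentration) measurement, one table row."""

    condition_label: str
    size_nm: float
    particles_per_ml: float
    size_sd_nm: Optional[float] = None
    particles_sd: Optional[float] = None
    pdi: Optional[float] = None
    span: Optional[float] = None

    def __post_init__(self):
        if self.size_nm <= 0:
            raise ValueError("size_nm must be > 0")
        if self.particles_per_ml < 0:
            raise ValueError("particles_per_ml must be >= 0")


@dataclass
class StabilitySeries:
    """Ordered measurements across conditions (solvent ratio, surfactant %, time)."""

    records: List[MeasurementRecord]
    ordering_variable: str = "condition"

    def __post_init__(self):
        labels = [r.condition_label for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    def field(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], dtype=float)


@dataclass(frozen=True)
class InstabilityVerdict:
    status: str  # stable | aggregation_or_fusion | degradation
    relative_size_change: float
    relative_concentration_change: float


class UndefinedCorrelationError(ValueError):
    pass


def pearson_correlation(
    series: StabilitySeries,
    x: str = "size_nm",
    y: str = "particles_per_ml",
    with_p_value: bool = False,
):
    """Sample Pearson correlation of per-condition means.

    ``n`` is the number of conditions, not replicates.  The optional t-based
    two-sided p-value is meaningful only for larger series; with the typical
    n ≤ 5 destabilization sweep it is reported for completeness only.
    """
    if len(series.records) < 2:
        raise UndefinedCorrelationError("need >= 2 records for correlation")
    xv, yv = series.field(x), series.field(y)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError(f"constant field: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return (float(r), float(p)) if with_p_value else float(r)


def classify_instability(
    baseline: MeasurementRecord,
    current: MeasurementRecord,
    size_threshold: float = 0.10,
    conc_threshold: float = 0.10,
) -> InstabilityVerdict:
    """Classify the change from baseline into a physical instability mode.

    A concentration drop beyond ``conc_threshold`` together with a size rise
    beyond ``size_threshold`` indicates fusion/aggregation (fewer, larger
    particles); a concentration drop without the size rise indicates
    degradation (particles disappearing); anything else is called stable.
    Thresholds are strict inequalities, so a change exactly at a threshold
    stays in the milder class.
    """
    if baseline.size_nm <= 0 or baseline.particles_per_ml <= 0:
        raise ValueError("baseline fields must be > 0")
    dsize = current.size_nm / baseline.size_nm - 1.0
    dconc = current.particles_per_ml / baseline.particles_per_ml - 1.0
    if -dconc > conc_threshold:
        status = "aggregation_or_fusion" if dsize > size_threshold else "degradation"
    else:
        status = "stable"
    return InstabilityVerdict(status, dsize, dconc)


@dataclass(frozen=True)
class AuditRow:
    condition_label: str
    product_molecules_per_ml: float
    relative_deviation: float
    passed: bool


def conservation_audit(
    series: StabilitySeries,
    n_molecules_per_ml: float,
    molecules_per_particle_values: Optional[List[float]] = None,
    tolerance: float = 0.05,
) -> List[AuditRow]:
    """Check that molecules/particle × particles/mL recovers total molecules/mL.

    When the excipient amount is constant across the series, every row's
    product must match the formulation's molecules/mL; deviations flag
    inconsistent counting or excipient loss.  If per-row molecules/particle
    values are not supplied they are recomputed from the row's count.
    """
    if n_molecules_per_ml <= 0:
        raise ValueError("molecules_per_ml must be > 0")
    rows = []
    for i, rec in enumerate(series.records):
        if molecules_per_particle_values is not None:
            n_per = molecules_per_particle_values[i]
        else:
            n_per = molecules_per_particle(n_molecules_per_ml, rec.particles_per_ml)
        product = n_per * rec.particles_per_ml
        dev = abs(product - n_molecules_per_ml) / n_molecules_per_ml
        rows.append(AuditRow(rec.condition_label, product, dev, dev <= tolerance))
    return rows
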