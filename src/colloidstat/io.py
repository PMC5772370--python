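"""CSV readers/writers, packaged reference tables, and the combined report.

A series table is a CSV with columns ``condition, size_nm, particles_per_ml``
(mandatory) plus optional ``size_sd_nm, particles_sd, pdi, span``; headers
are matched case-insensitively, extra columns are ignored, and scientific
notation is accepted everywhere.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from .stability import (
    MeasurementRecord,
    StabilitySeries,
    UndefinedCorrelationError,
    classify_instability,
    conservation_audit,
    pearson_correlation,
)
from .stoichiometry import (
    FormulationSpec,
    compute_stoichiometry,
    mass_fraction_to_molarity,
    molecules_per_ml,
)

MANDATORY = {"condition", "size_nm", "particles_per_ml"}
OPTIONAL = {"size_sd_nm", "particles_sd", "pdi", "span"}


class SchemaError(ValueError):
    pass


def read_series(path, ordering_variable: str = "condition") -> StabilitySeries:
    """Read a condition series from CSV, preserving row order."""
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file or missing header")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = MANDATORY - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for col in OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        try:
            records.append(
                MeasurementRecord(
                    condition_label=str(row["condition"]),
                    size_nm=float(row["size_nm"]),
                    particles_per_ml=float(row["particles_per_ml"]),
                    **kwargs,
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return StabilitySeries(records, ordering_variable=ordering_variable)


def write_series(series: StabilitySeries, path) -> None:
    """Write a series back to CSV (12-significant-digit numeric round trip)."""
    rows = []
    for r in series.records:
        rows.append(
            {
                "condition": r.condition_label,
                "size_nm": r.size_nm,
                "particles_per_ml": r.particles_per_ml,
                "size_sd_nm": r.size_sd_nm,
                "particles_sd": r.particles_sd,
                "pdi": r.pdi,
                "span": r.span,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_table1_dppc() -> StabilitySeries:
    """Packaged series: extruded DPPC liposomes under increasing chloroform."""
    with resources.as_file(
        resources.files("colloidstat.data") / "table1_dppc.csv"
    ) as p:
        return read_series(p, ordering_variable="chcl3_ratio")


def load_table2_sln() -> StabilitySeries:
    """Packaged series: cetyl palmitate SLN under decreasing poloxamer 188."""
    with resources.as_file(
        resources.files("colloidstat.data") / "table2_sln.csv"
    ) as p:
        return read_series(p, ordering_variable="pl_percent")


def _published_column(fname: str, column: str) -> list[float]:
    with resources.as_file(resources.files("colloidstat.data") / fname) as p:
        return [float(v) for v in pd.read_csv(p)[column]]


def table1_published_molecules_per_particle() -> list[float]:
    """The DPPC/liposome column as printed (rounded) in the source table."""
    return _published_column("table1_dppc.csv", "molecules_per_particle")


def table2_published_molecules_per_particle() -> list[float]:
    """The CP/SLN column as printed (rounded) in the source table."""
    return _published_column("table2_sln.csv", "molecules_per_particle")


def formulation_from_yaml(path) -> FormulationSpec:
    """Build a FormulationSpec from a YAML config.

    Accepted keys: ``name``; either ``molar_concentration_mM`` or
    ``mass_percent`` + ``molecular_weight``; ``headgroup_area_A2``,
    ``leaflets``, ``architecture``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "molar_concentration_mM" in cfg:
        molar = float(cfg["molar_concentration_mM"]) / 1000.0
    elif "mass_percent" in cfg and "molecular_weight" in cfg:
        molar = mass_fraction_to_molarity(
            float(cfg["mass_percent"]), float(cfg["molecular_weight"])
        )
    else:
        raise SchemaError(
            "config needs molar_concentration_mM or mass_percent+molecular_weight"
        )
    kwargs = dict(
        excipient_name=cfg.get("name", "excipient"),
        molar_concentration=molar,
    )
    if "molecular_weight" in cfg:
        kwargs["molecular_weight"] = float(cfg["molecular_weight"])
    if "headgroup_area_A2" in cfg:
        kwargs["headgroup_area"] = float(cfg["headgroup_area_A2"])
    if "leaflets" in cfg:
        kwargs["leaflets"] = int(cfg["leaflets"])
    if "architecture" in cfg:
        kwargs["architecture"] = cfg["architecture"]
    return FormulationSpec(**kwargs)


def run_report(
    series: StabilitySeries,
    formulation: FormulationSpec,
    audit_tolerance: float = 0.05,
) -> dict:
    """Per-condition stoichiometry, conservation audit, correlation, verdicts.

    Returns a JSON-serialisable dict; ``to_report_frame`` renders the
    per-condition part as a DataFrame.
    """
    n_ml = molecules_per_ml(formulation.molar_concentration)
    conditions = []
    baseline = series.records[0]
    for rec in series.records:
        st = compute_stoichiometry(formulation, rec.particles_per_ml)
        verdict = classify_instability(baseline, rec)
        conditions.append(
            {
                "condition": rec.condition_label,
                "size_nm": rec.size_nm,
                "particles_per_ml": rec.particles_per_ml,
                "molecules_per_particle": st.molecules_per_particle,
                "particle_molarity": st.particle_molarity,
                "verdict": verdict.status,
                "relative_size_change": verdict.relative_size_change,
                "relative_concentration_change": verdict.relative_concentration_change,
            }
        )
    audit = conservation_audit(series, n_ml, tolerance=audit_tolerance)
    try:
        r = pearson_correlation(series)
    except UndefinedCorrelationError:
        r = None
    return {
        "excipient": formulation.excipient_name,
        "molecules_per_ml": n_ml,
        "size_concentration_pearson_r": r,
        "conditions": conditions,
        "conservation_audit": [
            {
                "condition": a.condition_label,
                "product_molecules_per_ml": a.product_molecules_per_ml,
                "relative_deviation": a.relative_deviation,
                "passed": a.passed,
            }
            for a in audit
        ],
    }


def to_report_frame(report: dict) -> pd.DataFrame:
    return pd.DataFrame(report["conditions"])


def report_to_json(report: dict, path: Optional[str] = None) -> str:
    text = json.dumps(report, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
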