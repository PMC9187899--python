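"""SOFA and SIC severity scoring.

Thresholds are data, not code: the component tier tables live in
``data/severity_thresholds.json`` (standard SOFA 0-4 tiers for six organ
systems; the sepsis-induced-coagulopathy score's platelet/INR/SOFA-subtotal
tiers, each 0-2) so a different scoring variant can be swapped in without
touching the code.  All intervals are left-closed, right-open ([lo, hi)),
stated here once and applied uniformly.

The SOFA cardiovascular component scores hypotension from mean arterial
pressure (0-1) or, when a vasopressor tier 1-3 is supplied, 2-4 points.
A missing component contributes 0 points and is flagged, mirroring how
incomplete charts are handled in practice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

_THRESHOLDS = json.loads(
    resources.files("sepsis_phenoscope.data")
    .joinpath("severity_thresholds.json")
    .read_text()
)

SOFA_COMPONENTS = tuple(_THRESHOLDS["sofa"].keys())
#: SOFA components entering the SIC "SOFA subtotal" tier.
SIC_SOFA_COMPONENTS = ("respiration", "cardiovascular", "liver", "renal")


@dataclass
class ScoreBreakdown:
    total: int
    components: dict[str, int]
    missing: tuple[str, ...]


def _lookup(intervals: list, value: float) -> int:
    for lo, hi, points in intervals:
        lo_ok = lo is None or value >= lo
        hi_ok = hi is None or value < hi
        if lo_ok and hi_ok:
            return int(points)
    raise ValueError(f"value {value} not covered by tier table")


def _component_points(name: str, spec: Mapping, panel: Mapping) -> int | None:
    value = panel.get(spec["variable"])
    if name == "cardiovascular":
        tier = panel.get("vasopressor_tier")
        if tier is not None and not _is_missing(tier):
            tier = int(tier)
            if not 1 <= tier <= len(spec["vasopressor_tiers"]):
                raise ValueError(f"vasopressor_tier must be 1..3, got {tier}")
            return int(spec["vasopressor_tiers"][tier - 1])
    if value is None or _is_missing(value):
        return None
    value = float(value)
    if value < 0:
        raise ValueError(f"negative {spec['variable']}: {value}")
    if name == "cns" and not 3 <= value <= 15:
        raise ValueError(f"GCS must be in [3, 15], got {value}")
    return _lookup(spec["intervals"], value)


def _is_missing(v) -> bool:
    return isinstance(v, float) and math.isnan(v)


def sofa_breakdown(panel: Mapping) -> ScoreBreakdown:
    """Per-component SOFA points for one patient panel.

    ``panel`` maps variable names (pao2_fio2, platelets, bilirubin,
    map_mmHg and/or vasopressor_tier, gcs, creatinine) to values.
    """
    comps: dict[str, int] = {}
    missing = []
    for name, spec in _THRESHOLDS["sofa"].items():
        pts = _component_points(name, spec, panel)
        if pts is None:
            missing.append(name)
            pts = 0
        comps[name] = pts
    return ScoreBreakdown(sum(comps.values()), comps, tuple(missing))


def sofa_score(panel: Mapping) -> int:
    """Total SOFA score in [0, 24] (sum of six 0-4 organ tiers)."""
    return sofa_breakdown(panel).total


def sofa_flag_high(score: int) -> bool:
    """High-mortality flag: SOFA strictly above 12 (beyond which observed
    mortality exceeds one half)."""
    if not 0 <= score <= 24:
        raise ValueError(f"SOFA score must be in [0, 24], got {score}")
    return score > 12


def sic_score(panel: Mapping) -> int:
    """Sepsis-induced-coagulopathy score in [0, 6].

    ``panel`` needs platelets (K/uL, linear), inr, and sofa_subtotal (the
    respiration+cardiovascular+liver+renal SOFA points).
    """
    total = 0
    for name, spec in _THRESHOLDS["sic"].items():
        value = panel.get(name)
        if value is None or _is_missing(value):
            raise ValueError(f"SIC panel missing {name!r}")
        value = float(value)
        if value < 0:
            raise ValueError(f"negative {name}: {value}")
        total += _lookup(spec["intervals"], value)
    return total


def score_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``sofa`` and ``sic`` columns to a cohort table.

    Platelets are de-logged from the stored log10 scale; bilirubin,
    creatinine and INR come from the blood-test columns; PaO2/FiO2, MAP
    and GCS from the simulator's organ-panel columns.
    """
    out = table.copy()
    platelets = np.power(10.0, table["Platelet Count (log K/uL)"].to_numpy(dtype=float))
    sofa = np.empty(len(table), dtype=int)
    sic = np.empty(len(table), dtype=int)
    for i, (_, row) in enumerate(table.iterrows()):
        panel = {
            "pao2_fio2": row.get("pao2_fio2"),
            "platelets": platelets[i],
            "bilirubin": row["Bilirubin (IU/L)"],
            "map_mmHg": row.get("map_mmHg"),
            "gcs": row.get("gcs"),
            "creatinine": row["Creatinine (mg/dL)"],
        }
        bd = sofa_breakdown(panel)
        sofa[i] = bd.total
        subtotal = sum(bd.components[c] for c in SIC_SOFA_COMPONENTS)
        sic[i] = sic_score(
            {
                "platelets": platelets[i],
                "inr": row["INR(PT)"],
                "sofa_subtotal": subtotal,
            }
        )
    out["sofa"] = sofa
    out["sic"] = sic
    return out
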