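"""Canonical column names for the sepsis cohort table.

The cohort is a rectangular table of 35 routine blood tests per ICU
admission plus outcome and covariate columns.  Features whose name carries
a ``log`` suffix are stored on the log10 scale, matching how they are
conventionally reported (platelet count ~2.4 means ~250 K/uL).
"""

# The 35 blood-test features, in fixed CSV header order.
FEATURES_35: tuple[str, ...] = (
    "PTT (sec)",
    "Neutrophils (%)",
    "PT (sec)",
    "INR(PT)",
    "Lymphocytes (%)",
    "White Blood Cells (K/uL)",
    "Platelet Count (log K/uL)",
    "MCHC (%)",
    "Albumin (g/dL)",
    "Red Blood Cells (m/uL)",
    "ALT (IU/L)",
    "Alkaline Phosphatase (log IU/L)",
    "Anion Gap (mEq/L)",
    "AST (log IU/L)",
    "Basophils (%)",
    "Bicarbonate (mEq/L)",
    "Bilirubin (IU/L)",
    "Calcium (mg/dL)",
    "Chloride (mEq/L)",
    "Creatinine (mg/dL)",
    "Eosinophils (%)",
    "Glucose (mg/dL)",
    "Hematocrit (%)",
    "Hemoglobin (g/dL)",
    "Lactate (mmol/L)",
    "Magnesium (mg/dL)",
    "MCH (pg)",
    "MCV (fL)",
    "Monocytes (%)",
    "pH (units)",
    "Phosphate (mg/dL)",
    "Potassium (mEq/L)",
    "RDW (%)",
    "Sodium (mEq/L)",
    "Urea Nitrogen (log mg/dL)",
)

# The 11 features of the compact quadratic survival model, in model order
# x_1 .. x_11.
FEATURES_11: tuple[str, ...] = (
    "Creatinine (mg/dL)",
    "Hemoglobin (g/dL)",
    "INR(PT)",
    "Lymphocytes (%)",
    "Neutrophils (%)",
    "Platelet Count (log K/uL)",
    "PTT (sec)",
    "White Blood Cells (K/uL)",
    "Lactate (mmol/L)",
    "Bilirubin (IU/L)",
    "pH (units)",
)

# Features stored on a log10 scale (generated and profiled on that scale).
LOG_SCALE_FEATURES: frozenset[str] = frozenset(
    {
        "Platelet Count (log K/uL)",
        "Alkaline Phosphatase (log IU/L)",
        "AST (log IU/L)",
        "Urea Nitrogen (log mg/dL)",
    }
)

# Percent-scale features, bounded to [0, 100].
PERCENT_FEATURES: frozenset[str] = frozenset(
    {
        "Neutrophils (%)",
        "Lymphocytes (%)",
        "MCHC (%)",
        "Basophils (%)",
        "Eosinophils (%)",
        "Hematocrit (%)",
        "Monocytes (%)",
        "RDW (%)",
    }
)

# Outcome / covariate columns, appended after the 35 features in the CSV.
OUTCOME_COLUMNS: tuple[str, ...] = (
    "survived_28d",
    "time_days",
    "event",
    "heparin",
    "age",
    "sex",
    "true_cluster",
)

# Auxiliary organ-panel columns emitted by the simulator for severity
# scoring (not part of the 35 clustered blood tests).
PANEL_COLUMNS: tuple[str, ...] = ("pao2_fio2", "map_mmHg", "gcs")

CLUSTERS: tuple[str, ...] = ("C1", "C2", "C3", "C4")
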