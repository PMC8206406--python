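"""Default clinical code vocabularies shared by the generator and the rules engine.

The lab-order CPT codes and the glucose / HbA1c LOINC codes are the ones the
eMERGE type 2 diabetes algorithms key on.  ICD-9-CM diabetes codes follow the
standard fifth-digit convention: 250.x0 / 250.x2 are type 2, 250.x1 / 250.x3
are type 1.  NDC sets are inherently plan-specific (they come from an
ingredient-to-package mapping); the defaults below are synthetic placeholder
package codes emitted by the bundled claims generator, and real analyses
replace them via config.
"""

from __future__ import annotations

# Glucose lab results
FASTING_GLUCOSE_LOINC = frozenset({"1558-6"})
RANDOM_GLUCOSE_LOINC = frozenset({"2339-0", "2345-7"})
GLUCOSE_LOINC = FASTING_GLUCOSE_LOINC | RANDOM_GLUCOSE_LOINC

# Hemoglobin A1c results
HBA1C_LOINC = frozenset({"4548-4", "17856-6", "4549-2", "17855-8"})

# Lab-order procedure codes (glucose panels and HbA1c)
LAB_ORDER_CPT = frozenset({"82947", "80047", "80048", "80053", "80069", "83036"})

# ICD-9-CM diabetes diagnoses by type (fifth digit 0/2 = type 2, 1/3 = type 1)
T2D_DX = frozenset(f"250.{x}{d}" for x in range(10) for d in (0, 2))
T1D_DX = frozenset(f"250.{x}{d}" for x in range(10) for d in (1, 3))

# Depressive-disorder rollup (a standard single-level grouping of ICD-9-CM
# depression codes; editable via config since groupers vary at the margins)
DEPRESSION_DX = frozenset({"296.2", "296.3", "298.0", "300.4", "309.1", "311"})

# Family history of diabetes
FAMILY_HISTORY_DX = frozenset({"V18.0"})

# Synthetic placeholder NDC package codes (see module docstring)
T2D_MED_NDC = frozenset({"60000000101", "60000000102", "60000000103"})
INSULIN_NDC = frozenset({"60000000201", "60000000202"})

# Generic background diagnoses the generator uses for healthcare-contact noise
BACKGROUND_DX = (
    "401.9",   # essential hypertension
    "272.4",   # hyperlipidemia
    "465.9",   # acute URI
    "724.2",   # low back pain
    "530.81",  # GERD
    "244.9",   # hypothyroidism
    "285.9",   # anemia
    "786.50",  # chest pain
    "719.46",  # knee pain
    "780.79",  # malaise and fatigue
)
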