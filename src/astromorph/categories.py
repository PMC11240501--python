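"""Controlled vocabulary for annotation categories and case-level diagnoses.

Astrocytic tumors are graded diffuse astrocytoma (WHO grade II),
anaplastic astrocytoma (grade III) and glioblastoma (grade IV).  ROIs and
patches carry one of five *characteristic pathological feature* labels;
three of them (tumor cell area, necrosis area, microvascular proliferation
area) are glioblastoma hallmarks and map to the glioblastoma diagnosis.
"""

from __future__ import annotations

# Canonical column order for patch-count tables and ratio vectors.
CATEGORIES: tuple[str, ...] = (
    "diffuse_astrocytoma",
    "anaplastic_astrocytoma",
    "gbm_tumor_cell_area",
    "gbm_necrosis_area",
    "gbm_microvascular_proliferation_area",
)

DIAGNOSES: tuple[str, ...] = (
    "diffuse_astrocytoma",
    "anaplastic_astrocytoma",
    "glioblastoma",
)

#: Diagnosis implied by each patch/ROI category (total map — every category
#: names exactly one diagnosis).
CATEGORY_TO_DIAGNOSIS: dict[str, str] = {
    "diffuse_astrocytoma": "diffuse_astrocytoma",
    "anaplastic_astrocytoma": "anaplastic_astrocytoma",
    "gbm_tumor_cell_area": "glioblastoma",
    "gbm_necrosis_area": "glioblastoma",
    "gbm_microvascular_proliferation_area": "glioblastoma",
}

#: WHO grade of the diagnosis a category implies; higher grade wins at the
#: case level.
DIAGNOSIS_GRADE: dict[str, int] = {
    "diffuse_astrocytoma": 2,
    "anaplastic_astrocytoma": 3,
    "glioblastoma": 4,
}


def category_grade(category: str) -> int:
    """WHO grade implied by a patch category."""
    return DIAGNOSIS_GRADE[CATEGORY_TO_DIAGNOSIS[category]]
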