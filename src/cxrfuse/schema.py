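"""Clinical-table column manifest for the post-acute COVID-19 cohort.

The cohort schema mirrors the fields collected at the initial post-COVID
check-up (4--12 weeks after acute onset): demographics, therapy flags,
HRCT findings, persistent symptoms, serology, vaccination, blood count,
spirometry, corticosteroid dose descriptors and the 0--10 radiological
regression score.  Synthetic and real tables share this manifest, so the
two are interchangeable everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

SCHEMA_VERSION = "1.0"

#: Radiological regression score at or above this value counts as
#: significant improvement of the lung damage (scale 0 = immutable state,
#: 10 = complete regression).
IMPROVEMENT_THRESHOLD = 7

TRISTATE_MISSING = "missing"
TRISTATE_VALUES = ("yes", "no", TRISTATE_MISSING)


class ColumnKind(str, Enum):
    ID = "id"
    BINARY = "binary"          # yes/no
    TRISTATE = "tristate"      # yes/no/missing (symptom fields)
    NUMERIC = "numeric"
    INTEGER = "integer"
    SCORE = "score"            # radiological regression score, 0..10
    LABEL = "label"            # optional explicit benefit label


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: ColumnKind
    required: bool = True
    description: str = ""


COLUMNS: tuple[ColumnSpec, ...] = (
    ColumnSpec("patient_id", ColumnKind.ID),
    ColumnSpec("gender", ColumnKind.BINARY, description="1 = male"),
    ColumnSpec("age", ColumnKind.NUMERIC, description="years"),
    ColumnSpec("weight_kg", ColumnKind.NUMERIC),
    ColumnSpec("height_cm", ColumnKind.NUMERIC),
    ColumnSpec("bmi", ColumnKind.NUMERIC),
    # Therapy during the acute phase
    ColumnSpec("hospitalized", ColumnKind.BINARY),
    ColumnSpec("oxygen", ColumnKind.BINARY),
    ColumnSpec("remdesivir", ColumnKind.BINARY),
    ColumnSpec("cs_during_hospitalization", ColumnKind.BINARY),
    ColumnSpec("cs_post_covid", ColumnKind.BINARY),
    ColumnSpec("cs_another_problems", ColumnKind.BINARY,
               description="corticosteroids received for other indications"),
    ColumnSpec("cs_use", ColumnKind.BINARY,
               description="received corticosteroid treatment"),
    # Lung damage on HRCT
    ColumnSpec("hrct_interstitial", ColumnKind.BINARY),
    ColumnSpec("hrct_inflammatory", ColumnKind.BINARY),
    ColumnSpec("pneumonia", ColumnKind.BINARY,
               description="pneumonia during the acute COVID-19 phase"),
    ColumnSpec("comorbidity", ColumnKind.BINARY),
    ColumnSpec("postcovid_disability", ColumnKind.BINARY),
    # Persistent symptoms (tri-state: a handful of N/A entries occur)
    ColumnSpec("dyspnea", ColumnKind.TRISTATE),
    ColumnSpec("cough", ColumnKind.TRISTATE),
    ColumnSpec("fatigue", ColumnKind.TRISTATE),
    ColumnSpec("olfactory_loss", ColumnKind.TRISTATE),
    ColumnSpec("gi_problems", ColumnKind.TRISTATE),
    # Serology and vaccination
    ColumnSpec("igm_qualit", ColumnKind.BINARY, description="1 = positive"),
    ColumnSpec("igm_quant", ColumnKind.NUMERIC,
               description="anti-SARS-CoV-2 IgM level"),
    ColumnSpec("igg_qualit", ColumnKind.BINARY, description="1 = positive"),
    ColumnSpec("vaccination_doses", ColumnKind.INTEGER, description="0..3"),
    # Blood count
    ColumnSpec("ko_rdw", ColumnKind.NUMERIC,
               description="red cell distribution width, %"),
    ColumnSpec("ko_mo_pct", ColumnKind.NUMERIC,
               description="peripheral blood monocytes, %"),
    # Spirometry / diffusing capacity
    ColumnSpec("vc_abs", ColumnKind.NUMERIC, description="vital capacity, L"),
    ColumnSpec("fvc_pct_pred", ColumnKind.NUMERIC,
               description="forced vital capacity, % predicted"),
    ColumnSpec("fev1_abs", ColumnKind.NUMERIC, description="FEV1, L"),
    ColumnSpec("pef_pct_pred", ColumnKind.NUMERIC,
               description="peak expiratory flow, % predicted"),
    ColumnSpec("erv_abs", ColumnKind.NUMERIC,
               description="expiratory reserve volume, L"),
    ColumnSpec("mef25_abs", ColumnKind.NUMERIC,
               description="maximal expiratory flow at 25% VC, L/s"),
    ColumnSpec("dlcoc_abs", ColumnKind.NUMERIC,
               description="CO diffusing capacity, transfer factor"),
    ColumnSpec("kcoc_abs", ColumnKind.NUMERIC,
               description="CO diffusing capacity, transfer coefficient"),
    # Corticosteroid dose descriptors
    ColumnSpec("cs_amount", ColumnKind.NUMERIC,
               description="dose x period of corticosteroids received"),
    ColumnSpec("cs_total", ColumnKind.NUMERIC,
               description="total corticosteroids received"),
    ColumnSpec("cs_duration_weeks", ColumnKind.NUMERIC),
    # Outcome
    ColumnSpec("radiological_score", ColumnKind.SCORE, required=False,
               description="lung-damage regression, 0..10"),
    ColumnSpec("benefit_label", ColumnKind.LABEL, required=False,
               description="1 = patient will benefit from CS treatment"),
)

COLUMN_BY_NAME: dict[str, ColumnSpec] = {c.name: c for c in COLUMNS}

#: Symptom fields to which record-level missingness may apply.
SYMPTOM_COLUMNS: tuple[str, ...] = tuple(
    c.name for c in COLUMNS if c.kind is ColumnKind.TRISTATE
)

#: The curated final feature set (21 features) used for the mixed-data
#: experiments: the union of Shapley-importance picks, k-best picks and a
#: manually curated pneumonia-severity block.
FINAL_FEATURES: tuple[str, ...] = (
    "pneumonia",
    "comorbidity",
    "cs_use",
    "olfactory_loss",
    "postcovid_disability",
    "igg_qualit",
    "igm_quant",
    "cs_amount",
    "cs_total",
    "cs_duration_weeks",
    "ko_rdw",
    "vc_abs",
    "fvc_pct_pred",
    "fev1_abs",
    "ko_mo_pct",
    "pef_pct_pred",
    "dlcoc_abs",
    "kcoc_abs",
    "cough",
    "dyspnea",
    "mef25_abs",
)

#: The 14 finding labels of the public multilabel CXR corpus used for
#: pretraining, in its canonical order.
DISEASE_LABELS: tuple[str, ...] = (
    "Atelectasis", "Cardiomegaly", "Consolidation", "Edema", "Effusion",
    "Emphysema", "Fibrosis", "Hernia", "Infiltration", "Mass", "Nodule",
    "Pleural_Thickening", "Pneumonia", "Pneumothorax",
)


def mandatory_columns() -> tuple[str, ...]:
    return tuple(c.name for c in COLUMNS if c.required)
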