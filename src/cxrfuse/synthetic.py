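"""Synthetic cohort generator: multilabel CXR-like images plus a clinical
table with a known ground-truth benefit label.

The generator emulates the study conditions of a post-acute COVID-19
corticosteroid cohort: 273 patients by default, a roughly balanced
benefit label (132/273 positive), 14 finding labels per image, and a
clinical table following the shared column manifest.  Images are crude
radiograph stand-ins -- two bright elliptical lung fields on a dark
background, one textured blob per active finding at a fixed per-label
location, plus Gaussian noise -- built so that separability is
controllable, not so that they look like radiographs.

The benefit label is drawn from a logistic link on standardized clinical
features, ``P(benefit) = sigmoid(b0 + beta . z)``; it is the *only*
source of label information.  When ``image_effect > 0`` a diffuse
opacity is added inside the lung fields of benefit-positive patients so
that images alone also carry signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from . import schema
from .schema import ColumnKind, COLUMNS, SYMPTOM_COLUMNS

#: Log-odds per standardized clinical feature in the benefit link.
DEFAULT_EFFECTS: dict[str, float] = {
    "cs_amount": 1.2,
    "igm_quant": 0.9,
    "pneumonia": 0.8,
    "erv_abs": -0.6,
    "ko_mo_pct": 0.5,
}

#: (mean, sd, low, high) for numeric fields; means/SDs follow the cohort
#: summary table where printed (age, weight, height), otherwise
#: physiologically plausible defaults.
NUMERIC_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "age": (64.38, 11.18, 30, 90),
    "weight_kg": (88.03, 15.87, 57, 136),
    "height_cm": (170.01, 9.84, 145, 198),
    "igm_quant": (20.0, 15.0, 0.0, 200.0),
    "ko_rdw": (13.5, 1.2, 10.0, 20.0),
    "ko_mo_pct": (8.0, 2.0, 1.0, 20.0),
    "vc_abs": (3.9, 0.9, 1.0, 8.0),
    "fvc_pct_pred": (85.0, 15.0, 30.0, 140.0),
    "fev1_abs": (2.9, 0.7, 0.8, 6.0),
    "pef_pct_pred": (90.0, 20.0, 30.0, 160.0),
    "erv_abs": (1.1, 0.4, 0.1, 3.0),
    "mef25_abs": (1.5, 0.6, 0.1, 5.0),
    "dlcoc_abs": (6.5, 1.8, 1.5, 12.0),
    "kcoc_abs": (1.4, 0.3, 0.5, 2.5),
}

#: Bernoulli prevalence per binary field (cohort table fractions where
#: printed, e.g. hospitalized 222/273).
BINARY_PREVALENCES: dict[str, float] = {
    "gender": 166 / 273,
    "hospitalized": 222 / 273,
    "oxygen": 179 / 273,
    "remdesivir": 222 / 273,
    "cs_during_hospitalization": 99 / 273,
    "cs_post_covid": 92 / 273,
    "cs_another_problems": 42 / 273,
    "cs_use": 0.55,
    "hrct_interstitial": 49 / 273,
    "hrct_inflammatory": 118 / 273,
    "pneumonia": 0.6,
    "comorbidity": 0.5,
    "postcovid_disability": 0.25,
    "igm_qualit": 219 / 273,
    "igg_qualit": 0.9,
}

TRISTATE_PREVALENCES: dict[str, float] = {
    "dyspnea": 188 / 273,
    "cough": 93 / 273,
    "fatigue": 77 / 273,
    "olfactory_loss": 39 / 273,
    "gi_problems": 68 / 273,
}


@dataclass(frozen=True)
class CohortSimParams:
    n_patients: int = 273
    image_size: int = 64
    n_disease_labels: int = 14
    label_prevalences: float | tuple[float, ...] = 0.2
    clinical_effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    image_effect: float = 0.04
    noise_sd: float = 0.05
    missing_rate: float = 0.02
    benefit_prevalence: float = 132 / 273
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 (square images)")
        prevs = self.prevalences()
        if ((prevs < 0) | (prevs > 1)).any():
            raise ValueError("label prevalences must lie in [0, 1]")
        for name, p in (("noise_sd", self.noise_sd),):
            if p < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_rate", "benefit_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for key in self.clinical_effect_sizes:
            if key not in schema.COLUMN_BY_NAME:
                raise ValueError(f"effect-size key {key!r} is not a schema column")
            kind = schema.COLUMN_BY_NAME[key].kind
            if kind in (ColumnKind.ID, ColumnKind.SCORE, ColumnKind.LABEL):
                raise ValueError(f"effect-size key {key!r} has kind {kind}")

    def prevalences(self) -> np.ndarray:
        p = self.label_prevalences
        if np.isscalar(p):
            return np.full(self.n_disease_labels, float(p))
        arr = np.asarray(p, dtype=float)
        if arr.shape != (self.n_disease_labels,):
            raise ValueError("label_prevalences length must equal n_disease_labels")
        return arr


@dataclass
class SyntheticCohort:
    images: np.ndarray          # (n, S, S) in [0, 1]
    masks: np.ndarray           # (n, S, S) bool lung masks
    clinical: pd.DataFrame
    benefit_labels: np.ndarray  # (n,) 0/1
    disease_labels: np.ndarray  # (n, 14) 0/1
    truth: CohortSimParams

    def __post_init__(self) -> None:
        n = len(self.images)
        for name in ("masks", "benefit_labels", "disease_labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from images")
        if len(self.clinical) != n:
            raise ValueError("clinical table length differs from images")


# ------------------------------------------------------------------
# Images
# ------------------------------------------------------------------

def lung_fields(size: int, soft: bool = False) -> np.ndarray:
    """Two elliptical lung fields; boolean mask, or a [0,1] field with a
    bright plateau and a soft rim when ``soft``."""
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    out = np.zeros((size, size))
    for cx in (0.32, 0.68):
        d = ((yy - 0.55) / 0.30) ** 2 + ((xx - cx) / 0.15) ** 2
        out = np.maximum(out, np.clip((1.0 - d) / 0.35, 0.0, 1.0))
    if soft:
        return out
    return out > 0.0


def _label_template(label: int, size: int) -> np.ndarray:
    """Fixed textured blob for one finding label, keyed by label index so
    the geometry is reproducible across cohorts and seeds."""
    rng = np.random.default_rng(10_000 + label)
    cy = 0.35 + 0.4 * rng.random()
    cx = (0.32 if label % 2 == 0 else 0.68) + 0.08 * (rng.random() - 0.5)
    radius = 0.06 + 0.06 * rng.random()
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius ** 2)))
    texture = gaussian_filter(rng.normal(size=(size, size)), sigma=size / 24)
    texture = texture / (np.abs(texture).max() + 1e-12)
    return bump * (0.35 + 0.15 * texture)


def generate_multilabel_images(
        params: CohortSimParams, n: int | None = None,
        rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Images with label-specific blobs; returns (images, disease_labels)."""
    n = params.n_patients if n is None else n
    rng = rng or np.random.default_rng(params.seed)
    size = params.image_size
    prevs = params.prevalences()
    labels = (rng.random((n, params.n_disease_labels)) < prevs).astype(int)

    base = 0.08 + 0.5 * lung_fields(size, soft=True)
    templates = np.stack([_label_template(k, size)
                          for k in range(params.n_disease_labels)])
    images = np.empty((n, size, size))
    for i in range(n):
        img = base.copy()
        active = np.flatnonzero(labels[i])
        if active.size:
            img = img + templates[active].sum(axis=0)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    return images, labels


def apply_benefit_opacity(images: np.ndarray, benefit: np.ndarray,
                          amplitude: float) -> np.ndarray:
    """Add a diffuse intra-lung opacity to benefit-positive images."""
    if amplitude == 0:
        return images
    size = images.shape[-1]
    veil = amplitude * lung_fields(size, soft=True)
    out = images.copy()
    out[benefit.astype(bool)] = np.clip(out[benefit.astype(bool)] + veil, 0, 1)
    return out


# ------------------------------------------------------------------
# Clinical table
# ------------------------------------------------------------------

def _encode_for_link(table: pd.DataFrame, feature: str) -> np.ndarray:
    col = table[feature]
    if schema.COLUMN_BY_NAME[feature].kind is ColumnKind.TRISTATE:
        return (col == "yes").astype(float).to_numpy()
    return col.astype(float).to_numpy()


def generate_clinical_table(
        params: CohortSimParams, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Clinical table per the column manifest plus benefit labels drawn
    from the logistic link on standardized effect features."""
    rng = rng or np.random.default_rng(params.seed)
    n = params.n_patients
    data: dict[str, object] = {"patient_id": [f"P{i:04d}" for i in range(n)]}

    for name, p in BINARY_PREVALENCES.items():
        data[name] = (rng.random(n) < p).astype(int)
    for name, p in TRISTATE_PREVALENCES.items():
        data[name] = np.where(rng.random(n) < p, "yes", "no")
    for name, (mean, sd, lo, hi) in NUMERIC_DISTRIBUTIONS.items():
        data[name] = np.clip(rng.normal(mean, sd, size=n), lo, hi)
    data["bmi"] = np.asarray(data["weight_kg"]) / (
        np.asarray(data["height_cm"]) / 100.0) ** 2
    data["vaccination_doses"] = rng.integers(0, 4, size=n)

    cs_use = np.asarray(data["cs_use"], dtype=float)
    amount = np.clip(rng.normal(1000.0, 400.0, size=n), 50.0, None) * cs_use
    data["cs_amount"] = amount
    data["cs_duration_weeks"] = np.clip(
        rng.normal(8.0, 3.0, size=n), 1.0, None) * cs_use
    data["cs_total"] = amount * np.clip(rng.normal(1.0, 0.1, size=n), 0.5, None)

    table = pd.DataFrame(data)

    # Benefit from the logistic link on standardized effect features.
    eta = np.full(n, logit(params.benefit_prevalence))
    for feature, beta in params.clinical_effect_sizes.items():
        x = _encode_for_link(table, feature)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta = eta + beta * z
    benefit = (rng.random(n) < expit(eta)).astype(int)

    # Radiological regression score consistent with the benefit label:
    # benefit-positive patients mostly land in the improved band (>= 7).
    score = np.where(benefit == 1,
                     np.round(rng.normal(8.0, 1.2, size=n)),
                     np.round(rng.normal(4.0, 1.8, size=n)))
    table["radiological_score"] = np.clip(score, 0, 10).astype(int)
    table["benefit_label"] = benefit

    if params.missing_rate > 0:
        for name in SYMPTOM_COLUMNS:
            hit = rng.random(n) < params.missing_rate
            table.loc[hit, name] = schema.TRISTATE_MISSING

    order = [c.name for c in COLUMNS if c.name in table.columns]
    return table[order], benefit


def generate_cohort(params: CohortSimParams | None = None) -> SyntheticCohort:
    """Compose images and clinical table into one seeded cohort."""
    params = params or CohortSimParams()
    root = np.random.SeedSequence(params.seed)
    img_rng, clin_rng = (np.random.default_rng(s) for s in root.spawn(2))
    images, disease = generate_multilabel_images(params, rng=img_rng)
    clinical, benefit = generate_clinical_table(params, rng=clin_rng)
    images = apply_benefit_opacity(images, benefit, params.image_effect)
    masks = np.broadcast_to(lung_fields(params.image_size),
                            images.shape).copy()
    return SyntheticCohort(images=images, masks=masks, clinical=clinical,
                           benefit_labels=benefit, disease_labels=disease,
                           truth=params)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write PNG images, the clinical CSV, label CSVs and a truth JSON."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    ids = cohort.clinical["patient_id"].tolist()
    for pid, img in zip(ids, cohort.images):
        iio.imwrite(outdir / "images" / f"{pid}.png",
                    (img * 255).astype(np.uint8))
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    pd.DataFrame(cohort.disease_labels,
                 columns=list(schema.DISEASE_LABELS[:cohort.disease_labels.shape[1]]),
                 index=pd.Index(ids, name="patient_id")).to_csv(
        outdir / "disease_labels.csv")
    truth = asdict(cohort.truth)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=float))
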