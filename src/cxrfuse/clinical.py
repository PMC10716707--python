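"""Clinical-table handling: loading/validation, benefit-label derivation
from the radiological regression score, univariate k-best selection, and
assembly of the curated final feature matrix.

The benefit label ("will the patient profit from corticosteroid
treatment") is taken verbatim from an explicit label column when one
exists.  Otherwise it must be derived from the 0--10 radiological
regression score (>= 7 counts as significant improvement) together with
the treatment flags -- and because that mapping encodes clinical
semantics, the caller must supply the rule explicitly; nothing is
invented silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2, f_classif

from . import schema
from .schema import ColumnKind, COLUMN_BY_NAME, FINAL_FEATURES, IMPROVEMENT_THRESHOLD

log = logging.getLogger(__name__)

_TRUE = {"1", "yes", "y", "true", "m", "male", "positive", "pos"}
_FALSE = {"0", "no", "n", "false", "f", "female", "negative", "neg"}
_MISSING = {"", "na", "n/a", "nan", "none", "missing", "?"}


class SchemaError(ValueError):
    pass


class LabelingError(ValueError):
    pass


def _parse_binary(col: pd.Series, name: str) -> pd.Series:
    s = col.astype(str).str.strip().str.lower()
    out = pd.Series(np.nan, index=col.index, dtype=float)
    out[s.isin(_TRUE)] = 1
    out[s.isin(_FALSE)] = 0
    bad = out.isna() & ~s.isin(_MISSING)
    if bad.any():
        raise SchemaError(
            f"column {name!r}: unparseable binary values "
            f"{sorted(s[bad].unique())[:5]}")
    return out.fillna(0).astype(int)


def _parse_tristate(col: pd.Series) -> pd.Series:
    s = col.astype(str).str.strip().str.lower()
    out = pd.Series(schema.TRISTATE_MISSING, index=col.index, dtype=object)
    out[s.isin(_TRUE)] = "yes"
    out[s.isin(_FALSE)] = "no"
    return out


def load_clinical_table(path: str | Path,
                        columns=schema.COLUMNS) -> pd.DataFrame:
    """Load and type a clinical CSV against the column manifest.

    Unknown columns are preserved (and flagged in the log); a missing
    mandatory column or an unparseable numeric cell is an error naming
    the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    known = {c.name for c in columns}
    missing = [c.name for c in columns if c.required and c.name not in raw.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing: {missing}")
    extra = [c for c in raw.columns if c not in known]
    if extra:
        log.warning("unknown columns preserved but unused: %s", extra)

    out = raw.copy()
    for spec in columns:
        if spec.name not in out.columns:
            continue
        col = out[spec.name]
        if spec.kind is ColumnKind.BINARY:
            out[spec.name] = _parse_binary(col, spec.name)
        elif spec.kind is ColumnKind.TRISTATE:
            out[spec.name] = _parse_tristate(col)
        elif spec.kind in (ColumnKind.NUMERIC, ColumnKind.INTEGER,
                           ColumnKind.SCORE, ColumnKind.LABEL):
            parsed = pd.to_numeric(col, errors="coerce")
            bad = parsed.isna() & col.notna() & ~col.astype(str).str.strip().str.lower().isin(_MISSING)
            if bad.any():
                rid = out.loc[bad, "patient_id"].iloc[0] if "patient_id" in out else bad.idxmax()
                raise SchemaError(
                    f"column {spec.name!r}: unparseable numeric value in "
                    f"record {rid!r}")
            out[spec.name] = parsed
    if "radiological_score" in out.columns:
        present = out["radiological_score"].dropna()
        if ((present < 0) | (present > 10)).any():
            raise SchemaError("radiological_score outside 0..10")
    log.info("loaded %d clinical records from %s", len(out), path)
    return out


def derive_improvement(score: int, threshold: int = IMPROVEMENT_THRESHOLD) -> int:
    """1 when the radiological regression score reaches the improvement
    band (default: scores 7--10 improved, 0--6 not)."""
    score = int(score)
    if not 0 <= score <= 10:
        raise ValueError(f"radiological score must lie in 0..10, got {score}")
    return int(score >= threshold)


@dataclass(frozen=True)
class LabelRule:
    """Mapping from (treated, improved) to the benefit label.

    ``treated_column`` names the treatment flag consulted.  The mapping
    must cover all four combinations.
    """
    mapping: dict[tuple[int, int], int]
    treated_column: str = "cs_use"
    threshold: int = IMPROVEMENT_THRESHOLD

    def __post_init__(self) -> None:
        need = {(t, i) for t in (0, 1) for i in (0, 1)}
        if set(self.mapping) != need:
            raise ValueError("rule must map all four (treated, improved) pairs")


#: The counterfactual reading documented with the package: a treated
#: patient benefited iff they improved; an untreated patient would have
#: benefited iff they did not improve spontaneously.  Supplied as a
#: convenience, never applied implicitly.
COUNTERFACTUAL_RULE = LabelRule(mapping={(1, 1): 1, (1, 0): 0,
                                         (0, 1): 0, (0, 0): 1})


def derive_benefit_label(table: pd.DataFrame,
                         rule: LabelRule | None = None) -> np.ndarray:
    """Benefit labels for a table: an explicit ``benefit_label`` column
    wins; otherwise the supplied rule is applied to (treated, improved)."""
    if "benefit_label" in table.columns and table["benefit_label"].notna().all():
        return table["benefit_label"].astype(int).to_numpy()
    if rule is None:
        raise LabelingError(
            "no explicit benefit_label column: supply a LabelRule mapping "
            "(treated, improved) -> benefit; see COUNTERFACTUAL_RULE")
    for col in (rule.treated_column, "radiological_score"):
        if col not in table.columns or table[col].isna().any():
            raise LabelingError(f"label rule needs complete column {col!r}")
    treated = table[rule.treated_column].astype(int).to_numpy()
    improved = np.array([derive_improvement(s, rule.threshold)
                         for s in table["radiological_score"]])
    log.info("benefit labels derived via rule %s on column %r",
             rule.mapping, rule.treated_column)
    return np.array([rule.mapping[(t, i)] for t, i in zip(treated, improved)])


# ------------------------------------------------------------------
# Feature selection
# ------------------------------------------------------------------

def kbest_select(X: pd.DataFrame, y, k: int) -> pd.DataFrame:
    """Univariate scores per feature -- ANOVA F for numeric columns,
    chi-square for binary ones -- ranked by score with a deterministic
    tie-break on column name.  Returns the full scored table with a
    ``selected`` flag on the top k rows.
    """
    if X.isna().any().any():
        raise ValueError("kbest_select requires a complete matrix")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} columns")
    y = np.asarray(y)
    rows = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            rows.append((name, 0.0, 1.0))
            continue
        is_binary = set(np.unique(col)) <= {0.0, 1.0}
        if is_binary:
            score, p = chi2(col.reshape(-1, 1), y)
        else:
            score, p = f_classif(col.reshape(-1, 1), y)
        rows.append((name, float(score[0]), float(p[0])))
    out = pd.DataFrame(rows, columns=["feature", "score", "p_value"])
    out = out.sort_values(["score", "feature"],
                          ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["selected"] = out["rank"] <= k
    return out.reset_index(drop=True)


@dataclass
class FeatureMatrix:
    """Numeric feature matrix with per-column provenance tags."""
    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")

    @property
    def ids(self):
        return self.frame.index

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def subset(self, positions) -> "FeatureMatrix":
        """Row subset by integer position (e.g. a split index array)."""
        return FeatureMatrix(frame=self.frame.iloc[np.asarray(positions)],
                             provenance=dict(self.provenance))


def assemble_final_features(table: pd.DataFrame,
                            manifest=FINAL_FEATURES,
                            missing_indicators: bool = False) -> FeatureMatrix:
    """Encode the curated feature manifest (default: the 21-feature set)
    into a numeric matrix: binary fields to 0/1, tri-state symptoms to
    0/1 with "missing" imputed to "no" (optionally adding a companion
    missing-indicator column), numeric fields passed through.
    """
    manifest = list(manifest)
    if not manifest:
        raise ValueError("empty feature manifest")
    absent = [m for m in manifest if m not in table.columns]
    if absent:
        raise SchemaError(f"manifest feature(s) absent from table: {absent}")

    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for name in manifest:
        spec = COLUMN_BY_NAME.get(name)
        col = table[name]
        if spec is not None and spec.kind is ColumnKind.TRISTATE \
                and col.dtype == object:
            vals = (col == "yes").astype(int).to_numpy()
            if missing_indicators:
                ind = (col == schema.TRISTATE_MISSING).astype(int).to_numpy()
                cols[f"{name}__missing"] = ind
                provenance[f"{name}__missing"] = "clinical"
        else:
            vals = pd.to_numeric(col).to_numpy(dtype=float)
            if np.isnan(vals).any():
                vals = np.where(np.isnan(vals), np.nanmedian(vals), vals)
        cols[name] = vals
        provenance[name] = "clinical"

    ordered = [m for m in manifest if m in cols]
    ordered += [c for c in cols if c not in manifest]
    index = (table["patient_id"] if "patient_id" in table.columns
             else table.index)
    frame = pd.DataFrame({c: cols[c] for c in ordered},
                         index=pd.Index(index, name="patient_id"))
    return FeatureMatrix(frame=frame, provenance=provenance)


def stratified_split(y, test_fraction: float = 0.2, seed: int = 0):
    """Stratified train/test index split (default 80/20); on a cohort of
    273 this yields 218 training and 55 test patients."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(y))
    train, test = train_test_split(idx, test_size=test_fraction,
                                   random_state=seed, stratify=np.asarray(y))
    return np.sort(train), np.sort(test)
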