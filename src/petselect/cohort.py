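"""Cohort data model: patients, feature schema, CSV I/O, group summaries.

A cohort is a table of memory-clinic patients with demographics, APOE e4
carrier status, a neuropsychological battery, quantified-MRI markers,
amyloid-PET results (binary visual read and/or continuous Centiloid), an
appropriate-use-criteria flag, and (for training/reference data) a ground
truth diagnosis among CN (control / subjective cognitive decline), AD
(Alzheimer's dementia), FTD (frontotemporal dementia) and VaD (vascular
dementia).  Missing values are first-class: the classifier downstream
tolerates them, so the data model must round-trip them faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical diagnosis order.  Used everywhere a deterministic tie-break is
#: needed (CN < AD < FTD < VaD).
DIAGNOSES: tuple[str, ...] = ("CN", "AD", "FTD", "VaD")

_LABEL_RANK = {lab: i for i, lab in enumerate(DIAGNOSES)}


def label_sort_key(label: str) -> tuple[int, str]:
    """Sort key putting canonical diagnoses first, in canonical order."""
    return (_LABEL_RANK.get(label, len(DIAGNOSES)), label)


class CohortError(ValueError):
    """Raised for schema violations, range violations and duplicate ids."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one cohort feature.

    Parameters
    ----------
    name : str
        Column name, unique within a cohort.
    kind : {"continuous", "binary"}
        Binary features are stored as 0.0 / 1.0 (NaN = missing).
    category : str
        One of ``demographics``, ``apoe``, ``neuropsychology``, ``mri``,
        ``pet_visual``, ``pet_centiloid`` (free-form for synthetic schemas).
    lower, upper : float or None
        Physical range; enforced at read/validation time on non-missing
        values.  ``strict_lower`` marks an open lower bound (value > lower).
    """

    name: str
    kind: str
    category: str
    lower: float | None = None
    upper: float | None = None
    strict_lower: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise CohortError(f"feature {self.name!r}: unknown kind {self.kind!r}")


DEFAULT_SPECS: tuple[FeatureSpec, ...] = (
    FeatureSpec("age", "continuous", "demographics", 0, 120),
    FeatureSpec("sex", "binary", "demographics"),  # stored as female/male strings
    FeatureSpec("apoe_e4", "binary", "apoe"),
    FeatureSpec("mmse", "continuous", "neuropsychology", 0, 30),
    FeatureSpec("ravlt_learning", "continuous", "neuropsychology", 0, 75),
    FeatureSpec("ravlt_recall", "continuous", "neuropsychology", 0, 15),
    FeatureSpec("fluency_animals", "continuous", "neuropsychology", 0, None),
    FeatureSpec("tmt_a", "continuous", "neuropsychology", 0, None, strict_lower=True),
    FeatureSpec("tmt_b", "continuous", "neuropsychology", 0, None, strict_lower=True),
    FeatureSpec("npi_total", "continuous", "neuropsychology", 0, 144),
    FeatureSpec("cmta_left", "continuous", "mri", 0, 4),
    FeatureSpec("cmta_right", "continuous", "mri", 0, 4),
    FeatureSpec("cgca", "continuous", "mri", 0, 3),
    FeatureSpec("ap_index", "continuous", "mri"),
    FeatureSpec("ad_similarity", "continuous", "mri", 0, 1),
    FeatureSpec("wmh_volume", "continuous", "mri", 0, None),
    FeatureSpec("pet_visual", "binary", "pet_visual"),
    FeatureSpec("centiloid", "continuous", "pet_centiloid"),
)

#: Metadata columns that are not classifier features.
META_COLUMNS: tuple[str, ...] = ("patient_id", "auc_positive", "true_label")

#: Categories excluded from the default classifier feature set.  The
#: classifier trains on APOE, neuropsychology and MRI; demographics are
#: carried in the data model but not used as evidence, and PET enters only
#: through the explicit with-PET configuration.
NON_DEFAULT_CATEGORIES: frozenset[str] = frozenset(
    {"demographics", "pet_visual", "pet_centiloid"}
)

_BINARY_TOKENS = {
    "0": 0.0, "1": 1.0,
    "neg": 0.0, "pos": 1.0,
    "negative": 0.0, "positive": 1.0,
}
_SEX_TOKENS = {"female": "female", "male": "male", "f": "female", "m": "male"}


@dataclass
class PatientRecord:
    """One patient's values, with missingness represented as None/NaN."""

    patient_id: str
    age: float | None = None
    sex: str | None = None
    features: dict[str, float] = field(default_factory=dict)
    pet_visual: float | None = None
    centiloid: float | None = None
    auc_positive: bool | None = None
    true_label: str | None = None


def _as_optional(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return value


@dataclass
class Cohort:
    """A table of patients plus the feature schema describing its columns."""

    data: pd.DataFrame
    specs: tuple[FeatureSpec, ...] = DEFAULT_SPECS

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        df = self.data.reset_index(drop=True).copy()
        if "patient_id" not in df.columns:
            raise CohortError("cohort is missing a patient_id column")
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicate patient_id values: {sorted(set(dup))}")
        for spec in self.specs:
            if spec.name not in df.columns:
                df[spec.name] = np.nan
        for col in META_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.data = df
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for spec in self.specs:
            if spec.name == "sex":
                bad = df["sex"].dropna()
                bad = bad[~bad.isin(["female", "male"])]
                if len(bad):
                    pid = df.loc[bad.index[0], "patient_id"]
                    raise CohortError(
                        f"invalid sex value {bad.iloc[0]!r} in row patient_id={pid}"
                    )
                continue
            col = pd.to_numeric(df[spec.name], errors="coerce")
            present = df[spec.name].notna()
            if (present & col.isna()).any():
                pid = df.loc[(present & col.isna()).idxmax(), "patient_id"]
                raise CohortError(
                    f"non-numeric value in column {spec.name!r}, row patient_id={pid}"
                )
            df[spec.name] = col
            vals = col[col.notna()]
            if spec.kind == "binary":
                bad = vals[~vals.isin([0.0, 1.0])]
                if len(bad):
                    pid = df.loc[bad.index[0], "patient_id"]
                    raise CohortError(
                        f"binary column {spec.name!r} has value {bad.iloc[0]} "
                        f"in row patient_id={pid}"
                    )
                continue
            if spec.lower is not None:
                low = vals < spec.lower if not spec.strict_lower else vals <= spec.lower
                if low.any():
                    pid = df.loc[low[low].index[0], "patient_id"]
                    raise CohortError(
                        f"value {vals[low].iloc[0]} out of range for column "
                        f"{spec.name!r} in row patient_id={pid}"
                    )
            if spec.upper is not None:
                hi = vals > spec.upper
                if hi.any():
                    pid = df.loc[hi[hi].index[0], "patient_id"]
                    raise CohortError(
                        f"value {vals[hi].iloc[0]} out of range for column "
                        f"{spec.name!r} in row patient_id={pid}"
                    )
        labels = df["true_label"].dropna()
        bad = labels[~labels.isin(DIAGNOSES)]
        if len(bad):
            pid = df.loc[bad.index[0], "patient_id"]
            raise CohortError(
                f"unknown diagnosis {bad.iloc[0]!r} in row patient_id={pid}"
            )
        auc = pd.to_numeric(df["auc_positive"], errors="coerce")
        df["auc_positive"] = auc

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data["patient_id"])

    def spec(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def default_features(self) -> list[str]:
        """Classifier feature selection: everything except demographics/PET."""
        return [s.name for s in self.specs if s.category not in NON_DEFAULT_CATEGORIES]

    def binary_features(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "binary" and s.name != "sex"]

    def feature_matrix(self, features: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric feature frame indexed by patient_id.

        ``sex`` (if requested) is encoded as 1.0 = female.
        """
        features = list(features) if features is not None else self.default_features()
        known = {s.name for s in self.specs}
        unknown = [f for f in features if f not in known]
        if unknown:
            raise CohortError(f"unknown features requested: {unknown}")
        out = {}
        for f in features:
            if f == "sex":
                s = self.data["sex"]
                out[f] = np.where(s.isna(), np.nan, (s == "female").astype(float))
            else:
                out[f] = self.data[f].to_numpy(dtype=float)
        return pd.DataFrame(out, index=pd.Index(self.data["patient_id"], name="patient_id"))

    def labels(self) -> pd.Series:
        return pd.Series(
            self.data["true_label"].to_numpy(),
            index=pd.Index(self.data["patient_id"], name="patient_id"),
            name="true_label",
        )

    def record(self, patient_id: str) -> PatientRecord:
        rows = self.data[self.data["patient_id"] == patient_id]
        if not len(rows):
            raise KeyError(patient_id)
        row = rows.iloc[0]
        feats = {
            s.name: row[s.name]
            for s in self.specs
            if s.name not in ("age", "sex", "pet_visual", "centiloid")
            and pd.notna(row[s.name])
        }
        auc = _as_optional(row["auc_positive"])
        return PatientRecord(
            patient_id=patient_id,
            age=_as_optional(row.get("age")),
            sex=_as_optional(row.get("sex")),
            features=feats,
            pet_visual=_as_optional(row.get("pet_visual")),
            centiloid=_as_optional(row.get("centiloid")),
            auc_positive=None if auc is None else bool(auc),
            true_label=_as_optional(row["true_label"]),
        )


# -- CSV I/O ----------------------------------------------------------------

def read_cohort(
    path: str | Path,
    specs: Sequence[FeatureSpec] = DEFAULT_SPECS,
    missing_sentinel: str = "",
) -> Cohort:
    """Read a cohort CSV (comma-separated, UTF-8, header row required).

    Empty cells (or ``missing_sentinel``) become missing values.  Binary
    columns accept {0, 1, neg, pos, negative, positive}; sex accepts
    {female, male, F, M}.  Unknown columns, duplicate patient ids and
    out-of-range values raise :class:`CohortError` naming the offender.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = {s.name for s in specs} | set(META_COLUMNS)
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        raise CohortError(f"unknown columns in {path}: {unknown}")
    if "patient_id" not in raw.columns:
        raise CohortError(f"{path} has no patient_id column")

    def clean(col: pd.Series) -> pd.Series:
        col = col.astype(str).str.strip()
        return col.mask((col == missing_sentinel) | (col == ""), other=np.nan)

    df = pd.DataFrame({"patient_id": raw["patient_id"].astype(str)})
    spec_by_name = {s.name: s for s in specs}
    for c in raw.columns:
        if c == "patient_id":
            continue
        col = clean(raw[c])
        spec = spec_by_name.get(c)
        if spec is not None and spec.name == "sex":
            df[c] = col.str.lower().map(_SEX_TOKENS).where(col.notna())
            bad = col.notna() & df[c].isna()
            if bad.any():
                pid = df.loc[bad.idxmax(), "patient_id"]
                raise CohortError(
                    f"invalid sex value {col[bad].iloc[0]!r} in row patient_id={pid}"
                )
        elif (spec is not None and spec.kind == "binary") or c == "auc_positive":
            mapped = col.str.lower().map(_BINARY_TOKENS)
            bad = col.notna() & mapped.isna()
            if bad.any():
                pid = df.loc[bad.idxmax(), "patient_id"]
                raise CohortError(
                    f"invalid binary value {col[bad].iloc[0]!r} in column {c!r}, "
                    f"row patient_id={pid}"
                )
            df[c] = mapped.astype(float)
        elif c == "true_label":
            df[c] = col
        else:
            # float() is correctly rounded; pandas' fast CSV parser is not,
            # which would break lossless round-trips.
            def parse(v):
                if pd.isna(v):
                    return np.nan
                try:
                    return float(v)
                except ValueError:
                    return None

            parsed = col.map(parse)
            bad = parsed.isna() & col.notna()
            if bad.any():
                pid = df.loc[bad.idxmax(), "patient_id"]
                raise CohortError(
                    f"non-numeric value {col[bad].iloc[0]!r} in column {c!r}, "
                    f"row patient_id={pid}"
                )
            df[c] = parsed.astype(float)
    return Cohort(df, tuple(specs))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips losslessly."""
    df = cohort.data.copy()
    cols = ["patient_id"] + [s.name for s in cohort.specs] + ["auc_positive", "true_label"]
    out = {}
    for c in cols:
        col = df[c]
        spec = next((s for s in cohort.specs if s.name == c), None)
        if c == "sex" or c == "true_label":
            out[c] = col.fillna("")
        elif (spec is not None and spec.kind == "binary") or c == "auc_positive":
            out[c] = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
        elif c == "patient_id":
            out[c] = col
        else:
            out[c] = col.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    pd.DataFrame(out)[cols].to_csv(path, index=False)


# -- group summaries --------------------------------------------------------

def summarize_groups(
    cohort: Cohort,
    grouping: Mapping[str, object] | pd.Series,
) -> pd.DataFrame:
    """Per-group summary table (Table-1 style).

    For each (group, feature): ``n_obs`` non-missing values; continuous
    features report mean and sample SD (ddof=1); binary features report the
    positive count and percentage.  Groups with no observed values for a
    feature get ``n_obs = 0`` and NaN statistics (flagged, not an error).
    ``sex`` is summarised as the female count/percentage.

    Returns a tidy frame with columns
    ``group, feature, kind, n_group, n_obs, mean, sd, count_pos, pct_pos``.
    """
    g = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    ids = cohort.data["patient_id"]
    missing = [pid for pid in ids if pid not in g.index]
    if missing:
        raise CohortError(f"patients without a group assignment: {missing[:5]}")
    assigned = g.loc[ids].to_numpy()

    rows = []
    groups = pd.unique(assigned)
    for grp in groups:
        mask = assigned == grp
        n_group = int(mask.sum())
        for spec in cohort.specs:
            if spec.name == "sex":
                col = cohort.data.loc[mask, "sex"]
                obs = col.dropna()
                pos = int((obs == "female").sum())
                rows.append(
                    dict(group=grp, feature="sex", kind="binary", n_group=n_group,
                         n_obs=len(obs), mean=np.nan, sd=np.nan, count_pos=pos,
                         pct_pos=100 * pos / len(obs) if len(obs) else np.nan)
                )
                continue
            col = cohort.data.loc[mask, spec.name]
            obs = col.dropna().astype(float)
            if spec.kind == "binary":
                pos = int(obs.sum())
                rows.append(
                    dict(group=grp, feature=spec.name, kind="binary",
                         n_group=n_group, n_obs=len(obs), mean=np.nan, sd=np.nan,
                         count_pos=pos,
                         pct_pos=100 * pos / len(obs) if len(obs) else np.nan)
                )
            else:
                rows.append(
                    dict(group=grp, feature=spec.name, kind="continuous",
                         n_group=n_group, n_obs=len(obs),
                         mean=obs.mean() if len(obs) else np.nan,
                         sd=obs.std(ddof=1) if len(obs) > 1 else np.nan,
                         count_pos=np.nan, pct_pos=np.nan)
                )
    return pd.DataFrame(rows)
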