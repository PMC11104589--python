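"""Disease State Index (DSI) classifier.

The DSI is a supervised, pairwise, distribution-comparison classifier for
dementia differential diagnosis.  For every unordered pair of diagnostic
groups (P, N) and every feature, the training values of the two groups form
two empirical distributions.  A patient's value ``x`` is scored by the
misclassification-ratio form

    DSI_f(x) = FN(x) / (FN(x) + FP(x))

where, after orienting the feature so that higher values are more P-like,
``FN(x)`` is the fraction of P training values strictly below ``x`` and
``FP(x)`` the fraction of N training values at or above ``x``.  The score
lives in [0, 1]: 1 means the value sits deep inside the P distribution,
0 deep inside N, 0.5 is uninformative.  Binary features use Laplace-smoothed
group frequencies instead of the ECDF.

Per-feature scores are combined into a composite pairwise DSI by a
relevance-weighted mean, where a feature's relevance is the maximum Youden
index (sensitivity + specificity - 1) achievable by thresholding it on the
training data — features that separate the pair better weigh more, features
that do not separate at all weigh zero.  Features missing for a patient are
simply skipped, which is what makes the classifier tolerant of incomplete
clinical data.

The per-group DSI is the average of the composite values of the three pairs
containing that group (orienting each pair so the group plays the P role;
the reverse orientation is 1 - value).  The predicted diagnosis is the group
with the highest DSI; the margin between the two highest DSI values feeds
the downstream probability-of-correct-class estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, DIAGNOSES, PatientRecord, label_sort_key

__all__ = [
    "FeatureEvidence",
    "PairModel",
    "DSIProfile",
    "DSIClassifier",
    "fit_feature_evidence",
    "youden_relevance",
    "feature_dsi",
    "feature_dsi_batch",
    "composite_pairwise_dsi",
    "weighted_composite",
    "fit_pair_models",
    "dsi_profile",
    "make_folds",
    "cv_profiles",
    "cross_validate",
]


# -- per-feature evidence -----------------------------------------------------

@dataclass
class FeatureEvidence:
    """Fitted evidence for one feature in one ordered pair (P, N).

    ``direction`` is +1 when the P training mean is at least the N training
    mean (so raw values are already P-oriented) and -1 otherwise.  For
    continuous features the oriented, sorted training values of both sides
    are kept; for binary features the Laplace-smoothed (add-one) frequency
    of value 1 on each side.
    """

    name: str
    kind: str  # "continuous" | "binary"
    direction: int
    relevance: float
    p_sorted: np.ndarray | None = None
    n_sorted: np.ndarray | None = None
    p_rate: float | None = None
    n_rate: float | None = None


def youden_relevance(p_vals: np.ndarray, n_vals: np.ndarray, direction: int) -> float:
    """Maximum Youden index over all thresholds, clamped at 0.

    The decision rule is "predict P when the oriented value >= t"; candidate
    thresholds are every distinct training value (the trivial rule scoring 0
    is always available, hence the clamp).  Identical training multisets give
    exactly 0; fully separated ones give exactly 1.
    """
    po = np.sort(direction * np.asarray(p_vals, dtype=float))
    no = np.sort(direction * np.asarray(n_vals, dtype=float))
    ts = np.unique(np.concatenate([po, no]))
    sens = 1.0 - np.searchsorted(po, ts, side="left") / po.size
    spec = np.searchsorted(no, ts, side="left") / no.size
    return float(max(0.0, float(np.max(sens + spec - 1.0))))


def fit_feature_evidence(
    name: str,
    kind: str,
    p_vals: Iterable[float],
    n_vals: Iterable[float],
) -> FeatureEvidence | None:
    """Fit evidence from the non-missing training values of both sides.

    Returns ``None`` when either side has fewer than 2 usable values, in
    which case the feature is dropped from the pair.
    """
    p = np.asarray(list(p_vals), dtype=float)
    n = np.asarray(list(n_vals), dtype=float)
    p = p[~np.isnan(p)]
    n = n[~np.isnan(n)]
    if p.size < 2 or n.size < 2:
        return None
    direction = 1 if p.mean() >= n.mean() else -1
    relevance = youden_relevance(p, n, direction)
    if kind == "binary":
        if not (np.isin(p, (0.0, 1.0)).all() and np.isin(n, (0.0, 1.0)).all()):
            raise ValueError(f"binary feature {name!r} has non 0/1 training values")
        return FeatureEvidence(
            name, kind, direction, relevance,
            p_rate=(p.sum() + 1.0) / (p.size + 2.0),
            n_rate=(n.sum() + 1.0) / (n.size + 2.0),
        )
    return FeatureEvidence(
        name, kind, direction, relevance,
        p_sorted=np.sort(direction * p),
        n_sorted=np.sort(direction * n),
    )


def feature_dsi_batch(ev: FeatureEvidence, x: np.ndarray) -> np.ndarray:
    """Vectorised per-feature DSI; NaN inputs propagate to NaN outputs."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    if not obs.any():
        return out
    if ev.kind == "binary":
        xv = x[obs]
        pp = np.where(xv == 1.0, ev.p_rate, 1.0 - ev.p_rate)
        pn = np.where(xv == 1.0, ev.n_rate, 1.0 - ev.n_rate)
        out[obs] = pp / (pp + pn)
        return out
    xo = ev.direction * x[obs]
    fn = np.searchsorted(ev.p_sorted, xo, side="left") / ev.p_sorted.size
    fp = (ev.n_sorted.size - np.searchsorted(ev.n_sorted, xo, side="left")) / ev.n_sorted.size
    s = fn + fp
    out[obs] = np.where(s == 0.0, 0.5, fn / np.where(s == 0.0, 1.0, s))
    return out


def feature_dsi(ev: FeatureEvidence, x: float) -> float:
    """Per-feature DSI of a single observed value (see module docstring)."""
    if x is None or np.isnan(x):
        raise ValueError("feature_dsi requires a non-missing value")
    return float(feature_dsi_batch(ev, np.asarray([x]))[0])


def weighted_composite(values: Sequence[float], weights: Sequence[float]) -> float | None:
    """Relevance-weighted mean; None when no positive weight remains."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = (w > 0) & ~np.isnan(v)
    if not keep.any():
        return None
    return float(np.sum(w[keep] * v[keep]) / np.sum(w[keep]))


# -- pair models --------------------------------------------------------------

@dataclass
class PairModel:
    """Fitted evidence for one ordered pair of diagnostic groups."""

    p_label: str
    n_label: str
    evidence: dict[str, FeatureEvidence]

    @property
    def pair(self) -> tuple[str, str]:
        return (self.p_label, self.n_label)


def composite_dsi_batch(
    model: PairModel, X: pd.DataFrame, relevance_exponent: float = 1.0
) -> np.ndarray:
    """Composite pairwise DSI for every row of X (NaN where undefined).

    Undefined means no feature that is both observed for the patient and has
    positive relevance in this pair.
    """
    m = len(X)
    num = np.zeros(m)
    den = np.zeros(m)
    for name, ev in model.evidence.items():
        if ev.relevance <= 0.0:
            continue
        if name not in X.columns:
            continue
        vals = feature_dsi_batch(ev, X[name].to_numpy(dtype=float))
        w = ev.relevance ** relevance_exponent
        obs = ~np.isnan(vals)
        num[obs] += w * vals[obs]
        den[obs] += w
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def composite_pairwise_dsi(
    model: PairModel,
    patient: PatientRecord | Mapping[str, float] | pd.Series,
    relevance_exponent: float = 1.0,
) -> float | None:
    """Composite pairwise DSI for one patient; None when undefined."""
    values = _patient_values(patient)
    X = pd.DataFrame([values]) if values else pd.DataFrame(index=[0])
    out = composite_dsi_batch(model, X, relevance_exponent)[0]
    return None if np.isnan(out) else float(out)


def _patient_values(patient) -> dict[str, float]:
    if isinstance(patient, PatientRecord):
        vals = dict(patient.features)
        if patient.pet_visual is not None:
            vals["pet_visual"] = patient.pet_visual
        if patient.centiloid is not None:
            vals["centiloid"] = patient.centiloid
        if patient.age is not None:
            vals["age"] = patient.age
        if patient.sex is not None:
            vals["sex"] = 1.0 if patient.sex == "female" else 0.0
        return vals
    if isinstance(patient, pd.Series):
        return {k: v for k, v in patient.items()}
    return dict(patient)


# -- profiles -----------------------------------------------------------------

@dataclass
class DSIProfile:
    """Per-group DSI values for one patient, plus the decision geometry."""

    patient_id: str
    dsi: dict[str, float]
    top_label: str
    margin: float
    tie_flag: bool


def aggregate_profiles(
    pair_values: Mapping[tuple[str, str], np.ndarray],
    labels: Sequence[str],
    patient_ids: Sequence[str],
) -> pd.DataFrame:
    """Average pairwise composites into per-group DSI values.

    For group g the three pairs containing g contribute, oriented with g in
    the P role (the stored value when g is the pair's P label, 1 - value
    otherwise); pairs undefined for a patient are skipped from the mean.
    Adds ``top_label`` (argmax, canonical-order tie-break), ``margin``
    (difference of the two highest defined DSI values) and ``tie_flag``
    (exact tie at the top).  A patient for whom every pair is undefined
    raises a ValueError.
    """
    m = len(patient_ids)
    cols = {}
    for g in labels:
        stack = []
        for (p, n), vals in pair_values.items():
            if g == p:
                stack.append(vals)
            elif g == n:
                stack.append(1.0 - vals)
        arr = np.vstack(stack)
        with np.errstate(invalid="ignore"):
            counts = (~np.isnan(arr)).sum(axis=0)
            sums = np.nansum(arr, axis=0)
        cols[g] = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    df = pd.DataFrame(cols, index=pd.Index(patient_ids, name="patient_id"))

    A = df.to_numpy()
    valid = ~np.isnan(A)
    dead = ~valid.any(axis=1)
    if dead.any():
        bad = [patient_ids[i] for i in np.flatnonzero(dead)[:5]]
        raise ValueError(f"patient has no usable features: {bad}")
    B = np.where(valid, A, -np.inf)
    top_idx = np.argmax(B, axis=1)  # first max -> canonical-order tie-break
    top = B[np.arange(m), top_idx]
    tie = (B == top[:, None]).sum(axis=1) > 1
    second = np.partition(B, -2, axis=1)[:, -2] if B.shape[1] >= 2 else np.full(m, -np.inf)
    margin = np.where(np.isfinite(second), top - second, 0.0)
    df["top_label"] = [labels[i] for i in top_idx]
    df["margin"] = margin
    df["tie_flag"] = tie
    return df


def _profiles_to_objects(frame: pd.DataFrame, labels: Sequence[str]) -> dict[str, DSIProfile]:
    out = {}
    for pid, row in frame.iterrows():
        out[pid] = DSIProfile(
            patient_id=pid,
            dsi={g: float(row[g]) for g in labels},
            top_label=row["top_label"],
            margin=float(row["margin"]),
            tie_flag=bool(row["tie_flag"]),
        )
    return out


# -- the estimator ------------------------------------------------------------

class DSIClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn style Disease State Index classifier.

    Parameters
    ----------
    features : sequence of str, optional
        Feature columns to use; defaults to every column of the training
        frame.
    binary_features : sequence of str, optional
        Columns treated as binary (Laplace-smoothed frequencies instead of
        the ECDF score).  Auto-detected from the training values
        (all in {0, 1}) when omitted.
    relevance_exponent : float
        Exponent applied to the Youden relevance when weighting features
        (1 = linear weights).

    Attributes
    ----------
    classes_ : ndarray
        Diagnostic labels seen in ``y``, canonical order CN < AD < FTD < VaD.
    pair_models_ : dict[(str, str), PairModel]
        One fitted model per unordered label pair (orientation stored once;
        the reverse orientation is 1 - value).

    Notes
    -----
    ``X`` is a pandas DataFrame with NaN for missing values; missingness is
    handled natively (missing features are skipped, never imputed).
    """

    def __init__(
        self,
        features: Sequence[str] | None = None,
        binary_features: Sequence[str] | None = None,
        relevance_exponent: float = 1.0,
    ):
        self.features = features
        self.binary_features = binary_features
        self.relevance_exponent = relevance_exponent

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "DSIClassifier":
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        if y.isna().any():
            raise ValueError("training labels contain missing values")
        feats = list(self.features) if self.features is not None else list(X.columns)
        missing_cols = [f for f in feats if f not in X.columns]
        if missing_cols:
            raise ValueError(f"training data lacks feature columns: {missing_cols}")
        labels = sorted(pd.unique(y), key=label_sort_key)
        if len(labels) < 2:
            raise ValueError("need at least two diagnostic groups to fit")
        counts = y.value_counts()
        thin = [lab for lab in labels if counts[lab] < 2]
        if thin:
            raise ValueError(f"labels with fewer than 2 training records: {thin}")

        if self.binary_features is not None:
            binary = set(self.binary_features)
        else:
            binary = {
                f for f in feats
                if np.isin(X[f].dropna().to_numpy(dtype=float), (0.0, 1.0)).all()
                and X[f].notna().any()
            }

        self.classes_ = np.asarray(labels, dtype=object)
        self.features_ = feats
        self.binary_features_ = sorted(binary & set(feats))
        self.pair_models_ = {}
        by_label = {lab: X.loc[y == lab] for lab in labels}
        for p_lab, n_lab in combinations(labels, 2):
            evidence = {}
            for f in feats:
                kind = "binary" if f in binary else "continuous"
                ev = fit_feature_evidence(
                    f, kind,
                    by_label[p_lab][f].to_numpy(dtype=float),
                    by_label[n_lab][f].to_numpy(dtype=float),
                )
                if ev is not None:
                    evidence[f] = ev
            self.pair_models_[(p_lab, n_lab)] = PairModel(p_lab, n_lab, evidence)
        return self

    # -- inference ----------------------------------------------------------

    def pair_dsi(self, X: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
        check_is_fitted(self, "pair_models_")
        X = pd.DataFrame(X)
        return {
            pair: composite_dsi_batch(model, X, self.relevance_exponent)
            for pair, model in self.pair_models_.items()
        }

    def profiles_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-group DSI values plus top_label / margin / tie_flag, one row per patient."""
        check_is_fitted(self, "pair_models_")
        X = pd.DataFrame(X)
        ids = list(X.index)
        return aggregate_profiles(self.pair_dsi(X), list(self.classes_), ids)

    def profiles(self, X: pd.DataFrame) -> dict[str, DSIProfile]:
        frame = self.profiles_frame(X)
        return _profiles_to_objects(frame, list(self.classes_))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.profiles_frame(X)["top_label"].to_numpy(dtype=object)


# -- spec-surface wrappers ----------------------------------------------------

def fit_pair_models(
    train: Cohort,
    feature_selection: Sequence[str] | None = None,
    relevance_exponent: float = 1.0,
) -> dict[tuple[str, str], PairModel]:
    """Fit the six pairwise models on a labelled cohort.

    All four diagnostic groups must be present; an absent group raises an
    error naming it.
    """
    y = train.labels()
    if y.isna().any():
        bad = list(y.index[y.isna()][:5])
        raise ValueError(f"training cohort has unlabelled patients: {bad}")
    present = set(y)
    absent = [lab for lab in DIAGNOSES if lab not in present]
    if absent:
        raise ValueError(f"diagnostic group(s) absent from training data: {absent}")
    feats = list(feature_selection) if feature_selection is not None else train.default_features()
    clf = DSIClassifier(
        features=feats,
        binary_features=[f for f in train.binary_features() if f in feats],
        relevance_exponent=relevance_exponent,
    )
    clf.fit(train.feature_matrix(feats), y)
    return clf.pair_models_


def dsi_profile(
    models: Mapping[tuple[str, str], PairModel],
    patient: PatientRecord | Mapping[str, float] | pd.Series,
    relevance_exponent: float = 1.0,
    patient_id: str = "",
) -> DSIProfile:
    """Four-group DSI profile of one patient from fitted pair models."""
    values = _patient_values(patient)
    pid = patient.patient_id if isinstance(patient, PatientRecord) else (patient_id or "patient")
    X = pd.DataFrame([values], index=[pid]) if values else pd.DataFrame(index=[pid])
    labels = sorted({lab for pair in models for lab in pair}, key=label_sort_key)
    pair_vals = {
        m.pair: composite_dsi_batch(m, X, relevance_exponent) for m in models.values()
    }
    frame = aggregate_profiles(pair_vals, labels, [pid])
    return _profiles_to_objects(frame, labels)[pid]


# -- cross-validation ---------------------------------------------------------

def make_folds(labels: pd.Series, k: int, seed: int) -> pd.Series:
    """Deterministic label-stratified fold assignment.

    Within each diagnostic group (canonical order) the members are shuffled
    with the seeded generator and dealt round-robin over the k folds, so
    groups smaller than k are still spread as evenly as possible.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if labels.isna().any():
        bad = list(labels.index[labels.isna()][:5])
        raise ValueError(f"cross-validation requires labels for all patients: {bad}")
    rng = np.random.default_rng(seed)
    folds = pd.Series(-1, index=labels.index, dtype=int)
    for lab in sorted(pd.unique(labels), key=label_sort_key):
        pos = np.flatnonzero((labels == lab).to_numpy())
        rng.shuffle(pos)
        folds.iloc[pos] = np.arange(pos.size) % k
    return folds


def cv_profiles(
    cohort: Cohort,
    features: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
    relevance_exponent: float = 1.0,
) -> pd.DataFrame:
    """Cross-validated DSI profiles for every patient of a labelled cohort.

    Each patient is scored exactly once, by models fitted on the
    complementary folds (the classical 80/20 five-fold protocol when k=5).
    Returns the profile frame in the cohort's row order.
    """
    feats = list(features) if features is not None else cohort.default_features()
    X = cohort.feature_matrix(feats)
    y = cohort.labels()
    folds = make_folds(y, k, seed)
    binary = [f for f in cohort.binary_features() if f in feats]
    parts = []
    for fold in range(k):
        test = folds == fold
        if not test.any():
            continue
        clf = DSIClassifier(
            features=feats, binary_features=binary,
            relevance_exponent=relevance_exponent,
        )
        clf.fit(X.loc[~test], y.loc[~test])
        parts.append(clf.profiles_frame(X.loc[test]))
    out = pd.concat(parts)
    return out.loc[X.index]


def cross_validate(
    cohort: Cohort,
    k: int = 5,
    seed: int = 0,
    feature_selection: Sequence[str] | None = None,
    relevance_exponent: float = 1.0,
) -> dict[str, DSIProfile]:
    """Spec surface over :func:`cv_profiles`: patient_id -> DSIProfile."""
    frame = cv_profiles(cohort, feature_selection, k, seed, relevance_exponent)
    labels = [c for c in frame.columns if c not in ("top_label", "margin", "tie_flag")]
    return _profiles_to_objects(frame, labels)
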