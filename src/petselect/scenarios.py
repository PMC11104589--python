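"""Diagnostic scenarios for ordering amyloid-PET.

Four test-ordering policies are compared on a cohort, all using the same
certainty rule: a patient counts as diagnosed when the probability of
correct class (PCC) of their DSI profile reaches the cutoff tau (0.75 by
default, the headline compromise between yield and accuracy).

* **Scenario A — computer-supported selection.**  Step 1: if the PCC based
  on APOE, neuropsychology and MRI alone reaches tau, diagnose directly
  (group 1).  Step 2: otherwise re-score the patient twice with a
  *hypothetical* positive and a hypothetical negative amyloid-PET result
  added; if neither hypothetical PCC reaches tau, PET cannot help — no scan,
  follow-up advised (group 2).  Step 3: otherwise the scan is performed and
  the actual result added; reaching tau diagnoses the patient (group 3),
  failing leaves them undiagnosed despite PET (group 4).
* **Scenario B — no PET.**  The baseline tau test only; no scans.
* **Scenario C — appropriate-use criteria.**  Patients flagged AUC-positive
  receive PET and are tested with it; AUC-negative patients get the
  baseline test.
* **Scenario D — PET for all.**  Every patient is scanned and tested with
  PET included.

The hypothetical PET values are the two faces of the biomarker: for visual
reads simply positive/negative; for Centiloids the mean AD value (69.40)
and the mean control value (11.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort, DIAGNOSES, PatientRecord
from .dsi import DSIClassifier, DSIProfile, make_folds, _profiles_to_objects
from .pcc import ReferenceDB, build_reference

__all__ = [
    "PetMode",
    "StageResult",
    "PatientDecision",
    "ScenarioResult",
    "PatientEvaluator",
    "PetUnavailableError",
    "decide_pet",
    "classify_auc",
    "DecisionEngine",
    "run_scenario",
    "sweep_cutoffs",
]

SCENARIOS = ("A", "B", "C", "D")

#: Hypothetical Centiloid values: group means of AD patients (positive face)
#: and controls (negative face).
CENTILOID_HYPOTHETICAL_POSITIVE = 69.40
CENTILOID_HYPOTHETICAL_NEGATIVE = 11.95


class PetUnavailableError(RuntimeError):
    """PET is advised by the decision flow but the actual result is missing."""


@dataclass(frozen=True)
class PetMode:
    """Which amyloid-PET measure is used, and its two hypothetical faces."""

    kind: str  # "visual_read" | "centiloid"
    positive_value: float
    negative_value: float

    @property
    def feature_name(self) -> str:
        return "pet_visual" if self.kind == "visual_read" else "centiloid"

    @classmethod
    def visual_read(cls) -> "PetMode":
        return cls("visual_read", 1.0, 0.0)

    @classmethod
    def centiloid(
        cls,
        positive_value: float = CENTILOID_HYPOTHETICAL_POSITIVE,
        negative_value: float = CENTILOID_HYPOTHETICAL_NEGATIVE,
    ) -> "PetMode":
        return cls("centiloid", positive_value, negative_value)


@dataclass
class StageResult:
    """Profile and PCC of one evaluation stage."""

    profile: DSIProfile
    pcc: float


@dataclass
class PatientDecision:
    """Outcome of the decision flow for one patient.

    Group semantics: 1 = directly certain (no PET), 2 = PET not useful
    (no PET, undiagnosed), 3 = PET helpful (scanned, diagnosed),
    4 = not diagnosed despite PET.
    """

    patient_id: str
    group: int
    pet_performed: bool
    diagnosed: bool
    final_label: str | None
    pcc_baseline: float
    pcc_final: float
    pcc_hyp_pos: float | None = None
    pcc_hyp_neg: float | None = None

    def __post_init__(self) -> None:
        consistent = {
            1: (False, True),
            2: (False, False),
            3: (True, True),
            4: (True, False),
        }[self.group]
        if (self.pet_performed, self.diagnosed) != consistent:
            raise ValueError(
                f"inconsistent decision for {self.patient_id}: group {self.group} "
                f"with pet={self.pet_performed}, diagnosed={self.diagnosed}"
            )


@dataclass
class ScenarioResult:
    """Per-scenario tallies plus the individual decisions."""

    scenario: str
    tau: float
    n: int
    n_diagnosed: int
    n_pet: int
    n_correct: int
    decisions: list[PatientDecision]

    @property
    def group_counts(self) -> dict[int, int]:
        counts = {1: 0, 2: 0, 3: 0, 4: 0}
        for d in self.decisions:
            counts[d.group] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "tau": self.tau,
            "n": self.n,
            "n_diagnosed": self.n_diagnosed,
            "n_pet": self.n_pet,
            "n_correct": self.n_correct,
            "group_counts": {str(k): v for k, v in self.group_counts.items()},
        }


# -- per-patient evaluation -----------------------------------------------------

class PatientEvaluator:
    """Lazy, cached evaluator of one patient under the feature configurations.

    Stages: ``baseline`` (APOE + neuropsychology + MRI), ``hyp_pos`` /
    ``hyp_neg`` (PET feature overridden by the hypothetical values),
    ``actual`` (the observed PET result).  Each stage is computed at most
    once; the set of executed stages drives the per-patient report.
    """

    def __init__(
        self,
        patient_id: str,
        row: pd.Series,
        clf_baseline: DSIClassifier,
        clf_pet: DSIClassifier,
        db_baseline: ReferenceDB,
        db_pet: ReferenceDB,
        mode: PetMode,
        auc_positive: bool | None = None,
        true_label: str | None = None,
    ):
        self.patient_id = patient_id
        self._row = row.astype(float)
        self._clf_baseline = clf_baseline
        self._clf_pet = clf_pet
        self._db_baseline = db_baseline
        self._db_pet = db_pet
        self.mode = mode
        self.auc_positive = auc_positive
        self.true_label = true_label
        self._cache: dict[str, StageResult] = {}

    @property
    def has_pet(self) -> bool:
        v = self._row.get(self.mode.feature_name, np.nan)
        return not pd.isna(v)

    def _stage(self, name: str, clf: DSIClassifier, db: ReferenceDB,
               pet_value: float | None) -> StageResult:
        if name not in self._cache:
            row = self._row.copy()
            if pet_value is not None:
                row[self.mode.feature_name] = pet_value
            X = row.to_frame().T
            X.index = [self.patient_id]
            profile = clf.profiles(X)[self.patient_id]
            self._cache[name] = StageResult(profile, db.pcc_of_profile(profile))
        return self._cache[name]

    def baseline(self) -> StageResult:
        return self._stage("baseline", self._clf_baseline, self._db_baseline, None)

    def hypothetical(self, positive: bool) -> StageResult:
        value = self.mode.positive_value if positive else self.mode.negative_value
        return self._stage("hyp_pos" if positive else "hyp_neg",
                           self._clf_pet, self._db_pet, value)

    def actual(self) -> StageResult:
        if not self.has_pet:
            raise PetUnavailableError(
                f"PET advised but unavailable for patient {self.patient_id}"
            )
        return self._stage("actual", self._clf_pet, self._db_pet, None)

    def executed_stages(self) -> list[str]:
        order = ("baseline", "hyp_pos", "hyp_neg", "actual")
        return [s for s in order if s in self._cache]


def decide_pet(evaluator: PatientEvaluator, tau: float = 0.75) -> PatientDecision:
    """Three-step computer-supported decision flow (scenario A) for one patient.

    Step 1: PCC on APOE/neuropsychology/MRI >= tau -> diagnose directly.
    Step 2: otherwise score both hypothetical PET faces; if neither reaches
    tau the scan cannot create certainty -> no PET.  Step 3: otherwise the
    scan is performed and the actual result decides.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    base = evaluator.baseline()
    if base.pcc >= tau:
        return PatientDecision(
            patient_id=evaluator.patient_id, group=1, pet_performed=False,
            diagnosed=True, final_label=base.profile.top_label,
            pcc_baseline=base.pcc, pcc_final=base.pcc,
        )
    hyp_pos = evaluator.hypothetical(True)
    hyp_neg = evaluator.hypothetical(False)
    if max(hyp_pos.pcc, hyp_neg.pcc) < tau:
        return PatientDecision(
            patient_id=evaluator.patient_id, group=2, pet_performed=False,
            diagnosed=False, final_label=None,
            pcc_baseline=base.pcc, pcc_final=base.pcc,
            pcc_hyp_pos=hyp_pos.pcc, pcc_hyp_neg=hyp_neg.pcc,
        )
    actual = evaluator.actual()
    diagnosed = actual.pcc >= tau
    return PatientDecision(
        patient_id=evaluator.patient_id, group=3 if diagnosed else 4,
        pet_performed=True, diagnosed=diagnosed,
        final_label=actual.profile.top_label if diagnosed else None,
        pcc_baseline=base.pcc, pcc_final=actual.pcc,
        pcc_hyp_pos=hyp_pos.pcc, pcc_hyp_neg=hyp_neg.pcc,
    )


def classify_auc(
    patient: PatientRecord,
    ad_possibility: float,
    ad_confidence: float,
) -> bool:
    """Appropriate-use-criteria flag from pre-PET clinician probabilities.

    Positive when AD is a diagnostic possibility (>= 15%) with confidence in
    an AD diagnosis below 85%, or when the patient is a young-onset (< 65
    years) dementia case.
    """
    for p in (ad_possibility, ad_confidence):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    if patient.age is None:
        raise ValueError("age is required to apply the appropriate-use criteria")
    clause_i = ad_possibility >= 0.15 and ad_confidence < 0.85
    is_dementia = patient.true_label is not None and patient.true_label != "CN"
    clause_ii = patient.age < 65 and is_dementia
    return bool(clause_i or clause_ii)


# -- the engine -------------------------------------------------------------------

class DecisionEngine(BaseEstimator):
    """Fits reference databases and runs the four scenarios on cohorts.

    Parameters
    ----------
    mode : PetMode
        Amyloid-PET measure (visual read by default).
    features : list of str, optional
        Pre-PET feature selection; defaults to the cohort's APOE +
        neuropsychology + MRI features.
    tau : float
        PCC certainty cutoff.
    k : int
        Cross-validation folds (both for reference building and for scoring
        a target cohort).
    k_ref : int
        PCC neighbourhood size.
    seed : int
        Seeds the stratified fold assignment; identical seeds give
        bit-identical results.

    After ``fit(reference_cohort)`` the engine holds one reference database
    per feature configuration (``db_baseline_``, ``db_pet_``) plus
    classifiers trained on the full reference cohort for scoring external
    patients (``clf_baseline_``, ``clf_pet_``).
    """

    def __init__(
        self,
        mode: PetMode | None = None,
        features: Sequence[str] | None = None,
        tau: float = 0.75,
        k: int = 5,
        k_ref: int = 50,
        seed: int = 0,
        relevance_exponent: float = 1.0,
        isotonic: bool = False,
    ):
        self.mode = mode
        self.features = features
        self.tau = tau
        self.k = k
        self.k_ref = k_ref
        self.seed = seed
        self.relevance_exponent = relevance_exponent
        self.isotonic = isotonic

    # -- fitting ---------------------------------------------------------------

    def fit(self, reference_cohort: Cohort) -> "DecisionEngine":
        mode = self.mode or PetMode.visual_read()
        feats = (
            list(self.features)
            if self.features is not None
            else reference_cohort.default_features()
        )
        pet_feats = feats + [mode.feature_name]
        self.mode_ = mode
        self.features_ = feats
        self.pet_features_ = pet_feats
        self.db_baseline_ = build_reference(
            reference_cohort, feats, self.k, self.seed, tag="without_pet",
            k_ref=self.k_ref, isotonic=self.isotonic,
            relevance_exponent=self.relevance_exponent,
        )
        self.db_pet_ = build_reference(
            reference_cohort, pet_feats, self.k, self.seed,
            tag=f"with_{mode.kind}", k_ref=self.k_ref, isotonic=self.isotonic,
            relevance_exponent=self.relevance_exponent,
        )
        binary = reference_cohort.binary_features()
        y = reference_cohort.labels()
        self.clf_baseline_ = DSIClassifier(
            features=feats, binary_features=[f for f in binary if f in feats],
            relevance_exponent=self.relevance_exponent,
        ).fit(reference_cohort.feature_matrix(feats), y)
        self.clf_pet_ = DSIClassifier(
            features=pet_feats, binary_features=[f for f in binary if f in pet_feats],
            relevance_exponent=self.relevance_exponent,
        ).fit(reference_cohort.feature_matrix(pet_feats), y)
        return self

    # -- evaluators --------------------------------------------------------------

    def evaluators(self, cohort: Cohort, cv: bool = True) -> dict[str, PatientEvaluator]:
        """One cached evaluator per patient.

        With ``cv=True`` (the study protocol) the cohort is scored by
        stratified cross-validation within itself: each patient's
        classifiers are fitted on the complementary folds.  With
        ``cv=False`` the reference-fitted classifiers score the cohort
        directly (the clinical situation of a new patient).
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "db_baseline_")
        X = cohort.feature_matrix(self.pet_features_)
        binary = cohort.binary_features()
        auc = cohort.data.set_index("patient_id")["auc_positive"]
        truth = cohort.labels()

        clf_pairs: dict[str, tuple[DSIClassifier, DSIClassifier]] = {}
        if cv:
            y = truth
            folds = make_folds(y, self.k, self.seed)
            for fold in range(self.k):
                test = folds == fold
                if not test.any():
                    continue
                cb = DSIClassifier(
                    features=self.features_,
                    binary_features=[f for f in binary if f in self.features_],
                    relevance_exponent=self.relevance_exponent,
                ).fit(X.loc[~test, self.features_], y.loc[~test])
                cp = DSIClassifier(
                    features=self.pet_features_,
                    binary_features=[f for f in binary if f in self.pet_features_],
                    relevance_exponent=self.relevance_exponent,
                ).fit(X.loc[~test], y.loc[~test])
                for pid in X.index[test]:
                    clf_pairs[pid] = (cb, cp)
        else:
            for pid in X.index:
                clf_pairs[pid] = (self.clf_baseline_, self.clf_pet_)

        out = {}
        for pid in X.index:
            cb, cp = clf_pairs[pid]
            a = auc.get(pid, np.nan)
            t = truth.get(pid, np.nan)
            out[pid] = PatientEvaluator(
                pid, X.loc[pid], cb, cp, self.db_baseline_, self.db_pet_,
                self.mode_,
                auc_positive=None if pd.isna(a) else bool(a),
                true_label=None if pd.isna(t) else t,
            )
        return out

    def evaluate_patient(self, record: PatientRecord) -> PatientEvaluator:
        """Evaluator for an external patient, scored by the reference-fitted models."""
        from .dsi import _patient_values

        values = _patient_values(record)
        row = pd.Series(
            {f: values.get(f, np.nan) for f in self.pet_features_}, dtype=float
        )
        return PatientEvaluator(
            record.patient_id, row, self.clf_baseline_, self.clf_pet_,
            self.db_baseline_, self.db_pet_, self.mode_,
            auc_positive=record.auc_positive, true_label=record.true_label,
        )

    # -- scenarios ----------------------------------------------------------------

    def _decide_one(self, scenario: str, ev: PatientEvaluator, tau: float) -> PatientDecision:
        if scenario == "A":
            return decide_pet(ev, tau)
        if scenario == "B":
            base = ev.baseline()
            diagnosed = base.pcc >= tau
            return PatientDecision(
                patient_id=ev.patient_id, group=1 if diagnosed else 2,
                pet_performed=False, diagnosed=diagnosed,
                final_label=base.profile.top_label if diagnosed else None,
                pcc_baseline=base.pcc, pcc_final=base.pcc,
            )
        if scenario == "C":
            if ev.auc_positive is None:
                raise ValueError(
                    f"scenario C requires auc_positive flags; missing for "
                    f"patient {ev.patient_id}"
                )
            if ev.auc_positive:
                actual = ev.actual()
                base = ev.baseline()
                diagnosed = actual.pcc >= tau
                return PatientDecision(
                    patient_id=ev.patient_id, group=3 if diagnosed else 4,
                    pet_performed=True, diagnosed=diagnosed,
                    final_label=actual.profile.top_label if diagnosed else None,
                    pcc_baseline=base.pcc, pcc_final=actual.pcc,
                )
            base = ev.baseline()
            diagnosed = base.pcc >= tau
            return PatientDecision(
                patient_id=ev.patient_id, group=1 if diagnosed else 2,
                pet_performed=False, diagnosed=diagnosed,
                final_label=base.profile.top_label if diagnosed else None,
                pcc_baseline=base.pcc, pcc_final=base.pcc,
            )
        if scenario == "D":
            actual = ev.actual()
            base = ev.baseline()
            diagnosed = actual.pcc >= tau
            return PatientDecision(
                patient_id=ev.patient_id, group=3 if diagnosed else 4,
                pet_performed=True, diagnosed=diagnosed,
                final_label=actual.profile.top_label if diagnosed else None,
                pcc_baseline=base.pcc, pcc_final=actual.pcc,
            )
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")

    def run_scenario(
        self,
        cohort: Cohort,
        scenario: str,
        tau: float | None = None,
        cv: bool = True,
        evaluators: Mapping[str, PatientEvaluator] | None = None,
    ) -> ScenarioResult:
        """Apply one test-ordering policy to a whole cohort."""
        scenario = scenario.upper()
        tau = self.tau if tau is None else tau
        if scenario == "C":
            auc = cohort.data["auc_positive"]
            missing = list(cohort.data.loc[auc.isna(), "patient_id"])
            if missing:
                raise ValueError(
                    f"scenario C requires auc_positive for all patients; "
                    f"missing: {missing[:10]}"
                )
        evs = evaluators if evaluators is not None else self.evaluators(cohort, cv=cv)
        decisions = [self._decide_one(scenario, evs[pid], tau) for pid in cohort.patient_ids]
        n_correct = sum(
            1 for d in decisions
            if d.diagnosed and evs[d.patient_id].true_label is not None
            and d.final_label == evs[d.patient_id].true_label
        )
        return ScenarioResult(
            scenario=scenario, tau=tau, n=len(decisions),
            n_diagnosed=sum(d.diagnosed for d in decisions),
            n_pet=sum(d.pet_performed for d in decisions),
            n_correct=n_correct, decisions=decisions,
        )

    def sweep_cutoffs(
        self,
        cohort: Cohort,
        scenarios: Sequence[str] = SCENARIOS,
        taus: Sequence[float] | None = None,
        cv: bool = True,
    ) -> pd.DataFrame:
        """Share diagnosed and share scanned per (scenario, tau) over a cutoff grid."""
        if taus is None:
            taus = np.round(np.arange(0.50, 1.0001, 0.01), 2)
        taus = list(taus)
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("taus must be strictly increasing")
        if taus[0] < 0.5 or taus[-1] > 1.0:
            raise ValueError("taus must lie within [0.5, 1.0]")
        evs = self.evaluators(cohort, cv=cv)
        rows = []
        n = len(cohort)
        for scenario in scenarios:
            for tau in taus:
                res = self.run_scenario(cohort, scenario, tau=tau, evaluators=evs)
                rows.append(
                    dict(scenario=scenario, tau=tau,
                         share_diagnosed=res.n_diagnosed / n,
                         share_pet=res.n_pet / n)
                )
        return pd.DataFrame(rows)


# -- thin module-level surface ----------------------------------------------------

def run_scenario(
    cohort: Cohort,
    scenario: str,
    engine: DecisionEngine,
    tau: float | None = None,
    cv: bool = True,
) -> ScenarioResult:
    return engine.run_scenario(cohort, scenario, tau=tau, cv=cv)


def sweep_cutoffs(
    cohort: Cohort,
    engine: DecisionEngine,
    scenarios: Sequence[str] = SCENARIOS,
    taus: Sequence[float] | None = None,
    cv: bool = True,
) -> pd.DataFrame:
    return engine.sweep_cutoffs(cohort, scenarios=scenarios, taus=taus, cv=cv)
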