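"""Synthetic memory-clinic cohort generator.

Generates cohorts whose per-group feature distributions reproduce the
published summary statistics of the study population (group sizes, feature
means and SDs, APOE carrier rates, PET positivity rates, appropriate-use
rates, missingness rates), so every downstream module is testable without
access to the private clinical data.

Continuous features are drawn from truncated normal distributions whose
location parameter is solved so that the *realized* truncated mean equals
the configured group mean (a naive truncated normal with the configured
location would be biased away from the printed mean wherever the bound is
within a couple of SDs, e.g. MMSE 28 +/- 2 truncated at 30).  Binary
attributes (sex, APOE, visual read, AUC flag) are per-group Bernoulli
draws; Centiloid is drawn conditional on the sampled visual read from
read-specific normals whose mixture reproduces the published group
marginal means.  Missingness is applied completely at random afterwards.

What this generator deliberately does *not* model: inter-feature
correlations within a patient (the published table gives no covariances).
Features are sampled independently by default; an optional shared latent
"severity" factor (Gaussian copula, configurable loading) is available for
sensitivity analysis.  Because real cohorts are correlated, headline
proportions measured on synthetic cohorts are not expected to match the
published cohort's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import ndtr

from .cohort import Cohort, DEFAULT_SPECS, DIAGNOSES, FeatureSpec

__all__ = [
    "GroupParams",
    "MissingnessSpec",
    "table1_defaults",
    "load_profile",
    "generate_cohort",
    "make_separable_cohort",
    "reference_composition",
]

#: Published composition of the 770-patient reference database
#: (controls / AD / FTD / VaD).
REFERENCE_COMPOSITION: dict[str, int] = {"CN": 308, "AD": 338, "FTD": 89, "VaD": 35}


@dataclass
class GroupParams:
    """Generator parameters for one diagnostic group."""

    label: str
    n: int
    female_rate: float
    age_mean: float
    age_sd: float
    apoe_rate: float
    features: dict[str, tuple[float, float]]  # name -> (mean, sd)
    pet_positive_rate: float
    centiloid_negative: tuple[float, float]
    centiloid_positive: tuple[float, float]
    auc_positive_rate: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.label}: n must be >= 0")
        for name, rate in (
            ("female_rate", self.female_rate),
            ("apoe_rate", self.apoe_rate),
            ("pet_positive_rate", self.pet_positive_rate),
            ("auc_positive_rate", self.auc_positive_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"group {self.label}: {name} must lie in [0, 1]")
        sds = [self.age_sd, self.centiloid_negative[1], self.centiloid_positive[1]]
        sds += [sd for _, sd in self.features.values()]
        if any(sd < 0 for sd in sds):
            raise ValueError(f"group {self.label}: SDs must be non-negative")


@dataclass
class MissingnessSpec:
    """Per-feature missing-completely-at-random probabilities."""

    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"missingness rate for {name!r} must lie in [0, 1]")

    def rate(self, feature: str) -> float:
        return self.rates.get(feature, 0.0)


# -- profile loading -----------------------------------------------------------

def load_profile(source: str | Path | Mapping) -> tuple[list[GroupParams], MissingnessSpec]:
    """Load generator parameters from a YAML profile (path or parsed mapping)."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    groups = []
    for label, g in raw["groups"].items():
        groups.append(
            GroupParams(
                label=label,
                n=int(g["n"]),
                female_rate=float(g["female_rate"]),
                age_mean=float(g["age"]["mean"]),
                age_sd=float(g["age"]["sd"]),
                apoe_rate=float(g["apoe_e4_rate"]),
                features={
                    name: (float(fv["mean"]), float(fv["sd"]))
                    for name, fv in g["features"].items()
                },
                pet_positive_rate=float(g["pet_positive_rate"]),
                centiloid_negative=(
                    float(g["centiloid_negative"]["mean"]),
                    float(g["centiloid_negative"]["sd"]),
                ),
                centiloid_positive=(
                    float(g["centiloid_positive"]["mean"]),
                    float(g["centiloid_positive"]["sd"]),
                ),
                auc_positive_rate=float(g["auc_positive_rate"]),
            )
        )
    missing = MissingnessSpec({k: float(v) for k, v in raw.get("missingness", {}).items()})
    return groups, missing


def table1_defaults() -> tuple[list[GroupParams], MissingnessSpec]:
    """The packaged default profile (the published study conditions)."""
    text = resources.files("petselect").joinpath("data/table1_defaults.yaml").read_text()
    return load_profile(yaml.safe_load(text))


# -- truncated-normal sampling ---------------------------------------------------

@lru_cache(maxsize=4096)
def _matched_loc(mean: float, sd: float, lower: float, upper: float) -> float:
    """Location parameter whose [lower, upper]-truncated normal has the given mean."""

    def trunc_mean(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    lo, hi = mean - 8.0 * sd, mean + 8.0 * sd
    return float(optimize.brentq(lambda loc: trunc_mean(loc) - mean, lo, hi, xtol=1e-10))


def _sample_feature(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    lower: float | None,
    upper: float | None,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Truncated-normal draw with the realized mean matched to ``mean``.

    ``z`` optionally supplies standard-normal innovations (for the latent
    severity copula); the truncated marginal is preserved by the
    probability-integral transform.
    """
    if z is None:
        z = rng.standard_normal(size)
    if sd == 0.0:
        return np.full(size, mean)
    lo = -np.inf if lower is None else float(lower)
    hi = np.inf if upper is None else float(upper)
    # Bounds further than 8 SDs away are inert; skip the solve.
    if (lo == -np.inf or (mean - lo) / sd > 8.0) and (hi == np.inf or (hi - mean) / sd > 8.0):
        return mean + sd * z
    loc = _matched_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


#: Sign of each feature's loading on the shared severity factor (+1: higher
#: with more severe disease, -1: lower, 0: unrelated).  Only used when
#: ``severity_loading > 0``.
SEVERITY_SIGNS: dict[str, int] = {
    "mmse": -1, "ravlt_learning": -1, "ravlt_recall": -1, "fluency_animals": -1,
    "tmt_a": 1, "tmt_b": 1, "npi_total": 1,
    "cmta_left": 1, "cmta_right": 1, "cgca": 1, "ad_similarity": 1,
    "wmh_volume": 1, "ap_index": 0,
}


# -- main generator ---------------------------------------------------------------

def generate_cohort(
    params: Sequence[GroupParams],
    missing: MissingnessSpec | None = None,
    seed: int = 0,
    severity_loading: float = 0.0,
    id_prefix: str = "P",
) -> Cohort:
    """Generate a synthetic cohort; a pure function of (params, missing, seed).

    Per group: continuous features from mean-matched truncated normals on the
    schema's physical ranges; sex/APOE/visual-read/AUC as independent
    Bernoulli draws; Centiloid conditional on the sampled read; MCAR
    missingness applied afterwards; ``true_label`` recorded.
    """
    if not params:
        raise ValueError("params must be non-empty")
    if not (0.0 <= severity_loading < 1.0):
        raise ValueError("severity_loading must lie in [0, 1)")
    missing = missing or MissingnessSpec()
    rng = np.random.default_rng(seed)
    spec_by_name = {s.name: s for s in DEFAULT_SPECS}

    frames = []
    offset = 0
    for gp in params:
        n = gp.n
        cols: dict[str, np.ndarray | list] = {}
        cols["patient_id"] = [f"{id_prefix}{offset + i + 1:04d}" for i in range(n)]
        offset += n
        severity = rng.standard_normal(n)
        cols["age"] = _sample_feature(rng, gp.age_mean, gp.age_sd, n, 0.0, 120.0)
        cols["sex"] = np.where(rng.random(n) < gp.female_rate, "female", "male")
        cols["apoe_e4"] = (rng.random(n) < gp.apoe_rate).astype(float)
        for name, (mean, sd) in gp.features.items():
            spec = spec_by_name[name]
            lam = severity_loading * SEVERITY_SIGNS.get(name, 0)
            eps = rng.standard_normal(n)
            z = lam * severity + np.sqrt(1.0 - lam**2) * eps
            lower = spec.lower if not spec.strict_lower else spec.lower
            cols[name] = _sample_feature(rng, mean, sd, n, lower, spec.upper, z=z)
        read = (rng.random(n) < gp.pet_positive_rate).astype(float)
        cols["pet_visual"] = read
        cl = np.empty(n)
        neg_mean, neg_sd = gp.centiloid_negative
        pos_mean, pos_sd = gp.centiloid_positive
        noise = rng.standard_normal(n)
        cl = np.where(
            read == 1.0, pos_mean + pos_sd * noise, neg_mean + neg_sd * noise
        )
        cols["centiloid"] = cl
        cols["auc_positive"] = (rng.random(n) < gp.auc_positive_rate).astype(float)
        cols["true_label"] = [gp.label] * n
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)

    # MCAR missingness, applied after generation so it is value-independent.
    for spec in DEFAULT_SPECS:
        p = missing.rate(spec.name)
        if p <= 0.0:
            continue
        drop = rng.random(len(df)) < p
        if spec.name == "sex":
            df.loc[drop, "sex"] = None
        else:
            df.loc[drop, spec.name] = np.nan
    return Cohort(df, DEFAULT_SPECS)


def reference_composition(
    total: Mapping[str, int] | None = None,
) -> list[GroupParams]:
    """Table-1 group parameters re-sized to the published reference-database mix.

    By default: 308 controls, 338 AD, 89 FTD, 35 VaD (770 in total).
    """
    sizes = dict(total or REFERENCE_COMPOSITION)
    groups, _ = table1_defaults()
    out = []
    for gp in groups:
        gp2 = GroupParams(**{**gp.__dict__, "n": int(sizes.get(gp.label, gp.n))})
        out.append(gp2)
    return out


# -- separable fixture cohorts ------------------------------------------------------

SEPARABLE_SPECS: tuple[FeatureSpec, ...] = (
    FeatureSpec("age", "continuous", "demographics", 0, 120),
    FeatureSpec("sex", "binary", "demographics"),
    FeatureSpec("sep_1", "continuous", "synthetic"),
    FeatureSpec("sep_2", "continuous", "synthetic"),
    FeatureSpec("sep_3", "continuous", "synthetic"),
    FeatureSpec("sep_4", "continuous", "synthetic"),
    FeatureSpec("pet_visual", "binary", "pet_visual"),
    FeatureSpec("centiloid", "continuous", "pet_centiloid"),
)


def make_separable_cohort(
    n_per_group: int = 50,
    gap: float = 10.0,
    seed: int = 0,
) -> Cohort:
    """Four-group cohort with group means ``gap`` SDs apart on orthogonal axes.

    Each diagnostic group is shifted by ``gap`` (in units of the common
    unit SD) along its own feature axis; gap 0 means no signal at all, large
    gaps make the groups essentially disjoint.  PET reads, Centiloids and
    AUC flags are present but uninformative (identical across groups), so
    the scenario machinery runs end to end.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for gi, label in enumerate(DIAGNOSES):
        n = n_per_group
        cols: dict[str, np.ndarray | list] = {
            "patient_id": [f"S{gi * n_per_group + i + 1:04d}" for i in range(n)],
            "age": 65.0 + 8.0 * rng.standard_normal(n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "pet_visual": (rng.random(n) < 0.5).astype(float),
            "centiloid": 30.0 + 15.0 * rng.standard_normal(n),
            "auc_positive": (rng.random(n) < 0.5).astype(float),
            "true_label": [label] * n,
        }
        for j in range(4):
            mean = gap if j == gi else 0.0
            cols[f"sep_{j + 1}"] = mean + rng.standard_normal(n)
        frames.append(pd.DataFrame(cols))
    return Cohort(pd.concat(frames, ignore_index=True), SEPARABLE_SPECS)
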