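"""Probability of correct class (PCC) estimation.

A DSI profile compresses a patient's diagnostic evidence into two numbers:
the top DSI value (``dmax``) and the margin between the two highest DSI
values.  Both carry certainty information — a high top value or a wide
margin means the suggested diagnosis is more likely right.  The PCC makes
this operational: in a reference database of previously classified patients
with known ground truth, the cases whose (dmax, margin) geometry is
comparable to the query are looked up and the share of correct diagnoses
among them is the estimated probability that the query's top diagnosis is
correct.

"Comparable" is operationalised as the ``k_ref`` nearest neighbours in
(dmax, margin) space after dividing each coordinate by its reference-set
standard deviation (a coordinate with zero spread is ignored).  The
reference entries themselves come from cross-validated classification of a
labelled reference cohort, so their correctness flags are out-of-sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .cohort import Cohort
from .dsi import DSIProfile, cv_profiles

__all__ = [
    "ReferenceEntry",
    "ReferenceDB",
    "build_reference",
    "estimate_pcc",
    "calibration_report",
    "save_reference",
    "load_reference",
]


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference case: top DSI, margin, and whether the top label was right."""

    dmax: float
    margin: float
    correct: bool


@dataclass
class ReferenceDB:
    """Reference database mapping DSI geometry to empirical correctness.

    Parameters
    ----------
    entries : DataFrame with columns dmax, margin, correct
    tag : str
        The feature configuration the profiles were computed under
        (e.g. ``without_pet``, ``with_visual_read``); one DB per
        configuration, because adding a strong feature shifts the DSI
        geometry.
    k_ref : int
        Neighbourhood size for the PCC lookup (capped at the DB size).
    isotonic : bool
        When True, replace the kNN lookup by a 1-D isotonic regression of
        correctness on margin (monotone smoothing; off by default).
    """

    entries: pd.DataFrame
    tag: str = ""
    k_ref: int = 50
    isotonic: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries).reset_index(drop=True)
        required = {"dmax", "margin", "correct"}
        if set(df.columns) < required:
            raise ValueError(f"reference entries need columns {sorted(required)}")
        if not len(df):
            raise ValueError("reference database is empty")
        for c in ("dmax", "margin"):
            v = df[c].to_numpy(dtype=float)
            if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
                raise ValueError(f"reference column {c!r} must lie in [0, 1]")
        df["correct"] = df["correct"].astype(bool)
        self.entries = df[["dmax", "margin", "correct"]]
        self._iso = None
        if self.isotonic:
            self._iso = IsotonicRegression(
                y_min=0.0, y_max=1.0, increasing=True, out_of_bounds="clip"
            ).fit(self.entries["margin"], self.entries["correct"].astype(float))

    def __len__(self) -> int:
        return len(self.entries)

    # -- queries --------------------------------------------------------------

    def estimate_pcc_batch(self, dmax, margin) -> np.ndarray:
        d = np.asarray(dmax, dtype=float)
        m = np.asarray(margin, dtype=float)
        if d.shape != m.shape:
            raise ValueError("dmax and margin must have matching shapes")
        bad = np.isnan(d) | np.isnan(m) | (d < 0) | (d > 1) | (m < 0) | (m > 1)
        if bad.any():
            raise ValueError("PCC queries require dmax and margin in [0, 1]")
        if self._iso is not None:
            return np.asarray(self._iso.predict(m), dtype=float)
        ref = self.entries[["dmax", "margin"]].to_numpy(dtype=float)
        correct = self.entries["correct"].to_numpy(dtype=float)
        sd = ref.std(axis=0, ddof=0)
        scale = np.where(sd > 0, sd, np.inf)  # zero-SD coordinate drops out
        R = ref / scale
        Q = np.column_stack([d.ravel(), m.ravel()]) / scale
        k = min(self.k_ref, len(ref))
        out = np.empty(len(Q))
        for lo in range(0, len(Q), 512):
            chunk = Q[lo:lo + 512]
            d2 = ((chunk[:, None, :] - R[None, :, :]) ** 2).sum(axis=-1)
            idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
            out[lo:lo + 512] = correct[idx].mean(axis=1)
        return out.reshape(d.shape)

    def estimate_pcc(self, dmax: float, margin: float) -> float:
        return float(self.estimate_pcc_batch(np.asarray([dmax]), np.asarray([margin]))[0])

    def pcc_of_profile(self, profile: DSIProfile) -> float:
        top = max(v for v in profile.dsi.values() if not np.isnan(v))
        return self.estimate_pcc(top, profile.margin)


def estimate_pcc(db: ReferenceDB, dmax: float, margin: float) -> float:
    """Fraction of correct diagnoses among the k_ref comparable reference cases."""
    return db.estimate_pcc(dmax, margin)


# -- building ------------------------------------------------------------------

def build_reference(
    cohort: Cohort,
    feature_selection: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
    tag: str = "",
    k_ref: int = 50,
    isotonic: bool = False,
    relevance_exponent: float = 1.0,
) -> ReferenceDB:
    """Build a reference database by cross-validating a labelled cohort.

    Every patient contributes exactly one entry: the top DSI value and the
    margin of their cross-validated profile, and whether the suggested
    diagnosis matched the ground truth.
    """
    frame = cv_profiles(cohort, feature_selection, k, seed, relevance_exponent)
    labels = [c for c in frame.columns if c not in ("top_label", "margin", "tie_flag")]
    vals = frame[labels].to_numpy(dtype=float)
    dmax = np.nanmax(vals, axis=1)
    truth = cohort.labels().loc[frame.index]
    entries = pd.DataFrame(
        {
            "dmax": dmax,
            "margin": frame["margin"].to_numpy(dtype=float),
            "correct": (frame["top_label"].to_numpy(dtype=object) == truth.to_numpy()),
        }
    )
    return ReferenceDB(entries, tag=tag, k_ref=k_ref, isotonic=isotonic, seed=seed)


# -- calibration ---------------------------------------------------------------

def calibration_report(
    db: ReferenceDB,
    held_out: Iterable[tuple[DSIProfile, str]] | pd.DataFrame,
    bins: int = 10,
) -> pd.DataFrame:
    """Reliability table: binned estimated PCC vs empirical accuracy.

    ``held_out`` is either a list of (profile, true label) pairs or a frame
    with columns dmax, margin, correct.  Rows are equal-width PCC bins (the
    last bin closed at 1.0); empty bins are omitted.
    """
    if isinstance(held_out, pd.DataFrame):
        ho = held_out
        dmax = ho["dmax"].to_numpy(dtype=float)
        margin = ho["margin"].to_numpy(dtype=float)
        correct = ho["correct"].to_numpy(dtype=bool)
    else:
        items = list(held_out)
        if not items:
            raise ValueError("held_out must be non-empty")
        dmax = np.array(
            [max(v for v in p.dsi.values() if not np.isnan(v)) for p, _ in items]
        )
        margin = np.array([p.margin for p, _ in items])
        correct = np.array([p.top_label == truth for p, truth in items])
    if not len(dmax):
        raise ValueError("held_out must be non-empty")
    pcc = db.estimate_pcc_batch(dmax, margin)
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(pcc, edges[1:-1], right=False), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = which == b
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            dict(
                bin_low=edges[b],
                bin_high=edges[b + 1],
                n=n,
                mean_pcc=float(pcc[mask].mean()),
                accuracy=float(correct[mask].mean()),
            )
        )
    return pd.DataFrame(rows)


# -- serialisation -------------------------------------------------------------

def save_reference(db: ReferenceDB, path: str | Path) -> None:
    """Write ``<path>.csv`` (dmax, margin, correct) and a ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".csv" else path
    out = db.entries.copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(base.with_suffix(".csv"), index=False)
    sidecar = {"tag": db.tag, "k_ref": db.k_ref, "isotonic": db.isotonic, "seed": db.seed}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_reference(path: str | Path) -> ReferenceDB:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".csv", ".json") else path
    entries = pd.read_csv(base.with_suffix(".csv"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return ReferenceDB(
        entries,
        tag=meta.get("tag", ""),
        k_ref=int(meta.get("k_ref", 50)),
        isotonic=bool(meta.get("isotonic", False)),
        seed=meta.get("seed"),
    )
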