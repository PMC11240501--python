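"""Case-level diagnosis from per-case patch-prediction counts.

A patch classifier assigns each tile of a case to one of the five
characteristic-pathological-feature categories.  The case-level rule first
converts counts to ratios, then applies an *inclusion criterion* tau: a
category participates in classification only if its patch ratio reaches tau
(for tau = 0, any strictly positive ratio participates).  Among the
participating categories the one implying the highest WHO grade determines
the diagnosis — a single admitted glioblastoma-hallmark category outweighs
any amount of lower-grade tissue.  Raising tau therefore filters out
scant, likely-erroneous predictions and can flip a case back to its
lower-grade diagnosis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .categories import (
    CATEGORIES,
    CATEGORY_TO_DIAGNOSIS,
    DIAGNOSES,
    category_grade,
)

__all__ = [
    "CaseClassification",
    "CaseRatioClassifier",
    "compute_ratios",
    "classify_case",
    "classify_table",
    "load_reference_cohort",
]


@dataclass(frozen=True)
class CaseClassification:
    """Outcome of the inclusion-criterion rule for one case at one tau.

    ``determinant`` is the admitted category of highest implied grade; the
    predicted diagnosis is the diagnosis that category maps to.
    """

    case_id: str
    tau: float
    ratios: tuple[float, ...]
    passing_set: tuple[str, ...]
    determinant: str
    predicted_diagnosis: str
    true_diagnosis: str | None = None

    @property
    def display_ratios(self) -> tuple[float, ...]:
        """Ratios rounded to 3 decimals, the conventional report format."""
        return tuple(float(round(r, 3)) for r in self.ratios)


def compute_ratios(counts) -> np.ndarray:
    """Patch ratios ``count_i / sum(counts)`` for one case.

    Classification always uses the unrounded ratios; rounding to three
    decimals is display-only (see :attr:`CaseClassification.display_ratios`).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(CATEGORIES),):
        raise ValueError(f"expected {len(CATEGORIES)} counts, got shape {counts.shape}")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("case has zero total patch count")
    return counts / total


def _passing_set(ratios: np.ndarray, tau: float) -> list[int]:
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"tau must lie in [0, 1), got {tau}")
    if tau == 0.0:
        # Any predicted ratio participates — but absent categories never do.
        return [i for i, r in enumerate(ratios) if r > 0.0]
    return [i for i, r in enumerate(ratios) if r >= tau]


def classify_case(
    ratios,
    tau: float,
    case_id: str = "",
    true_diagnosis: str | None = None,
) -> CaseClassification:
    """Apply the inclusion-criterion rule to one case's ratio vector.

    The admitted category implying the highest WHO grade decides the
    diagnosis; ties within a grade are broken by the larger ratio (this only
    matters among the three glioblastoma hallmark categories, which map to
    the same diagnosis anyway).  If tau admits no category (possible only
    for tau > 0.2 with five categories), the argmax-ratio category decides.
    """
    ratios = np.asarray(ratios, dtype=float)
    passing = _passing_set(ratios, tau)
    if passing:
        determinant_ix = max(
            passing, key=lambda i: (category_grade(CATEGORIES[i]), ratios[i])
        )
    else:
        determinant_ix = int(np.argmax(ratios))
    determinant = CATEGORIES[determinant_ix]
    return CaseClassification(
        case_id=case_id,
        tau=tau,
        ratios=tuple(ratios),
        passing_set=tuple(CATEGORIES[i] for i in passing),
        determinant=determinant,
        predicted_diagnosis=CATEGORY_TO_DIAGNOSIS[determinant],
        true_diagnosis=true_diagnosis,
    )


class CaseRatioClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based case classifier over 5-column patch-count matrices.

    Parameters
    ----------
    tau : float, default 0.02
        Inclusion criterion: minimum patch ratio a category must reach to be
        considered.  ``tau=0`` admits every strictly positive ratio.

    The rule has no free parameters to estimate; ``fit`` validates input and
    records ``classes_`` so the estimator composes with sklearn metrics and
    model selection (e.g. grid search over ``tau``).
    """

    def __init__(self, tau: float = 0.02):
        self.tau = tau

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(CATEGORIES):
            raise ValueError(f"X must be (n_cases, {len(CATEGORIES)}) counts")
        if not 0.0 <= self.tau < 1.0:
            raise ValueError(f"tau must lie in [0, 1), got {self.tau}")
        if y is not None:
            unknown = set(np.asarray(y, dtype=object)) - set(DIAGNOSES)
            if unknown:
                raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
        self.classes_ = np.asarray(DIAGNOSES, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return np.asarray(
            [classify_case(compute_ratios(row), self.tau).predicted_diagnosis for row in X],
            dtype=object,
        )

    def classify(self, table: pd.DataFrame) -> list[CaseClassification]:
        """Full per-case decision records for a patch-count table."""
        check_is_fitted(self)
        out = []
        for _, row in table.iterrows():
            ratios = compute_ratios(row[list(CATEGORIES)].to_numpy(dtype=float))
            out.append(
                classify_case(
                    ratios,
                    self.tau,
                    case_id=str(row["case_id"]),
                    true_diagnosis=row.get("true_diagnosis"),
                )
            )
        return out


@dataclass
class TableClassification:
    """Decisions, confusion matrix and accuracy for one inclusion criterion."""

    tau: float
    decisions: list[CaseClassification]
    confusion: pd.DataFrame  # rows = true diagnosis, columns = predicted
    accuracy: float = field(init=False)

    def __post_init__(self):
        total = self.confusion.to_numpy().sum()
        self.accuracy = float(np.trace(self.confusion.to_numpy()) / total)


def classify_table(table: pd.DataFrame, taus) -> dict[float, TableClassification]:
    """Classify every case of a patch-count table at each inclusion criterion.

    ``table`` needs columns ``case_id``, ``true_diagnosis`` and the five
    category count columns.  Returns, per tau, the per-case decisions plus a
    true-by-predicted confusion matrix and its accuracy (trace / total).
    """
    unknown = set(table["true_diagnosis"]) - set(DIAGNOSES)
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
    results: dict[float, TableClassification] = {}
    for tau in taus:
        clf = CaseRatioClassifier(tau=tau).fit(
            table[list(CATEGORIES)].to_numpy(dtype=float)
        )
        decisions = clf.classify(table)
        confusion = pd.DataFrame(
            0, index=list(DIAGNOSES), columns=list(DIAGNOSES), dtype=int
        )
        for d in decisions:
            confusion.loc[d.true_diagnosis, d.predicted_diagnosis] += 1
        results[tau] = TableClassification(tau=tau, decisions=decisions, confusion=confusion)
    return results


def load_reference_cohort() -> pd.DataFrame:
    """Packaged nine-case reference cohort of patch-prediction counts.

    Published per-case counts for cases an image-level classifier
    misclassified at one or more inclusion criteria; the fixed point the
    aggregation rule is validated against.
    """
    with importlib.resources.files("astromorph.data").joinpath(
        "reference_cohort.csv"
    ).open() as fh:
        return pd.read_csv(fh)
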