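"""Gating of nuclei into deformation regions and population scoring.

Each nucleus, summarised by its rectangularity deviation R and circle
variance CV, falls into one of five rectangular gates in (R, CV) space:

====== =============================== =================================
Region Bounds (after gap-filling)      Meaning
====== =============================== =================================
R1     R <= 0.1 and CV <= 0.1          no deformation
R2     R <= 0.2 and CV <= 0.2 (\\ R1)   low deformation, more compact
R3     R > 0.2 and CV <= 0.3           low deformation, less compact
R4     R <= 0.2 and CV > 0.2           high deformation, more compact
R5     otherwise                       high deformation, less compact
====== =============================== =================================

Values beyond 0.5 on either axis are clamped to 0.5 before assignment so
extreme shapes stay in the high-deformation gates.  The literal printed
gate bounds leave L-shaped gaps (e.g. R <= 0.2 with 0.2 < CV <= 0.3);
ordered evaluation with the extensions above is the minimal total
partition consistent with the gates' compactness semantics.

A population with region fractions p' (summing to 1) receives the
deformation score

    DS = sum_i  w_i * p'_i,      w_i = i  for i = R1..R5,

so DS is 1 when every nucleus is undeformed and 5 when every nucleus is
extremely deformed.  DS <= 3 classifies the population as Non-Deformed,
DS > 3 as Deformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

REGION_WEIGHTS = {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
GATE_CAP = 0.5
DS_CUTOFF = 3.0

DEFORMED = "Deformed"
NON_DEFORMED = "Non-Deformed"

__all__ = [
    "PopulationProfile",
    "SurfaceSummary",
    "DeformationGater",
    "assign_region",
    "classify_binary",
    "deformation_score",
    "classify_population",
    "population_profile",
    "surface_summary",
    "pc1_projection",
    "confusion_metrics",
    "REGION_WEIGHTS",
    "DS_CUTOFF",
    "DEFORMED",
    "NON_DEFORMED",
]


@dataclass
class PopulationProfile:
    """Region counts, fractions, deformation score and class for one population."""

    counts: np.ndarray  # length-5 integer counts for R1..R5
    p_prime: np.ndarray  # fractions, sums to 1
    ds: float
    n_cells: int
    population_class: str

    def to_dict(self) -> dict:
        return {
            "n_cells": int(self.n_cells),
            "counts": {f"R{i + 1}": int(c) for i, c in enumerate(self.counts)},
            "p_prime": [float(p) for p in self.p_prime],
            "DS": float(self.ds),
            "class": self.population_class,
        }


@dataclass
class SurfaceSummary:
    """Binary deformed/undeformed split of one surface's population."""

    surface_id: str
    n_cells: int
    undeformed_fraction: float
    deformed_fraction: float
    pc1_values: np.ndarray = field(default=None, repr=False)


def assign_region(r, cv) -> np.ndarray | int:
    """Map (R, CV) pairs to gate regions 1-5.  Vectorised; total partition.

    Negative inputs are rejected; values above 0.5 are clamped to 0.5.
    """
    r = np.asarray(r, dtype=float)
    cv = np.asarray(cv, dtype=float)
    if np.any(r < 0) or np.any(cv < 0):
        raise ValueError("R and CV must be non-negative")
    scalar = r.ndim == 0
    r = np.minimum(np.atleast_1d(r), GATE_CAP)
    cv = np.minimum(np.atleast_1d(cv), GATE_CAP)

    region = np.full(r.shape, 5, dtype=int)
    region[(r <= 0.2) & (cv > 0.2)] = 4
    region[(r > 0.2) & (cv <= 0.3)] = 3
    region[(r <= 0.2) & (cv <= 0.2)] = 2
    region[(r <= 0.1) & (cv <= 0.1)] = 1
    return int(region[0]) if scalar else region


def classify_binary(r, cv) -> np.ndarray | str:
    """Per-cell Deformed / Non-Deformed call.

    Non-Deformed iff R <= 0.2 and CV <= 0.2; everything else is Deformed
    (complement rule, so the two classes exhaust the population).
    """
    r = np.asarray(r, dtype=float)
    cv = np.asarray(cv, dtype=float)
    scalar = r.ndim == 0
    nd = (np.atleast_1d(r) <= 0.2) & (np.atleast_1d(cv) <= 0.2)
    out = np.where(nd, NON_DEFORMED, DEFORMED)
    return str(out[0]) if scalar else out


def deformation_score(counts) -> float:
    """Weighted deformation score DS = sum_i w_i p'_i of region counts.

    ``counts`` is a length-5 sequence of per-region cell counts (R1..R5).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (5,):
        raise ValueError("counts must have length 5 (regions R1..R5)")
    n = counts.sum()
    if n < 1:
        raise ValueError("empty population: deformation score undefined")
    p = counts / n
    w = np.arange(1, 6, dtype=float)
    return float(w @ p)


def classify_population(ds: float) -> str:
    """Non-Deformed iff DS <= 3 (boundary inclusive)."""
    return NON_DEFORMED if ds <= DS_CUTOFF else DEFORMED


def population_profile(regions) -> PopulationProfile:
    """Aggregate per-cell region labels (1..5) into a population profile."""
    regions = np.asarray(regions, dtype=int)
    if regions.size == 0:
        raise ValueError("empty population")
    if np.any(regions < 1) or np.any(regions > 5):
        raise ValueError("region labels must be in 1..5")
    counts = np.bincount(regions, minlength=6)[1:6]
    ds = deformation_score(counts)
    return PopulationProfile(
        counts=counts,
        p_prime=counts / counts.sum(),
        ds=ds,
        n_cells=int(counts.sum()),
        population_class=classify_population(ds),
    )


def pc1_projection(r, cv) -> np.ndarray:
    """First principal component of the centered 2-D (R, CV) cloud.

    The component sign is fixed so the CV loading is positive: higher PC1
    means more deformed.  With fewer than 2 cells the projection is zero.
    """
    x = np.column_stack([np.asarray(r, float), np.asarray(cv, float)])
    xc = x - x.mean(axis=0)
    if len(x) < 2:
        return np.zeros(len(x))
    cov = np.cov(xc.T)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    return xc @ v


def surface_summary(features: pd.DataFrame, surface_id: str = "", with_pc1: bool = True) -> SurfaceSummary:
    """Deformed/undeformed fractions (and PC1 values) for one surface.

    ``features`` needs columns ``R`` and ``CV``, one row per cell.
    """
    if len(features) == 0:
        raise ValueError("surface has no cells")
    calls = classify_binary(features["R"].to_numpy(), features["CV"].to_numpy())
    undeformed = float(np.mean(calls == NON_DEFORMED))
    pc1 = pc1_projection(features["R"].to_numpy(), features["CV"].to_numpy()) if with_pc1 else None
    return SurfaceSummary(
        surface_id=surface_id,
        n_cells=len(features),
        undeformed_fraction=undeformed,
        deformed_fraction=1.0 - undeformed,
        pc1_values=pc1,
    )


def confusion_metrics(calls, truth) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) with Deformed as the positive class.

    A metric whose denominator is empty (no positives / no negatives in
    the truth) is reported as None, not zero.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have the same length")
    pos = truth == DEFORMED
    neg = ~pos
    sens = float(np.mean(calls[pos] == DEFORMED)) if pos.any() else None
    spec = float(np.mean(calls[neg] == NON_DEFORMED)) if neg.any() else None
    return sens, spec


class DeformationGater(ClassifierMixin, BaseEstimator):
    """Rule-based gate classifier over (R, CV) features.

    ``predict`` returns the region label 1..5 for each cell;
    ``predict_binary`` the Deformed / Non-Deformed call;
    ``score_population`` aggregates labels into a
    :class:`PopulationProfile`.  The gate bounds are the fixed rubric
    constants, so ``fit`` is a no-op kept for pipeline compatibility.
    """

    def fit(self, X=None, y=None):
        self.classes_ = np.arange(1, 6)
        return self

    @staticmethod
    def _split(X):
        if isinstance(X, pd.DataFrame):
            return X["R"].to_numpy(float), X["CV"].to_numpy(float)
        X = np.asarray(X, dtype=float)
        return X[:, 0], X[:, 1]

    def predict(self, X) -> np.ndarray:
        r, cv = self._split(X)
        return assign_region(r, cv)

    def predict_binary(self, X) -> np.ndarray:
        r, cv = self._split(X)
        return classify_binary(r, cv)

    def score_population(self, X) -> PopulationProfile:
        return population_profile(self.predict(X))
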