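"""Diagnosis variation characteristic (DVC / MK) surface and VUS.

The surface characterizes a diagnostic model's accuracy *and* precision
simultaneously.  For every percentile n = 1..100 of the healthy-control
predicted probabilities (the "upper reference" threshold; the percentile is
equivalent to specificity), each replicate model thresholds its own control
distribution, every patient receives one predicted label per model, and the
diagnostic coefficient of variation at that threshold is the mean over
patients of the CV of their predicted-label vector across models.  Plotting
CV over the (specificity, sensitivity) footprint gives the 3-D surface; its
volume (VUS) is the headline figure of merit — an ideal diagnostic has VUS 0
(labels never waver), so smaller is better.  A clinically usable operating
point is the largest percentile whose CV stays below 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnosis import ReplicateProbabilities

__all__ = ["MKSurface", "percentile_threshold", "labels_and_performance",
           "cv_stat", "build_surface", "vus", "select_threshold"]


@dataclass(frozen=True)
class MKSurface:
    """Per-percentile rows (n = 1..100) plus the scalar volume under surface."""

    percentiles: np.ndarray          # 1..100
    thresholds: np.ndarray           # mean over models of percentile threshold
    specificity: np.ndarray
    mean_sensitivity: np.ndarray
    sensitivity_per_model: np.ndarray  # rows x models
    cv: np.ndarray
    cv_mode: str = "patient_labels"

    def __post_init__(self) -> None:
        n = len(self.percentiles)
        for name in ("thresholds", "specificity", "mean_sensitivity", "cv"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(np.diff(self.thresholds) < -1e-12):
            raise ValueError("thresholds must be non-decreasing in n")
        if np.any(self.cv < 0):
            raise ValueError("cv must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percentile": self.percentiles,
                             "threshold": self.thresholds,
                             "specificity": self.specificity,
                             "sensitivity": self.mean_sensitivity,
                             "cv": self.cv})


def percentile_threshold(control_probs: np.ndarray, n: float) -> float:
    """Empirical nth percentile (linear interpolation) of control probabilities.

    Samples strictly above the returned threshold are called positive.
    """
    control_probs = np.asarray(control_probs, float)
    if control_probs.size == 0:
        raise ValueError("control probabilities must be nonempty")
    if not 1 <= n <= 100:
        raise ValueError("percentile must lie in [1, 100]")
    return float(np.percentile(control_probs, n, method="linear"))


def labels_and_performance(probs: ReplicateProbabilities, n: float,
                           ) -> tuple[np.ndarray, float, np.ndarray]:
    """Apply the nth-percentile threshold in every replicate model.

    Each model m thresholds at the nth percentile of *its own* control
    probabilities; patient labels are (prob > threshold).  Returns the
    per-model sensitivity vector, the specificity (mean over models of the
    control-negative fraction), and the patients x models label matrix.
    """
    thresholds = np.array([percentile_threshold(probs.control_probs[:, m], n)
                           for m in range(probs.n_models)])
    patient_labels = probs.patient_probs > thresholds[None, :]
    sens_per_model = patient_labels.mean(axis=0)
    specificity = float((probs.control_probs <= thresholds[None, :]).mean())
    return sens_per_model, specificity, patient_labels


def cv_stat(values: np.ndarray) -> float:
    """Sample standard deviation divided by mean; an all-zero vector is 0 by
    convention, a zero mean with nonzero spread is undefined."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("cv_stat needs a nonempty vector")
    mean = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if mean == 0:
        if sd == 0:
            return 0.0
        raise ValueError("CV undefined: zero mean with nonzero spread")
    return float(sd / mean)


def _patient_label_cv(patient_labels: np.ndarray) -> float:
    """Mean over patients of the CV of each patient's predicted-label vector."""
    out = []
    for row in patient_labels.astype(float):
        m = row.mean()
        if m == 0:
            out.append(0.0)
        else:
            out.append(row.std(ddof=1) / m)
    return float(np.mean(out)) if out else 0.0


def build_surface(probs: ReplicateProbabilities,
                  cv_mode: str = "patient_labels") -> MKSurface:
    """Scan percentiles 1..100 and assemble the DVC surface.

    ``cv_mode='patient_labels'`` (default): CV at percentile n is the mean
    over patients of the CV of that patient's predicted labels across the
    replicate models.  ``cv_mode='model_sensitivity'``: CV of the per-model
    sensitivities instead.
    """
    if cv_mode not in ("patient_labels", "model_sensitivity"):
        raise ValueError("unknown cv_mode")
    ns = np.arange(1, 101)
    thr, spec, msens, cvs, sens_rows = [], [], [], [], []
    for n in ns:
        sens_m, sp, patient_labels = labels_and_performance(probs, n)
        per_model_thr = [percentile_threshold(probs.control_probs[:, m], n)
                         for m in range(probs.n_models)]
        thr.append(float(np.mean(per_model_thr)))
        spec.append(sp)
        msens.append(float(sens_m.mean()))
        sens_rows.append(sens_m)
        if cv_mode == "patient_labels":
            cvs.append(_patient_label_cv(patient_labels))
        else:
            cvs.append(cv_stat(sens_m) if sens_m.mean() > 0 else 0.0)
    return MKSurface(ns, np.array(thr), np.array(spec), np.array(msens),
                     np.stack(sens_rows), np.array(cvs), cv_mode)


def vus(surface: MKSurface) -> float:
    """Volume under the DVC surface.

    Trapezoidal integration along the percentile sweep of the product
    cv(n) * mean_sensitivity(n) against the specificity increments — the
    volume of the CV sheet over its (specificity, sensitivity) footprint.
    Zero CV everywhere gives exactly 0.
    """
    order = np.argsort(surface.specificity, kind="stable")
    sp = surface.specificity[order]
    if np.any(np.diff(sp) < 0):
        raise ValueError("specificity must be sortable to non-decreasing order")
    z = surface.cv[order] * surface.mean_sensitivity[order]
    return float(np.trapezoid(z, sp))


def select_threshold(surface: MKSurface, cv_max: float = 0.10
                     ) -> tuple[int, float, float] | None:
    """Largest percentile with CV strictly below ``cv_max``.

    Returns (percentile, threshold value, mean sensitivity) or None when no
    percentile qualifies.
    """
    ok = np.flatnonzero(surface.cv < cv_max)
    if len(ok) == 0:
        return None
    k = int(ok[-1])
    return (int(surface.percentiles[k]), float(surface.thresholds[k]),
            float(surface.mean_sensitivity[k]))
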