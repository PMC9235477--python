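"""Hybrid network + sequence scoring for species with a partial PPI map.

When both proteins of a query pair occur in the target species' PPI
network, the network-based GLIDE score and the sequence model's
probability can be fused:

    hybrid(p, q) = GLIDE(p, q) + w * sequence_score(p, q)

with the GLIDE coefficient fixed to 1 (only the relative weight
matters). The weight w is calibrated as the ratio of logistic-regression
coefficients c_seq / c_glide fitted on held-out labelled pairs; the
shipped default w = 0.3268 is the value calibrated on a large held-out
human PPI set and is recommended when no species-specific calibration
data is available. Calibration data must be disjoint from both the
network that produced the GLIDE scores and the sequence model's training
pairs, otherwise w is biased by data leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import CalibrationError, ValidationError

DEFAULT_W = 0.3268

__all__ = ["HybridParams", "CalibrationRecord", "tt_hybrid", "calibrate_w", "DEFAULT_W"]


@dataclass(frozen=True)
class CalibrationRecord:
    """Provenance of a fitted hybrid weight."""

    c_glide: float
    c_seq: float
    intercept: float
    n: int
    n_pos: int
    n_neg: int
    disjointness_attestation: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class HybridParams:
    """The hybrid weight and where it came from."""

    w: float = DEFAULT_W
    provenance: object = "reference-default"

    def __post_init__(self):
        if self.w < 0:
            raise ValidationError(f"hybrid weight w must be >= 0, got {self.w}")


def tt_hybrid(glide_score: float, tt_score: float,
              params: HybridParams | None = None) -> float:
    """Fused score ``glide + w * sequence``; strictly increasing in both
    arguments (for w > 0)."""
    if glide_score is None or (isinstance(glide_score, float) and np.isnan(glide_score)):
        raise ValidationError(
            "GLIDE score unavailable (protein off-network); use the sequence score alone"
        )
    if params is None:
        params = HybridParams()
    return float(glide_score) + params.w * float(tt_score)


def calibrate_w(examples, disjointness_attestation: str = "") -> HybridParams:
    """Fit w = c_seq / c_glide by unregularized logistic regression.

    ``examples`` is an iterable of (glide_score, seq_score, label).
    The fit is maximum likelihood via Newton iterations (an intercept is
    included; it does not enter the coefficient ratio). Regularization
    is deliberately absent: shrinkage would bias the ratio. A
    non-positive GLIDE coefficient leaves w undefined and raises, with
    the fit diagnostics attached.
    """
    rows = [(float(g), float(t), int(y)) for g, t, y in examples]
    if not rows:
        raise ValidationError("no calibration examples")
    X = np.array([[g, t] for g, t, _ in rows])
    y = np.array([lab for _, _, lab in rows])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"need at least 2 examples of each class, got {n_pos} positive / {n_neg} negative"
        )
    if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
        raise ValidationError("scores must not be constant within the calibration set")
    design = sm.add_constant(X, prepend=True)
    fit = sm.Logit(y, design).fit(method="newton", tol=1e-8, maxiter=200, disp=0)
    intercept, c_glide, c_seq = (float(v) for v in fit.params)
    record = CalibrationRecord(
        c_glide=c_glide, c_seq=c_seq, intercept=intercept,
        n=len(rows), n_pos=n_pos, n_neg=n_neg,
        disjointness_attestation=disjointness_attestation,
    )
    if c_glide <= 0:
        raise CalibrationError(
            f"GLIDE coefficient is non-positive ({c_glide:.6g}); "
            "w = c_seq/c_glide is undefined as a ratio over a non-positive denominator",
            diagnostics=record.to_dict(),
        )
    return HybridParams(w=c_seq / c_glide, provenance=record)
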