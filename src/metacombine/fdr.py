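"""q-values: the minimum false discovery rate at which each test is called.

The step-up construction follows Storey: with p-values sorted ascending,

    q_(i) = min_{j >= i}  pi0 * m * p_(j) / j

mapped back to input order.  The null proportion ``pi0`` is estimated with
the fixed-lambda Storey estimator at lambda = 0.5,

    pi0_hat = min(1, #{p > lambda} / ((1 - lambda) * m)),

which is deterministic and adequate at the scale these analyses run
(thousands of tests).  With ``pi0_method="one"`` the estimator is skipped
and the q-values equal Benjamini–Hochberg adjusted p-values exactly.  For
short vectors (m < 100) the lambda estimator is too noisy to trust, so the
routine falls back to pi0 = 1 and notes it on the returned object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import ValidationError

logger = logging.getLogger(__name__)

#: Below this many tests the Storey estimator auto-falls back to pi0 = 1.
MIN_TESTS_FOR_STOREY = 100


@dataclass
class QValueVector:
    """q-values aligned to the input p-value order, plus the pi0 used."""

    q: np.ndarray
    pi0: float
    pi0_method: str

    def __len__(self) -> int:
        return len(self.q)


def estimate_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Fixed-lambda Storey estimate of the null proportion, floored at 1/m."""
    m = p.size
    pi0 = (p > lam).sum() / ((1.0 - lam) * m)
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalues(
    p: Sequence[float] | np.ndarray,
    pi0_method: str = "storey_lambda",
    lam: float = 0.5,
) -> QValueVector:
    """Convert a vector of p-values to q-values.

    Parameters
    ----------
    p : sequence of p-values in [0, 1], length m >= 1.
    pi0_method : "storey_lambda" (fixed-lambda estimate at ``lam``) or
        "one" (pi0 = 1; yields Benjamini–Hochberg adjusted p-values).
    lam : tuning point of the Storey estimator.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("qvalues expects a non-empty 1-d p-value vector")
    if np.any(np.isnan(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError("p-values must lie in [0, 1]")
    if pi0_method not in ("storey_lambda", "one"):
        raise ValidationError(f"unknown pi0_method {pi0_method!r}")
    m = arr.size
    method = pi0_method
    if pi0_method == "storey_lambda" and m < MIN_TESTS_FOR_STOREY:
        logger.info(
            "only %d tests: falling back from storey_lambda to pi0=1", m
        )
        method = "one"
    pi0 = 1.0 if method == "one" else estimate_pi0(arr, lam)
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueVector(q=q, pi0=pi0, pi0_method=method)


def attach_qvalues(results: Iterable, **kwargs) -> QValueVector:
    """Fill ``q_meta`` on a list of :class:`~metacombine.combine.MetaResult`."""
    results = list(results)
    qv = qvalues([r.p_meta for r in results], **kwargs)
    for res, q in zip(results, qv.q):
        res.q_meta = float(q)
    return qv
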