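"""Directional combination of signed p-values across studies.

Each study contributes, per protein, a direction (sign of the
Group1 − Group2 difference) and a two-sided p-value.  These are first
converted to a left-sided p-value ``p_L`` — the probability of falsely
concluding the protein is *less* abundant in Group 1 — with
``p_R = 1 − p_L`` its right-sided mirror:

* sign = −1:  ``p_L = p_two / 2``,      ``p_R = 1 − p_two / 2``
* sign = +1:  ``p_L = 1 − p_two / 2``,  ``p_R = p_two / 2``
* sign =  0:  ``p_L = p_R = 1/2`` (no directional information)

Both tails are carried explicitly so that flipping every input sign is an
exact mirror operation in floating point, not a lossy ``1 − p``.

Two directional combiners are provided for a protein quantified in
``K ≥ 2`` studies:

Stouffer
    ``Z = Σ_i Φ⁻¹(p_L_i) / √K``; the combined two-sided p-value is
    ``min(1, 2·min(Φ(Z), Φ(−Z)))`` (Bonferroni over the two sides).

Pearson (one-sided Fisher)
    ``Q_L = −2 Σ_i log p_L_i``, ``Q_R = −2 Σ_i log p_R_i``; the combined
    p-value is ``min(1, 2·Pr(χ²_{2K} ≥ max(Q_L, Q_R)))``.

Both report a combined sign: −1 when the left side carries the evidence,
+1 for the right side, 0 on a tie (the two tail statistics equal up to
floating-point error; see ``TIE_RTOL``).  A protein quantified in a single
study keeps that study's two-sided p-value and sign unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from .io import SignedPValue, StudyResult, ValidationError

#: One-sided p-values are clamped into [EPSILON, 1 − EPSILON] before the
#: inverse-normal / log transforms so that a p of exactly 0 or 1 cannot
#: produce infinities.  Far below any meaningful resolution of the inputs.
EPSILON = 1e-15

#: Relative scale below which the left/right tail statistics are declared
#: tied (combined sign 0): a directional call supported only by round-off
#: in the last few bits is noise, not evidence.
TIE_RTOL = 1e-12

METHODS = ("stouffer", "pearson")


@dataclass
class MetaResult:
    """Combined evidence for one protein across the studies quantifying it."""

    protein_id: str
    k_used: int
    sign: int
    p_meta: float
    method: str  # "stouffer", "pearson" or "single"
    q_meta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_meta <= 1.0:
            raise ValidationError(f"p_meta {self.p_meta} outside [0, 1]")
        if (self.method == "single") != (self.k_used == 1):
            raise ValidationError("method 'single' exactly when k_used == 1")


def one_sided_from_signed(rec: SignedPValue) -> float:
    """Left-sided p-value ``p_L`` for one signed two-sided record."""
    return one_sided_pair(rec)[0]


def one_sided_pair(rec: SignedPValue) -> tuple[float, float]:
    """Both one-sided tails ``(p_L, p_R)``; exact complements by construction."""
    half = rec.p_two / 2.0
    if rec.sign > 0:
        return 1.0 - half, half
    if rec.sign < 0:
        return half, 1.0 - half
    return 0.5, 0.5


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPSILON, 1.0 - EPSILON)


def _stouffer_matrix(
    p_left: np.ndarray, p_right: np.ndarray, k_used: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Stouffer combination over (proteins × studies) matrices.

    NaN marks proteins not quantified in a study; ``k_used`` is the per-row
    count of non-NaN entries (all ≥ 1).  Each study's Z-score is taken from
    the smaller tail (``Z = Φ⁻¹(p_L)`` when ``p_L ≤ 1/2``, else
    ``−Φ⁻¹(p_R)``) so mirrored inputs yield exactly negated Z.
    """
    use_left = p_left <= 0.5
    with np.errstate(invalid="ignore"):
        z = np.where(use_left, ndtri(_clamp(p_left)), -ndtri(_clamp(p_right)))
    z_comb = np.nansum(z, axis=1) / np.sqrt(k_used)
    p_l = ndtr(z_comb)
    p_r = ndtr(-z_comb)
    p_meta = np.minimum(1.0, 2.0 * np.minimum(p_l, p_r))
    scale = np.maximum(1.0, np.nansum(np.abs(z), axis=1) / np.sqrt(k_used))
    tied = np.abs(z_comb) <= TIE_RTOL * scale
    # Z < 0 means the left side (less abundant in Group 1) carries the evidence
    sign = np.where(tied, 0, np.where(z_comb < 0, -1, 1))
    return p_meta, sign


def _pearson_matrix(
    p_left: np.ndarray, p_right: np.ndarray, k_used: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson (directional one-sided Fisher) combination."""
    with np.errstate(invalid="ignore"):
        q_l = -2.0 * np.nansum(np.log(_clamp(p_left)), axis=1)
        q_r = -2.0 * np.nansum(np.log(_clamp(p_right)), axis=1)
    q_t = np.maximum(q_l, q_r)
    p_meta = np.minimum(1.0, 2.0 * stats.chi2.sf(q_t, 2 * k_used))
    tied = np.abs(q_l - q_r) <= TIE_RTOL * np.maximum(1.0, q_t)
    sign = np.where(tied, 0, np.where(q_l > q_r, -1, 1))
    return p_meta, sign


def _pair_from_lefts(p_lefts: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p_lefts, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValidationError("combiners need at least two one-sided p-values")
    if np.any(np.isnan(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValidationError("one-sided p-values must lie in [0, 1]")
    return p[None, :], (1.0 - p)[None, :]


def stouffer_combine(p_lefts: Sequence[float]) -> tuple[float, int]:
    """Combine ``K ≥ 2`` left-sided p-values with Stouffer's directional test.

    Returns ``(p_meta, sign)``.
    """
    pl, pr = _pair_from_lefts(p_lefts)
    pm, sg = _stouffer_matrix(pl, pr, np.array([pl.shape[1]]))
    return float(pm[0]), int(sg[0])


def pearson_combine(p_lefts: Sequence[float]) -> tuple[float, int]:
    """Combine ``K ≥ 2`` left-sided p-values with Pearson's directional test.

    Returns ``(p_meta, sign)``.
    """
    pl, pr = _pair_from_lefts(p_lefts)
    pm, sg = _pearson_matrix(pl, pr, np.array([pl.shape[1]]))
    return float(pm[0]), int(sg[0])


def combine_matrix(
    p_left: np.ndarray,
    p_right: np.ndarray,
    p_two: np.ndarray,
    sign: np.ndarray,
    method: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array-level pipeline used by :func:`combine_all` and the simulator.

    All inputs are (proteins × studies) with NaN marking proteins not
    quantified in a study.  Rows quantified in one study pass through that
    study's two-sided p-value and sign; rows with ``k ≥ 2`` are combined
    with the chosen method.  Returns ``(p_meta, sign_meta, k_used)``.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    quantified = ~np.isnan(p_left)
    k_used = quantified.sum(axis=1)
    if np.any(k_used == 0):
        raise ValidationError("every protein must be quantified in at least one study")
    combiner = _stouffer_matrix if method == "stouffer" else _pearson_matrix
    p_meta, sign_meta = combiner(p_left, p_right, k_used)
    single = k_used == 1
    if np.any(single):
        # passthrough: the one study's two-sided p and sign, unchanged
        only_p = np.nanmax(np.where(quantified, p_two, -np.inf), axis=1)
        only_sign = np.nansum(np.where(quantified, sign, 0.0), axis=1)
        p_meta = np.where(single, only_p, p_meta)
        sign_meta = np.where(single, only_sign, sign_meta)
    return p_meta, sign_meta.astype(int), k_used


def combine_all(studies: Sequence[StudyResult], method: str = "stouffer") -> list[MetaResult]:
    """Combine every protein quantified in at least one study.

    Proteins present in ≥ 2 studies get the chosen combiner applied to
    their one-sided p-values; proteins present in exactly one study keep
    that study's two-sided p-value and sign (``method="single"``).
    q-values are left unset; see :mod:`metacombine.fdr`.
    """
    if not studies:
        raise ValidationError("combine_all needs at least one study")
    union = sorted({rec.protein_id for st in studies for rec in st.records})
    index = {pid: i for i, pid in enumerate(union)}
    n, k = len(union), len(studies)
    p_left = np.full((n, k), np.nan)
    p_right = np.full((n, k), np.nan)
    p_two = np.full((n, k), np.nan)
    sign = np.full((n, k), np.nan)
    for j, st in enumerate(studies):
        for rec in st.records:
            i = index[rec.protein_id]
            p_left[i, j], p_right[i, j] = one_sided_pair(rec)
            p_two[i, j] = rec.p_two
            sign[i, j] = rec.sign
    p_meta, sign_meta, k_used = combine_matrix(p_left, p_right, p_two, sign, method)
    return [
        MetaResult(
            protein_id=pid,
            k_used=int(k_used[i]),
            sign=int(sign_meta[i]),
            p_meta=float(min(1.0, p_meta[i])),
            method="single" if k_used[i] == 1 else method,
        )
        for i, pid in enumerate(union)
    ]
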