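"""Detection sets and integration metrics.

A protein is *detected* by an analysis when its q-value is strictly below
the cutoff (default 5%).  Given the meta-analysis detection set M and the
single-study detection sets S_1..S_K with union U:

* IDR (integration-driven discovery rate) = 100·|M \\ U| / |M| — the share
  of meta detections no individual study found;
* IRR (integration-driven revision rate) = 100·|U \\ M| / |U| — the share
  of individually detected proteins the meta-analysis missed.

For simulated data, where the truly differential proteins are known,
truth-aware variants are defined: tFDR is the share of meta detections
that are not truly differential, and tIDR/tIRR are IDR/IRR computed after
intersecting every detection set with the truly-differential set.

Empty denominators yield a rate of 0 rather than NaN so that averages over
simulation replicates stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .io import ValidationError


@dataclass
class TruthLabels:
    """Ground truth for a simulated universe of proteins."""

    differential: dict[Hashable, bool]
    true_sign: dict[Hashable, int] = field(default_factory=dict)
    fold_change: dict[Hashable, float] = field(default_factory=dict)

    def differential_set(self) -> set:
        return {pid for pid, d in self.differential.items() if d}


@dataclass
class PerformanceReport:
    """Detection counts and integration metrics for one analysis run."""

    cutoff: float
    n_meta: int
    n_single: list[int]
    n_intersection: int
    n_union: int
    idr: float
    irr: float
    tfdr: float | None = None
    tidr: float | None = None
    tirr: float | None = None


def detection_sets(
    meta: Sequence,
    singles: Sequence[Mapping[Hashable, float]],
    cutoff: float = 0.05,
) -> tuple[set, list[set]]:
    """Detection sets at a q-value cutoff (strict ``q < cutoff``).

    ``meta`` is a sequence of MetaResults with q-values populated;
    ``singles`` maps, per study, protein id -> single-analysis q-value.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValidationError(f"cutoff must lie in (0, 1), got {cutoff}")
    for res in meta:
        if res.q_meta is None:
            raise ValidationError(f"q_meta unset for {res.protein_id!r}; run fdr first")
    meta_set = {res.protein_id for res in meta if res.q_meta < cutoff}
    single_sets = [
        {pid for pid, q in qmap.items() if q < cutoff} for qmap in singles
    ]
    return meta_set, single_sets


def idr_irr(meta_set: set, single_sets: Sequence[set]) -> tuple[float, float]:
    """Integration-driven discovery and revision rates, in percent."""
    union: set = set().union(*single_sets) if single_sets else set()
    idr = 100.0 * len(meta_set - union) / len(meta_set) if meta_set else 0.0
    irr = 100.0 * len(union - meta_set) / len(union) if union else 0.0
    return idr, irr


def truth_metrics(
    meta_set: set,
    single_sets: Sequence[set],
    truth: TruthLabels,
) -> tuple[float, float, float]:
    """Truth-aware (tFDR, tIDR, tIRR), in percent.

    tFDR counts a detection as false when the protein is not truly
    differential; direction accuracy is a separate diagnostic (see
    :func:`sign_accuracy`).
    """
    universe = set(meta_set).union(*single_sets) if single_sets else set(meta_set)
    missing = {pid for pid in universe if pid not in truth.differential}
    if missing:
        raise ValidationError(
            f"{len(missing)} detected protein(s) missing from truth labels"
        )
    true_diff = truth.differential_set()
    n_meta = len(meta_set)
    tfdr = 100.0 * len(meta_set - true_diff) / n_meta if n_meta else 0.0
    tidr, tirr = idr_irr(
        meta_set & true_diff, [s & true_diff for s in single_sets]
    )
    return tfdr, tidr, tirr


def sign_accuracy(
    meta: Sequence,
    truth: TruthLabels,
    detected: set | None = None,
) -> float:
    """Fraction (%) of truly differential detections whose combined sign
    matches the true direction.  Diagnostic only; not part of tFDR."""
    hits = 0
    total = 0
    for res in meta:
        pid = res.protein_id
        if detected is not None and pid not in detected:
            continue
        if truth.differential.get(pid):
            total += 1
            if truth.true_sign.get(pid) == res.sign:
                hits += 1
    return 100.0 * hits / total if total else 0.0


def performance_report(
    meta: Sequence,
    singles: Sequence[Mapping[Hashable, float]],
    cutoff: float = 0.05,
    truth: TruthLabels | None = None,
) -> PerformanceReport:
    """Full report: counts, IDR/IRR, and truth-aware rates when truth given."""
    meta_set, single_sets = detection_sets(meta, singles, cutoff)
    idr, irr = idr_irr(meta_set, single_sets)
    inter = set.intersection(*single_sets) if single_sets else set()
    union = set().union(*single_sets) if single_sets else set()
    report = PerformanceReport(
        cutoff=cutoff,
        n_meta=len(meta_set),
        n_single=[len(s) for s in single_sets],
        n_intersection=len(inter),
        n_union=len(union),
        idr=idr,
        irr=irr,
    )
    if truth is not None:
        report.tfdr, report.tidr, report.tirr = truth_metrics(
            meta_set, single_sets, truth
        )
    return report
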