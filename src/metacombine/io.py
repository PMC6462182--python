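"""Reading and writing per-study differential-abundance result tables.

Input dialect
-------------
One UTF-8 tab-separated file per study with a header row naming, in any
order and any capitalisation, the columns

* ``Protein`` — protein identifier, unique within a study;
* ``Sign``    — direction of the Group1 − Group2 abundance difference.
  Accepted spellings: ``-1``/``0``/``1``, ``-``/``+``/``0``, or any signed
  test-statistic value (only its sign is used);
* ``Pvalue``  — two-sided p-value in [0, 1].

The exact schema of the original tool's input files is not published; this
dialect realises its description (signs of test statistics plus p-values)
and is the format written by :func:`write_study`.

A folder of such files defines a multi-study analysis; lexicographic
filename order defines the study order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Literal written for a (study, protein) cell when the protein was not
#: quantified in that study.
NA_MARKER = "NA"

_COLUMNS = ("protein", "sign", "pvalue")


class FormatError(ValueError):
    """The file does not conform to the input dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """The file parses but violates a content invariant (range, uniqueness)."""


@dataclass(frozen=True)
class SignedPValue:
    """Per-protein, per-study evidence: a direction and a two-sided p-value."""

    protein_id: str
    sign: int
    p_two: float

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.sign not in (-1, 0, 1):
            raise ValidationError(f"sign must be -1, 0 or +1, got {self.sign!r}")
        if not (isinstance(self.p_two, (int, float)) and 0.0 <= self.p_two <= 1.0):
            raise ValidationError(
                f"p-value for {self.protein_id!r} must lie in [0, 1], got {self.p_two!r}"
            )


@dataclass
class StudyResult:
    """A named collection of :class:`SignedPValue` records for one study."""

    study_name: str
    records: list[SignedPValue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"study {self.study_name!r} has no records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise ValidationError(
                    f"duplicate protein {rec.protein_id!r} in study {self.study_name!r}"
                )
            seen.add(rec.protein_id)

    def protein_ids(self) -> list[str]:
        return [rec.protein_id for rec in self.records]

    def by_protein(self) -> dict[str, SignedPValue]:
        return {rec.protein_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)


def _parse_sign(raw: object, row: int, path: Path) -> int:
    text = str(raw).strip()
    if text in {"+", "+1", "1"}:
        return 1
    if text in {"-", "-1"}:
        return -1
    if text == "0":
        return 0
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(
            f"{path.name}, row {row}: cannot interpret sign {raw!r}"
        ) from None
    if math.isnan(value):
        raise ValidationError(f"{path.name}, row {row}: sign is NaN")
    return (value > 0) - (value < 0)


def read_study(path: str | Path, study_name: str | None = None) -> StudyResult:
    """Parse one per-study TSV into a :class:`StudyResult`.

    ``study_name`` defaults to the file name without its extension.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    lower = {str(c).strip().lower(): c for c in frame.columns}
    missing = [name for name in _COLUMNS if name not in lower]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)} "
            f"(header was {list(frame.columns)})"
        )
    records: list[SignedPValue] = []
    seen: set[str] = set()
    for row, (_, data) in enumerate(frame.iterrows(), start=1):
        protein = str(data[lower["protein"]]).strip()
        if not protein or protein.lower() == "nan":
            raise ValidationError(f"{path.name}, row {row}: empty protein identifier")
        if protein in seen:
            raise ValidationError(f"{path.name}, row {row}: duplicate protein {protein!r}")
        seen.add(protein)
        sign = _parse_sign(data[lower["sign"]], row, path)
        try:
            p_two = float(data[lower["pvalue"]])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path.name}, row {row}: cannot parse p-value {data[lower['pvalue']]!r}"
            ) from None
        if not (0.0 <= p_two <= 1.0) or math.isnan(p_two):
            raise ValidationError(
                f"{path.name}, row {row}: p-value {p_two} outside [0, 1]"
            )
        records.append(SignedPValue(protein, sign, p_two))
    return StudyResult(study_name or path.stem, records)


def read_study_folder(folder: str | Path) -> list[StudyResult]:
    """Read every ``*.tsv``/``*.txt`` file in ``folder``, in lexicographic order."""
    folder = Path(folder)
    if not folder.is_dir():
        raise FormatError(f"input folder {folder} does not exist")
    paths = sorted(
        p for p in folder.iterdir() if p.suffix.lower() in {".tsv", ".txt"} and p.is_file()
    )
    if not paths:
        raise FormatError(f"input folder {folder} contains no .tsv/.txt study files")
    return [read_study(p) for p in paths]


def write_study(study: StudyResult, path: str | Path) -> None:
    """Write a study back out in the input dialect (full-precision p-values)."""
    frame = pd.DataFrame(
        {
            "Protein": [r.protein_id for r in study.records],
            "Sign": [r.sign for r in study.records],
            "Pvalue": [repr(float(r.p_two)) for r in study.records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_results(results: Sequence, per_study: Sequence[StudyResult], path: str | Path) -> None:
    """Write the combined result table: one row per protein in the union.

    Columns: ``Protein``, then per study ``<name>_Sign/_Pvalue/_Qvalue``
    (``NA`` where the protein was not quantified), then
    ``Meta_Sign/Meta_Pvalue/Meta_Qvalue``.  Rows sorted by meta p-value
    ascending, ties broken by protein identifier.

    Per-study q-values are computed here from each study's own p-value
    vector, so the table compares every single analysis with the
    meta-analysis on the same footing.
    """
    from .fdr import qvalues  # local import: fdr does not import io

    if not results:
        raise ValidationError("results list is empty; nothing to write")
    study_q: list[dict[str, float]] = []
    for study in per_study:
        qv = qvalues([r.p_two for r in study.records])
        study_q.append(
            {r.protein_id: q for r, q in zip(study.records, qv.q)}
        )
    study_maps = [study.by_protein() for study in per_study]
    ordered = sorted(results, key=lambda r: (r.p_meta, r.protein_id))
    rows = []
    for res in ordered:
        row: dict[str, object] = {"Protein": res.protein_id}
        for study, smap, qmap in zip(per_study, study_maps, study_q):
            rec = smap.get(res.protein_id)
            prefix = study.study_name
            if rec is None:
                row[f"{prefix}_Sign"] = NA_MARKER
                row[f"{prefix}_Pvalue"] = NA_MARKER
                row[f"{prefix}_Qvalue"] = NA_MARKER
            else:
                row[f"{prefix}_Sign"] = rec.sign
                row[f"{prefix}_Pvalue"] = repr(float(rec.p_two))
                row[f"{prefix}_Qvalue"] = repr(float(qmap[rec.protein_id]))
        row["Meta_Sign"] = res.sign
        row["Meta_Pvalue"] = repr(float(res.p_meta))
        row["Meta_Qvalue"] = NA_MARKER if res.q_meta is None else repr(float(res.q_meta))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
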