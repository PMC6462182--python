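"""End-to-end analysis of a folder of study files, with report artifacts.

Given a folder of per-study TSVs, :func:`run` combines them, computes
q-values, and writes:

* ``result.tsv``       — combined table (per-study and meta sign/p/q);
* ``qplot.tsv``/``qplot.png`` — detections vs q-value threshold, one curve
  per single analysis plus the meta-analysis;
* ``summary.tsv``/``summary.txt`` — detection counts at the cutoff,
  intersection/union over the single analyses, IDR and IRR;
* ``top_proteins.tsv`` — top-N proteins ranked by meta p-value;
* ``run.log``          — configuration echo and any decisions taken.

All tables are deterministic; re-running on the same inputs reproduces
them byte for byte (the PNG is a rendering of ``qplot.tsv``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .combine import METHODS, MetaResult, combine_all
from .fdr import attach_qvalues, qvalues
from .io import StudyResult, ValidationError, read_study_folder, write_results
from .metrics import detection_sets, idr_irr

#: q-value threshold grid for the q-plot: (0, 0.10] in steps of 0.005.
QPLOT_GRID = np.round(np.arange(0.005, 0.1001, 0.005), 3)


@dataclass
class RunConfig:
    """Configuration mirroring the command-line flag surface."""

    metaanalysis: str = "Stouffer"
    cutoff: float = 0.05
    top: int = 15
    input: str | Path = "input"
    output: str | Path = "output"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError("cutoff must lie in (0, 1)")
        if self.top < 1:
            raise ValidationError("top must be >= 1")
        if self.metaanalysis.lower() not in METHODS:
            raise ValidationError(
                f"metaanalysis must be one of {[m.title() for m in METHODS]}"
            )

    @property
    def method(self) -> str:
        return self.metaanalysis.lower()


def top_n(results: Sequence[MetaResult], n: int) -> list[MetaResult]:
    """Top-``n`` proteins by ascending meta p-value, ties by protein id."""
    if n < 1:
        raise ValidationError("top-N count must be >= 1")
    return sorted(results, key=lambda r: (r.p_meta, r.protein_id))[:n]


def qplot_table(
    results: Sequence[MetaResult],
    studies: Sequence[StudyResult],
    singles_q: Sequence[dict[str, float]],
    grid: np.ndarray = QPLOT_GRID,
) -> pd.DataFrame:
    """Number of detections (strict ``q < t``) per analysis at each threshold."""
    meta_q = np.array([r.q_meta for r in results])
    rows = []
    for t in grid:
        row: dict[str, object] = {"q_threshold": t, "Meta": int((meta_q < t).sum())}
        for study, qmap in zip(studies, singles_q):
            row[study.study_name] = sum(q < t for q in qmap.values())
        rows.append(row)
    return pd.DataFrame(rows)


def summary_tables(
    results: Sequence[MetaResult],
    studies: Sequence[StudyResult],
    singles_q: Sequence[dict[str, float]],
    cutoff: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection counts and the IDR/IRR diagnosis at the cutoff."""
    meta_set, single_sets = detection_sets(results, singles_q, cutoff)
    counts = [("Meta analysis", len(meta_set))]
    counts += [
        (f"Single Analysis: {st.study_name}", len(s))
        for st, s in zip(studies, single_sets)
    ]
    counts.append(
        ("Intersection among Single Analyses", len(set.intersection(*single_sets)))
    )
    counts.append(("Union among Single Analyses", len(set().union(*single_sets))))
    count_frame = pd.DataFrame(counts, columns=["Analysis", "Detected"])
    idr, irr = idr_irr(meta_set, single_sets)
    diag_frame = pd.DataFrame(
        [("IDR (%)", round(idr, 2)), ("IRR (%)", round(irr, 2))],
        columns=["Measure", "Value"],
    )
    return count_frame, diag_frame


def _render_qplot(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in table.columns[1:]:
        style = "-" if col == "Meta" else "--"
        ax.plot(table["q_threshold"], table[col], style, label=col)
    ax.set_xlabel("q-value threshold")
    ax.set_ylabel("number of detected proteins")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns the paths of the written artifacts."""
    logger = logging.getLogger(__name__)
    out_dir = Path(config.output)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"metacombine {__version__}",
        f"metaanalysis={config.metaanalysis} cutoff={config.cutoff} top={config.top}",
        f"input={config.input} output={config.output}",
    ]

    studies = read_study_folder(config.input)
    log_lines.append(
        "studies (lexicographic order): "
        + ", ".join(f"{s.study_name} ({len(s)} proteins)" for s in studies)
    )
    if len(studies) == 1:
        msg = "single study supplied: meta columns equal the single-study passthrough"
        logger.warning(msg)
        log_lines.append("WARNING: " + msg)

    results = combine_all(studies, config.method)
    qv = attach_qvalues(results)
    log_lines.append(f"meta q-values: pi0={qv.pi0:.4f} ({qv.pi0_method})")
    singles_q = []
    for study in studies:
        sq = qvalues([r.p_two for r in study.records])
        singles_q.append(
            {r.protein_id: float(q) for r, q in zip(study.records, sq.q)}
        )
        log_lines.append(
            f"{study.study_name} q-values: pi0={sq.pi0:.4f} ({sq.pi0_method})"
        )

    paths: dict[str, Path] = {}
    paths["result"] = out_dir / "result.tsv"
    write_results(results, studies, paths["result"])

    qtable = qplot_table(results, studies, singles_q)
    paths["qplot_table"] = out_dir / "qplot.tsv"
    qtable.to_csv(paths["qplot_table"], sep="\t", index=False)
    paths["qplot_image"] = out_dir / "qplot.png"
    _render_qplot(qtable, paths["qplot_image"])

    counts, diag = summary_tables(results, studies, singles_q, config.cutoff)
    paths["summary"] = out_dir / "summary.tsv"
    pd.concat(
        [counts.rename(columns={"Analysis": "Row", "Detected": "Value"}),
         diag.rename(columns={"Measure": "Row"})]
    ).to_csv(paths["summary"], sep="\t", index=False)
    paths["summary_text"] = out_dir / "summary.txt"
    paths["summary_text"].write_text(
        counts.to_string(index=False)
        + "\n\n"
        + diag.to_string(index=False)
        + "\n",
        encoding="utf-8",
    )

    top = min(config.top, len(results))
    if top < config.top:
        msg = f"top={config.top} exceeds protein count; truncated to {top}"
        logger.warning(msg)
        log_lines.append("WARNING: " + msg)
    ranked = top_n(results, top)
    paths["top"] = out_dir / "top_proteins.tsv"
    pd.DataFrame(
        {
            "Protein": [r.protein_id for r in ranked],
            "Sign": [r.sign for r in ranked],
            "Pvalue": [repr(float(r.p_meta)) for r in ranked],
            "Qvalue": [repr(float(r.q_meta)) for r in ranked],
        }
    ).to_csv(paths["top"], sep="\t", index=False)

    paths["log"] = out_dir / "run.log"
    paths["log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return paths
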