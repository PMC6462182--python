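"""Multi-study proteomic abundance simulator and Monte-Carlo harness.

The generative model mimics label-free quantitative proteomics at the
protein level.  Abundances are on a log scale.  For protein ``j`` in any
study, a sample's abundance is

    x_ij ~ N(gamma_j, lambda_j^2)

with protein-level parameters drawn from a hierarchical mean–variance
model estimated from label-free mouse plasma data:

    log(gamma_j)  ~ N(mu, sigma^2)                        mu = 2.42, sigma = 0.30
    log(lambda_j) ~ N(alpha + beta*log(gamma_j), eta)     alpha = 1.63, beta = -0.90,
                                                          eta = 0.50 (variance)

``gamma_j`` and ``lambda_j`` belong to the protein and are shared by every
study quantifying it; ``eta`` is the *variance* of log(lambda), matching
the notation that writes the other two scales squared.  A 30% share of
proteins is differential with a fold change of 1.5, 2 or 4 (uniform) in a
random direction; since x is log-scale abundance, a fold change FC shifts
the Group-2 mean by -true_sign * ln(FC).

Each study quantifies 2,000 proteins: a core shared by all studies
(``round(2000*rho)`` proteins) plus study-unique remainders.  Per study a
Welch two-sample t-test (unequal variances, Satterthwaite df) yields the
signed two-sided p-values that feed the meta-analysis.

``alpha_scale`` (> 1 in Scenarios 7–8) inflates ``alpha`` — and hence every
protein's measurement spread — in all studies, emulating noisier
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import combine as _combine
from . import fdr as _fdr
from . import metrics as _metrics
from .io import SignedPValue, StudyResult, ValidationError, write_study


@dataclass(frozen=True)
class SimulationScenario:
    """Parameter bundle for one simulation condition."""

    n: int  # samples per group
    K: int = 2  # number of studies
    rho: float = 0.75  # overlap fraction of quantified proteins
    alpha_scale: float = 1.0  # multiplier on alpha (experiment quality)
    n_proteins: int = 2000  # proteins quantified per study
    diff_fraction: float = 0.30
    fold_changes: tuple[float, ...] = (1.5, 2.0, 4.0)
    mu: float = 2.42
    sigma: float = 0.30
    alpha: float = 1.63
    beta: float = -0.90
    eta: float = 0.50  # variance of log(lambda)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.K < 2:
            raise ValidationError("need at least 2 studies")
        if not 0.0 < self.rho <= 1.0:
            raise ValidationError("rho must lie in (0, 1]")
        if self.alpha_scale < 1.0:
            raise ValidationError("alpha_scale must be >= 1")

    @property
    def n_core(self) -> int:
        return round(self.n_proteins * self.rho)

    @property
    def n_unique(self) -> int:
        return self.n_proteins - self.n_core

    @property
    def n_universe(self) -> int:
        return self.n_core + self.K * self.n_unique


#: The ten study conditions explored in the simulation study.
SCENARIOS: dict[int, SimulationScenario] = {
    1: SimulationScenario(n=6),
    2: SimulationScenario(n=9),
    3: SimulationScenario(n=12),
    4: SimulationScenario(n=6, K=3),
    5: SimulationScenario(n=6, K=4),
    6: SimulationScenario(n=6, K=5),
    7: SimulationScenario(n=6, alpha_scale=1.5),
    8: SimulationScenario(n=6, alpha_scale=2.0),
    9: SimulationScenario(n=6, rho=0.50),
    10: SimulationScenario(n=6, rho=0.25),
}


@dataclass
class SimulatedStudy:
    """One study's abundance matrix plus the parameters that generated it."""

    study_name: str
    protein_ids: list[str]
    abundance: np.ndarray  # proteins x 2n samples; first n = Group 1
    n_per_group: int
    gamma: np.ndarray
    lam: np.ndarray

    @property
    def group1(self) -> np.ndarray:
        return self.abundance[:, : self.n_per_group]

    @property
    def group2(self) -> np.ndarray:
        return self.abundance[:, self.n_per_group :]


# ---------------------------------------------------------------------------
# array-level building blocks (also the fast path used by run_scenario)
# ---------------------------------------------------------------------------

def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def _universe_indices(scenario: SimulationScenario) -> list[np.ndarray]:
    """Per-study index arrays into the universe 0..n_universe-1.

    Indices 0..n_core-1 are the all-studies core; study i additionally gets
    the i-th block of study-unique indices.
    """
    core = np.arange(scenario.n_core)
    blocks = []
    for i in range(scenario.K):
        start = scenario.n_core + i * scenario.n_unique
        unique = np.arange(start, start + scenario.n_unique)
        blocks.append(np.concatenate([core, unique]))
    return blocks


def _draw_params_arrays(
    n_proteins: int, scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    log_gamma = rng.normal(scenario.mu, scenario.sigma, n_proteins)
    gamma = np.exp(log_gamma)
    alpha_eff = scenario.alpha * scenario.alpha_scale
    log_lam = rng.normal(alpha_eff + scenario.beta * log_gamma, np.sqrt(scenario.eta))
    return gamma, np.exp(log_lam)


def _assign_truth_arrays(
    n_universe: int, scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_diff = round(scenario.diff_fraction * n_universe)
    differential = np.zeros(n_universe, dtype=bool)
    differential[rng.choice(n_universe, n_diff, replace=False)] = True
    fold = np.asarray(scenario.fold_changes)[
        rng.integers(0, len(scenario.fold_changes), n_universe)
    ]
    sign = rng.choice(np.array([-1, 1]), n_universe)
    fold = np.where(differential, fold, 1.0)
    sign = np.where(differential, sign, 0)
    return differential, sign, fold


def _welch_arrays(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch test over rows: returns (two-sided p, sign of mean1-mean2)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    sign = np.sign(diff).astype(int)
    se2 = g1.var(axis=1, ddof=1) / g1.shape[1] + g2.var(axis=1, ddof=1) / g2.shape[1]
    degenerate = se2 == 0.0
    if np.any(degenerate):
        p = np.where(degenerate & (diff == 0.0), 1.0, p)
        p = np.where(degenerate & (diff != 0.0), 0.0, p)
    return p, sign


def _simulate_study_arrays(
    scenario: SimulationScenario,
    gamma: np.ndarray,
    lam: np.ndarray,
    shift: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Abundance matrix for one study: Group 1 then Group 2 columns."""
    n = scenario.n
    size = (gamma.size, n)
    g1 = rng.normal(gamma[:, None], lam[:, None], size)
    g2 = rng.normal((gamma - shift)[:, None], lam[:, None], size)
    return np.concatenate([g1, g2], axis=1)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_universe(scenario: SimulationScenario) -> list[list[str]]:
    """Per-study protein-id lists: an all-studies core plus unique remainders.

    Each study quantifies exactly ``scenario.n_proteins`` proteins.
    """
    return [[_protein_id(i) for i in idx] for idx in _universe_indices(scenario)]


def draw_protein_params(
    n_proteins: int, scenario: SimulationScenario, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Draw (gamma_j, lambda_j) pairs from the hierarchical model."""
    gamma, lam = _draw_params_arrays(n_proteins, scenario, rng)
    return list(zip(gamma.tolist(), lam.tolist()))


def assign_truth(
    universe: Sequence[str], scenario: SimulationScenario, rng: np.random.Generator
) -> _metrics.TruthLabels:
    """Flag 30% of the universe as differential; shared across all studies."""
    differential, sign, fold = _assign_truth_arrays(len(universe), scenario, rng)
    return _metrics.TruthLabels(
        differential={pid: bool(d) for pid, d in zip(universe, differential)},
        true_sign={pid: int(s) for pid, s in zip(universe, sign)},
        fold_change={pid: float(f) for pid, f in zip(universe, fold)},
    )


def simulate_study(
    scenario: SimulationScenario,
    protein_ids: Sequence[str],
    truth: _metrics.TruthLabels,
    rng: np.random.Generator,
    study_name: str = "study1",
    gamma: np.ndarray | None = None,
    lam: np.ndarray | None = None,
) -> SimulatedStudy:
    """Simulate one study's abundance matrix for the given protein slice.

    ``gamma``/``lam`` may be passed to share protein parameters across
    studies (the default within :func:`run_scenario`); otherwise they are
    drawn fresh.
    """
    ids = list(protein_ids)
    if gamma is None or lam is None:
        gamma, lam = _draw_params_arrays(len(ids), scenario, rng)
    sign = np.array([truth.true_sign.get(pid, 0) for pid in ids], dtype=float)
    fold = np.array([truth.fold_change.get(pid, 1.0) for pid in ids])
    shift = sign * np.log(fold)
    abundance = _simulate_study_arrays(scenario, np.asarray(gamma), np.asarray(lam), shift, rng)
    return SimulatedStudy(
        study_name=study_name,
        protein_ids=ids,
        abundance=abundance,
        n_per_group=scenario.n,
        gamma=np.asarray(gamma),
        lam=np.asarray(lam),
    )


def welch_test(study: SimulatedStudy) -> list[SignedPValue]:
    """Per-protein Welch two-sample test on a simulated study."""
    p, sign = _welch_arrays(study.group1, study.group2)
    return [
        SignedPValue(pid, int(s), float(pv))
        for pid, s, pv in zip(study.protein_ids, sign, p)
    ]


def study_result(study: SimulatedStudy) -> StudyResult:
    """Welch-test a simulated study into the meta-analysis input type."""
    return StudyResult(study.study_name, welch_test(study))


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------

@dataclass
class MethodPerformance:
    """Per-replicate metric traces for one combination method."""

    method: str
    detections: np.ndarray  # (reps,) meta detections
    single_detections: np.ndarray  # (reps, K)
    tfdr: np.ndarray
    tidr: np.ndarray
    tirr: np.ndarray
    sign_acc: np.ndarray

    @property
    def reps(self) -> int:
        return len(self.detections)

    @property
    def mean_detections(self) -> float:
        return float(self.detections.mean())

    @property
    def mean_single(self) -> np.ndarray:
        return self.single_detections.mean(axis=0)

    @property
    def best_single(self) -> float:
        return float(self.mean_single.max())

    @property
    def gain_pct(self) -> float:
        """Percent more detections than the best individual analysis."""
        return 100.0 * (self.mean_detections - self.best_single) / self.best_single

    def mean(self, name: str) -> float:
        return float(getattr(self, name).mean())

    def se(self, name: str) -> float:
        """Monte-Carlo standard error of the mean of a per-replicate trace."""
        trace = getattr(self, name)
        return float(trace.std(ddof=1) / np.sqrt(len(trace)))


@dataclass
class ScenarioResult:
    scenario: SimulationScenario
    cutoff: float
    seed: int
    methods: dict[str, MethodPerformance]


def _replicate(
    scenario: SimulationScenario,
    rng: np.random.Generator,
    cutoff: float,
    methods: Sequence[str],
) -> dict[str, tuple]:
    idx_lists = _universe_indices(scenario)
    n_univ = scenario.n_universe
    gamma, lam = _draw_params_arrays(n_univ, scenario, rng)
    differential, true_sign, fold = _assign_truth_arrays(n_univ, scenario, rng)
    shift = true_sign * np.log(fold)

    K = scenario.K
    p_left = np.full((n_univ, K), np.nan)
    p_right = np.full((n_univ, K), np.nan)
    p_two = np.full((n_univ, K), np.nan)
    sgn = np.full((n_univ, K), np.nan)
    for i, idx in enumerate(idx_lists):
        ab = _simulate_study_arrays(scenario, gamma[idx], lam[idx], shift[idx], rng)
        p, s = _welch_arrays(ab[:, : scenario.n], ab[:, scenario.n :])
        p_two[idx, i] = p
        sgn[idx, i] = s
        half = p / 2.0
        p_left[idx, i] = np.where(s > 0, 1.0 - half, np.where(s < 0, half, 0.5))
        p_right[idx, i] = np.where(s > 0, half, np.where(s < 0, 1.0 - half, 0.5))

    single_sets: list[set] = []
    single_counts = np.empty(K, dtype=int)
    for i, idx in enumerate(idx_lists):
        q = _fdr.qvalues(p_two[idx, i]).q
        det = idx[q < cutoff]
        single_sets.append(set(det.tolist()))
        single_counts[i] = det.size

    truth = _metrics.TruthLabels(
        differential=dict(enumerate(differential.tolist())),
        true_sign=dict(enumerate(true_sign.tolist())),
    )
    out: dict[str, tuple] = {}
    for method in methods:
        p_meta, sign_meta, _ = _combine.combine_matrix(p_left, p_right, p_two, sgn, method)
        q_meta = _fdr.qvalues(p_meta).q
        detected = np.flatnonzero(q_meta < cutoff)
        meta_set = set(detected.tolist())
        tfdr, tidr, tirr = _metrics.truth_metrics(meta_set, single_sets, truth)
        true_hits = detected[differential[detected]]
        acc = (
            100.0 * float((sign_meta[true_hits] == true_sign[true_hits]).mean())
            if true_hits.size
            else 0.0
        )
        out[method] = (len(meta_set), single_counts.copy(), tfdr, tidr, tirr, acc)
    return out


def run_scenario(
    scenario: SimulationScenario | int,
    method: str = "both",
    reps: int = 100,
    seed: int = 0,
    cutoff: float = 0.05,
) -> ScenarioResult:
    """Monte-Carlo run: generate, test, combine, and score ``reps`` replicates.

    Each replicate builds the protein universe, assigns ground truth,
    simulates every study, runs per-study Welch tests, combines them with
    the requested method(s), computes q-values for the meta-analysis and
    every single analysis, and scores truth-aware metrics at the q-value
    ``cutoff``.  Fully reproducible: (scenario, seed) fixes every draw.
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    methods = list(_combine.METHODS) if method == "both" else [method]
    for m in methods:
        if m not in _combine.METHODS:
            raise ValidationError(f"unknown method {m!r}")
    rng = np.random.default_rng(seed)
    traces = {m: [] for m in methods}
    for _ in range(reps):
        rep = _replicate(scenario, rng, cutoff, methods)
        for m, values in rep.items():
            traces[m].append(values)
    performances = {}
    for m, rows in traces.items():
        performances[m] = MethodPerformance(
            method=m,
            detections=np.array([r[0] for r in rows], dtype=float),
            single_detections=np.array([r[1] for r in rows], dtype=float),
            tfdr=np.array([r[2] for r in rows]),
            tidr=np.array([r[3] for r in rows]),
            tirr=np.array([r[4] for r in rows]),
            sign_acc=np.array([r[5] for r in rows]),
        )
    return ScenarioResult(scenario=scenario, cutoff=cutoff, seed=seed, methods=performances)


def write_example_inputs(
    scenario: SimulationScenario | int,
    folder: str | Path,
    seed: int = 0,
) -> list[Path]:
    """Dump one replicate's per-study input files in the TSV dialect.

    Doubles as the repository's fixture generator: the written files are
    valid :func:`metacombine.io.read_study` inputs.
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    universe = build_universe(scenario)
    all_ids = sorted({pid for ids in universe for pid in ids})
    truth = assign_truth(all_ids, scenario, rng)
    gamma, lam = _draw_params_arrays(len(all_ids), scenario, rng)
    by_id = {pid: i for i, pid in enumerate(all_ids)}
    paths = []
    for i, ids in enumerate(universe, start=1):
        rows = np.array([by_id[pid] for pid in ids])
        study = simulate_study(
            scenario, ids, truth, rng,
            study_name=f"study{i}", gamma=gamma[rows], lam=lam[rows],
        )
        path = folder / f"study{i}.tsv"
        write_study(study_result(study), path)
        paths.append(path)
    return paths
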