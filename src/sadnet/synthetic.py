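"""Synthetic cohorts with planted modular covariance structure.

The generator emulates the study design the analysis assumes: 22
subjects, two 320-s paradigms at TR = 2 s (160 volumes), 20 ROI signals
whose target correlations are positive within a dorsal and a ventral
module and negative between them, a shared nuisance signal plus linear
drifts, group-dependent condition effects on named edges, 20-trial
working-memory blocks with 25% catch trials, and bimodal subjective
sadness ratings on a 0-7 scale.

Ground truth is explicit: every (paradigm x group) cell has a target
correlation matrix, repaired to the nearest unit-diagonal positive
semidefinite matrix when the requested block structure is slightly
indefinite, so downstream recovery can be scored against what was
planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rois import load_roi_table
from .timeseries import RoiTimeSeriesSet

PARADIGMS = ("Neutral-WM1", "Sadness-WM2")
GROUPS = ("high-sadness", "low-sadness")

#: Default rating mixture: component means/SDs of the high- and
#: low-sadness groups (0-7 scale), mixture weight = share of high raters.
DEFAULT_RATING_MEANS = (6.14, 4.85)
DEFAULT_RATING_SDS = (0.35, 0.45)
DEFAULT_RATING_WEIGHT = 12 / 22

#: Behavioral defaults: 20-trial blocks, 25% catch trials, error
#: probabilities chosen to land near ~3 errors and ~1.3 inhibition
#: errors per block, reaction times ~1.33 s.
DEFAULT_WM_PARAMS = dict(
    n_trials=20,
    catch_fraction=0.25,
    p_error=0.12,
    p_inhibition_error=0.27,
    rt_mean=1.33,
    rt_sd=0.25,
)

GRID_SIZE = 16
N_TARGETS = 3
N_DISTRACTORS = 2


@dataclass(frozen=True)
class EdgeEffect:
    """Signed increment on one edge's target correlation.

    ``group=None`` applies the increment in both groups (a pure
    paradigm effect); otherwise only in the named group's cell, which
    is what creates a paradigm x group interaction downstream.
    """

    edge: tuple[str, str]
    paradigm: str
    delta: float
    group: str | None = None


@dataclass
class GroundTruthSpec:
    """Generative ground truth for one synthetic cohort.

    ``target_corr`` maps (paradigm, group) -> unit-diagonal PSD
    correlation matrix; ``repair_delta`` records the largest absolute
    entry change the PSD repair introduced per cell.
    """

    n_rois: int
    roi_order: list[str]
    planted_partition: np.ndarray
    target_corr: dict[tuple[str, str], np.ndarray]
    hub_nodes: frozenset[int]
    global_amp: float = 1.0
    drift_slope_sd: float = 0.01
    ar_coeff: float = 0.3
    noise_sd: float = 1.0
    repair_delta: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        self.planted_partition = np.asarray(self.planted_partition, dtype=np.int64)
        if self.planted_partition.shape != (self.n_rois,):
            raise ValueError("planted_partition must label every node exactly once")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.global_amp < 0 or self.drift_slope_sd < 0:
            raise ValueError("nuisance amplitudes must be nonnegative")
        for cell, mat in self.target_corr.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.n_rois, self.n_rois):
                raise ValueError(f"target matrix for {cell} has wrong shape")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"target matrix for {cell} is not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
                raise ValueError(f"target matrix for {cell} lacks unit diagonal")
            if np.abs(mat).max() > 1.0 + 1e-8:
                raise ValueError(f"target matrix for {cell} has |r| > 1")
            eigmin = np.linalg.eigvalsh(mat).min()
            if eigmin < -1e-8:
                raise ValueError(f"target matrix for {cell} is not PSD (min eig {eigmin:.3g})")
            self.target_corr[cell] = mat

    def cells(self) -> list[tuple[str, str]]:
        return list(self.target_corr.keys())

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "roi_order": list(self.roi_order),
            "planted_partition": self.planted_partition.tolist(),
            "target_corr": {
                "|".join(cell): mat.tolist() for cell, mat in self.target_corr.items()
            },
            "hub_nodes": sorted(self.hub_nodes),
            "global_amp": self.global_amp,
            "drift_slope_sd": self.drift_slope_sd,
            "ar_coeff": self.ar_coeff,
            "noise_sd": self.noise_sd,
            "repair_delta": {"|".join(cell): d for cell, d in self.repair_delta.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruthSpec":
        return cls(
            n_rois=payload["n_rois"],
            roi_order=list(payload["roi_order"]),
            planted_partition=np.asarray(payload["planted_partition"]),
            target_corr={
                tuple(key.split("|")): np.asarray(mat)
                for key, mat in payload["target_corr"].items()
            },
            hub_nodes=frozenset(payload["hub_nodes"]),
            global_amp=payload["global_amp"],
            drift_slope_sd=payload["drift_slope_sd"],
            ar_coeff=payload["ar_coeff"],
            noise_sd=payload["noise_sd"],
            repair_delta={
                tuple(key.split("|")): d for key, d in payload.get("repair_delta", {}).items()
            },
        )


@dataclass(frozen=True)
class TrialRecord:
    """One working-memory trial with a filtering component.

    Five stimuli on a 16-position grid: three targets to remember and
    two distractors to ignore.  A catch trial probes a distractor
    location; a "yes" response there is a cognitive inhibition error.
    ``response`` may be None for a missing response.
    """

    index: int
    targets: tuple[int, ...]
    distractors: tuple[int, ...]
    probe: int
    is_catch: bool
    response: bool | None
    reaction_time: float
    correct: bool

    def __post_init__(self):
        if set(self.targets) & set(self.distractors):
            raise ValueError("target and distractor locations must be disjoint")
        if self.is_catch != (self.probe in self.distractors):
            raise ValueError("is_catch must hold iff probe is at a distractor location")
        if self.response is not None:
            expected = (self.response is True) == (self.probe in self.targets)
            if self.correct != expected:
                raise ValueError("correct flag inconsistent with response and probe")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    rating: float
    timeseries: dict[str, RoiTimeSeriesSet]
    trials: dict[str, list[TrialRecord]]


@dataclass
class CohortDataset:
    """A full synthetic cohort: subjects plus the generative spec."""

    subjects: list[SubjectRecord]
    spec: GroundTruthSpec

    def __post_init__(self):
        for sub in self.subjects:
            if set(sub.timeseries) != set(PARADIGMS):
                raise ValueError(f"{sub.subject_id} must have exactly the two paradigms")
            shapes = {ts.data.shape for ts in sub.timeseries.values()}
            trs = {ts.tr for ts in sub.timeseries.values()}
            if len(shapes) != 1 or len(trs) != 1:
                raise ValueError(f"{sub.subject_id} paradigms differ in n_volumes or TR")

    def ratings(self) -> np.ndarray:
        return np.array([s.rating for s in self.subjects])

    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]


# ---------------------------------------------------------------------------
# target-matrix construction


def nearest_unit_diagonal_psd(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Repair a symmetric matrix to unit-diagonal PSD.

    Eigenvalues are clipped at zero and the result rescaled to unit
    diagonal.  Returns the repaired matrix and the largest absolute
    entry change.  Raises if the repair degenerates (zero diagonal).
    """
    matrix = np.asarray(matrix, dtype=float)
    sym = 0.5 * (matrix + matrix.T)
    vals, vecs = np.linalg.eigh(sym)
    clipped = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    diag = np.diag(clipped).copy()
    if np.any(diag <= 1e-12):
        bad = np.flatnonzero(diag <= 1e-12).tolist()
        raise ValueError(
            f"PSD repair degenerated: zero diagonal at node indices {bad}; "
            "requested correlations are not jointly realizable"
        )
    scale = 1.0 / np.sqrt(diag)
    repaired = clipped * np.outer(scale, scale)
    np.fill_diagonal(repaired, 1.0)
    repaired = np.clip(0.5 * (repaired + repaired.T), -1.0, 1.0)
    delta = float(np.abs(repaired - sym).max())
    return repaired, delta


def _check_entries(matrix: np.ndarray, cell, limit: float = 1.0) -> None:
    off = matrix.copy()
    np.fill_diagonal(off, 0.0)
    bad = np.argwhere(np.abs(off) > limit)
    if len(bad):
        pairs = sorted({tuple(sorted(p)) for p in map(tuple, bad)})
        raise ValueError(
            f"target correlations exceed |r| = {limit} in cell {cell} at entries {pairs}"
        )


def make_ground_truth(
    n_rois: int = 20,
    partition: np.ndarray | None = None,
    within_corr: float = 0.3,
    between_corr: float = -0.15,
    hub_spec: dict[int, tuple[float, float]] | None = None,
    condition_effects: list[EdgeEffect] | None = None,
    group_effect_scale: float = 1.0,
    roi_order: list[str] | None = None,
    global_amp: float = 1.0,
    drift_slope_sd: float = 0.01,
    ar_coeff: float = 0.3,
    noise_sd: float = 1.0,
) -> GroundTruthSpec:
    """Build target correlation matrices for every (paradigm x group) cell.

    The base matrix is block-constant: ``within_corr`` inside each
    planted community, ``between_corr`` across communities.  ``hub_spec``
    maps a node index to ``(within_strength, cross_strength)`` coupling
    magnitudes that replace the base values on that node's rows (the
    cross strength is applied with the between-module sign).  Condition
    effects then add signed increments to named edges in specific cells;
    group-specific deltas are multiplied by ``group_effect_scale``.
    Each resulting matrix is repaired to the nearest unit-diagonal PSD
    matrix and the repair magnitude logged.
    """
    if not (0.0 < within_corr < 1.0):
        raise ValueError("within_corr must lie in (0, 1)")
    if not (-1.0 < between_corr <= 0.0):
        raise ValueError("between_corr must lie in (-1, 0]")
    if roi_order is None:
        roi_order = [f"ROI{i:02d}" for i in range(n_rois)]
    if len(roi_order) != n_rois:
        raise ValueError("roi_order length must equal n_rois")
    if partition is None:
        half = n_rois // 2
        partition = np.array([0] * half + [1] * (n_rois - half))
    partition = np.asarray(partition, dtype=np.int64)
    if partition.shape != (n_rois,):
        raise ValueError("partition must cover every node exactly once")
    hub_spec = dict(hub_spec or {})
    condition_effects = list(condition_effects or [])
    index = {name: i for i, name in enumerate(roi_order)}

    same = partition[:, None] == partition[None, :]
    base = np.where(same, within_corr, between_corr)
    np.fill_diagonal(base, 1.0)

    # hub rows: elevated |coupling|, cross-module entries keep the
    # between-module sign
    sign_between = -1.0 if between_corr < 0 else 1.0
    for node, (hub_within, hub_cross) in hub_spec.items():
        for j in range(n_rois):
            if j == node:
                continue
            if same[node, j]:
                val = max(abs(base[node, j]), hub_within)
            else:
                val = sign_between * max(abs(base[node, j]), hub_cross)
            base[node, j] = base[j, node] = val

    target_corr: dict[tuple[str, str], np.ndarray] = {}
    repair_delta: dict[tuple[str, str], float] = {}
    for paradigm in PARADIGMS:
        for group in GROUPS:
            mat = base.copy()
            for eff in condition_effects:
                if eff.paradigm != paradigm:
                    continue
                if eff.group is not None and eff.group != group:
                    continue
                scale = group_effect_scale if eff.group is not None else 1.0
                a, b = eff.edge
                ia = index[a] if isinstance(a, str) else int(a)
                ib = index[b] if isinstance(b, str) else int(b)
                if ia == ib:
                    raise ValueError(f"condition effect on a self-edge: {eff.edge}")
                mat[ia, ib] += scale * eff.delta
                mat[ib, ia] = mat[ia, ib]
            _check_entries(mat, (paradigm, group))
            repaired, delta = nearest_unit_diagonal_psd(mat)
            target_corr[(paradigm, group)] = repaired
            repair_delta[(paradigm, group)] = delta

    return GroundTruthSpec(
        n_rois=n_rois,
        roi_order=list(roi_order),
        planted_partition=partition,
        target_corr=target_corr,
        hub_nodes=frozenset(int(k) for k in hub_spec),
        global_amp=global_amp,
        drift_slope_sd=drift_slope_sd,
        ar_coeff=ar_coeff,
        noise_sd=noise_sd,
        repair_delta=repair_delta,
    )


def default_ground_truth(**overrides) -> GroundTruthSpec:
    """Ground truth of the default 20-ROI cohort.

    Planted structure: the anatomical dorsal/ventral split with
    within r = +0.30 and between r = -0.15; connector hubs dlPFCl and
    mFPl with elevated couplings (0.40 within, 0.35 across); a
    segregation shift in the sadness paradigm for both groups
    (within-module couplings weaken by 0.06, between-module
    anticorrelations strengthen by 0.02 - a net decrease in
    integration); and high-sadness-group-only edge shifts of -0.30 on
    sACCl-dlPFCl and +0.20 on sACCl-mFPl in the sadness paradigm.
    """
    table = load_roi_table()
    roi_order = list(table["abbrev"])
    partition, _ = pd.factorize(table["community"])
    index = {name: i for i, name in enumerate(roi_order)}

    effects = [
        EdgeEffect(("sACCl", "dlPFCl"), "Sadness-WM2", -0.30, group="high-sadness"),
        EdgeEffect(("sACCl", "mFPl"), "Sadness-WM2", +0.20, group="high-sadness"),
    ]
    # paradigm-wide segregation shift after sadness induction (both groups):
    # weaker within-module coupling, slightly stronger between-module
    # anticorrelation
    part = np.asarray(partition)
    for i in range(len(roi_order)):
        for j in range(i + 1, len(roi_order)):
            delta = -0.06 if part[i] == part[j] else -0.02
            effects.append(
                EdgeEffect((roi_order[i], roi_order[j]), "Sadness-WM2", delta)
            )

    defaults = dict(
        n_rois=len(roi_order),
        partition=part,
        within_corr=0.3,
        between_corr=-0.15,
        hub_spec={index["dlPFCl"]: (0.40, 0.35), index["mFPl"]: (0.40, 0.35)},
        condition_effects=effects,
        roi_order=roi_order,
    )
    defaults.update(overrides)
    return make_ground_truth(**defaults)


# ---------------------------------------------------------------------------
# time-series simulation


def _ar1_series(rng: np.random.Generator, n: int, coeff: float, shape=()) -> np.ndarray:
    """Stationary unit-variance AR(1) noise, vectorized over `shape`."""
    innov = rng.standard_normal((n, *shape))
    if coeff == 0.0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = math.sqrt(1.0 - coeff**2)
    for t in range(1, n):
        out[t] = coeff * out[t - 1] + scale * innov[t]
    return out


def simulate_subject_timeseries(
    spec: GroundTruthSpec,
    cell: tuple[str, str],
    n_volumes: int = 160,
    tr: float = 2.0,
    seed=None,
    subject_id: str = "sim",
) -> RoiTimeSeriesSet:
    """Draw one paradigm's ROI time-series matrix for one cell.

    Correlated Gaussian innovations with the cell's target correlation
    receive AR(1) temporal coloring (same coefficient on every ROI, so
    zero-lag correlations are preserved), then a shared AR(1) nuisance
    series is added identically to all ROIs with amplitude
    ``global_amp``, plus an independent linear drift per ROI whose
    slope is drawn with SD ``drift_slope_sd`` per volume.
    """
    cell = tuple(cell)
    if cell not in spec.target_corr:
        available = sorted(spec.target_corr)
        raise KeyError(f"cell {cell} not in spec; available cells: {available}")
    if n_volumes < 8:
        raise ValueError("n_volumes must be at least 8")
    if seed is None:
        raise ValueError("a seed (int, SeedSequence or Generator) is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    target = spec.target_corr[cell]
    vals, vecs = np.linalg.eigh(target)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))  # target = factor @ factor.T

    colored = _ar1_series(rng, n_volumes, spec.ar_coeff, shape=(spec.n_rois,))
    signal = spec.noise_sd * (colored @ factor.T)

    if spec.global_amp > 0:
        nuisance = _ar1_series(rng, n_volumes, spec.ar_coeff)
        signal = signal + spec.global_amp * nuisance[:, None]
    if spec.drift_slope_sd > 0:
        slopes = rng.normal(0.0, spec.drift_slope_sd, size=spec.n_rois)
        t = np.arange(n_volumes) - (n_volumes - 1) / 2.0
        signal = signal + t[:, None] * slopes[None, :]

    return RoiTimeSeriesSet(
        subject_id=subject_id,
        paradigm=cell[0],
        data=signal,
        tr=tr,
        roi_order=list(spec.roi_order),
    )


# ---------------------------------------------------------------------------
# behavior simulation


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_wm_block(
    n_trials: int = 20,
    catch_fraction: float = 0.25,
    p_error: float = 0.12,
    p_inhibition_error: float = 0.27,
    rt_mean: float = 1.33,
    rt_sd: float = 0.25,
    seed=None,
    grid_size: int = GRID_SIZE,
) -> list[TrialRecord]:
    """Simulate one block of spatial working-memory trials.

    Exactly ``round(n_trials * catch_fraction)`` trials (round half up)
    probe a distractor location; a "yes" there occurs with probability
    ``p_inhibition_error``.  Non-catch trials probe a target or an
    unoccupied location with equal probability and are answered
    incorrectly with probability ``p_error``.  Reaction times are
    truncated-normal (positive).
    """
    if not (0.0 <= catch_fraction <= 1.0):
        raise ValueError("catch_fraction must lie in [0, 1]")
    if grid_size < N_TARGETS + N_DISTRACTORS + 1:
        raise ValueError(
            f"grid of {grid_size} positions cannot hold {N_TARGETS} targets, "
            f"{N_DISTRACTORS} distractors and an empty probe location"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_catch = _round_half_up(n_trials * catch_fraction)
    catch_idx = set(rng.choice(n_trials, size=n_catch, replace=False).tolist())

    if rt_sd > 0:
        a = (0.0 - rt_mean) / rt_sd
        rts = sps.truncnorm.rvs(a, np.inf, loc=rt_mean, scale=rt_sd, size=n_trials, random_state=rng)
    else:
        rts = np.full(n_trials, rt_mean)

    trials = []
    for i in range(n_trials):
        shown = rng.choice(grid_size, size=N_TARGETS + N_DISTRACTORS, replace=False)
        targets = tuple(int(v) for v in shown[:N_TARGETS])
        distractors = tuple(int(v) for v in shown[N_TARGETS:])
        is_catch = i in catch_idx
        if is_catch:
            probe = int(rng.choice(distractors))
            response = bool(rng.random() < p_inhibition_error)  # "yes" = error
        else:
            if rng.random() < 0.5:
                probe = int(rng.choice(targets))
            else:
                empty = np.setdiff1d(np.arange(grid_size), shown)
                probe = int(rng.choice(empty))
            truth = probe in targets
            wrong = rng.random() < p_error
            response = truth != wrong
        correct = (response is True) == (probe in targets)
        trials.append(
            TrialRecord(
                index=i,
                targets=targets,
                distractors=distractors,
                probe=probe,
                is_catch=is_catch,
                response=response,
                reaction_time=float(rts[i]),
                correct=correct,
            )
        )
    return trials


def simulate_sadness_ratings(
    n: int,
    mix_means: tuple[float, float] = DEFAULT_RATING_MEANS,
    mix_sds: tuple[float, float] = DEFAULT_RATING_SDS,
    mix_weight: float = DEFAULT_RATING_WEIGHT,
    scale_max: float = 7.0,
    seed=None,
) -> np.ndarray:
    """Two-component Gaussian mixture of ratings, clipped to [0, scale_max]."""
    if not (0.0 < mix_weight < 1.0):
        raise ValueError("mix_weight must lie strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    component = (rng.random(n) >= mix_weight).astype(int)  # 0 = first component
    means = np.asarray(mix_means)[component]
    sds = np.asarray(mix_sds)[component]
    ratings = rng.normal(means, sds)
    return np.clip(ratings, 0.0, scale_max)


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(
    spec: GroundTruthSpec | None = None,
    n_subjects_high: int = 12,
    n_subjects_low: int = 10,
    n_volumes: int = 160,
    tr: float = 2.0,
    seed: int = 0,
    rating_means: tuple[float, float] = DEFAULT_RATING_MEANS,
    rating_sds: tuple[float, float] = DEFAULT_RATING_SDS,
    wm_params: dict | None = None,
    max_rating_retries: int = 100,
) -> CohortDataset:
    """Simulate a full two-paradigm cohort.

    Each subject receives a rating from their group's mixture
    component, both paradigms' time series from the matching
    (paradigm x group) cell, and one trial table per paradigm.  The
    rating vector is redrawn (bounded retries) until the above-the-mean
    split rule reproduces the intended group labels, so labels
    round-trip through the behavioral split.
    """
    from .behavior import split_sadness_groups

    if n_subjects_high < 1 or n_subjects_low < 1:
        raise ValueError("both group sizes must be at least 1")
    if spec is None:
        spec = default_ground_truth()
    wm = dict(DEFAULT_WM_PARAMS)
    wm.update(wm_params or {})

    master = np.random.SeedSequence(seed)
    rating_ss, subjects_ss = master.spawn(2)
    n_total = n_subjects_high + n_subjects_low
    intended = ["high-sadness"] * n_subjects_high + ["low-sadness"] * n_subjects_low

    rating_rng = np.random.default_rng(rating_ss)
    ratings = None
    for _ in range(max_rating_retries):
        cand = np.empty(n_total)
        for i, grp in enumerate(intended):
            comp = 0 if grp == "high-sadness" else 1
            cand[i] = np.clip(
                rating_rng.normal(rating_means[comp], rating_sds[comp]), 0.0, 7.0
            )
        labels, _ = split_sadness_groups(cand)
        if labels == intended:
            ratings = cand
            break
    if ratings is None:
        raise RuntimeError(
            "could not draw ratings whose mean split reproduces the intended "
            f"groups in {max_rating_retries} attempts; mixture components overlap too much"
        )

    subject_streams = subjects_ss.spawn(n_total)
    subjects = []
    for i, (grp, sub_ss) in enumerate(zip(intended, subject_streams)):
        sid = f"sub-{i + 1:02d}"
        rng = np.random.default_rng(sub_ss)
        rt_mean_i = max(0.4, rng.normal(wm["rt_mean"], 0.12))
        timeseries = {}
        trials = {}
        for paradigm in PARADIGMS:
            ts = simulate_subject_timeseries(
                spec, (paradigm, grp), n_volumes=n_volumes, tr=tr, seed=rng, subject_id=sid
            )
            timeseries[paradigm] = ts
            trials[paradigm] = simulate_wm_block(
                n_trials=wm["n_trials"],
                catch_fraction=wm["catch_fraction"],
                p_error=wm["p_error"],
                p_inhibition_error=wm["p_inhibition_error"],
                rt_mean=rt_mean_i,
                rt_sd=wm["rt_sd"],
                seed=rng,
            )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=grp,
                rating=float(ratings[i]),
                timeseries=timeseries,
                trials=trials,
            )
        )
    return CohortDataset(subjects=subjects, spec=spec)


# ---------------------------------------------------------------------------
# cohort directory I/O


def _trials_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "trial": t.index,
                "targets": ",".join(map(str, t.targets)),
                "distractors": ",".join(map(str, t.distractors)),
                "probe": t.probe,
                "is_catch": int(t.is_catch),
                "response": "" if t.response is None else ("yes" if t.response else "no"),
                "reaction_time": t.reaction_time,
                "correct": int(t.correct),
            }
        )
    return pd.DataFrame(rows)


def _trials_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for _, row in frame.iterrows():
        resp = row["response"]
        if pd.isna(resp) or resp == "":
            response = None
        else:
            response = str(resp) == "yes"
        trials.append(
            TrialRecord(
                index=int(row["trial"]),
                targets=tuple(int(v) for v in str(row["targets"]).split(",")),
                distractors=tuple(int(v) for v in str(row["distractors"]).split(",")),
                probe=int(row["probe"]),
                is_catch=bool(row["is_catch"]),
                response=response,
                reaction_time=float(row["reaction_time"]),
                correct=bool(row["correct"]),
            )
        )
    return trials


def write_cohort(dataset: CohortDataset, out_dir) -> Path:
    """Write a cohort directory: ROI table, per-subject TSVs, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    load_roi_table().to_csv(out / "roi_table.tsv", sep="\t", index=False)

    participants = []
    for sub in dataset.subjects:
        participants.append(
            {"participant_id": sub.subject_id, "group": sub.group, "rating": sub.rating}
        )
        for paradigm in PARADIGMS:
            ts = sub.timeseries[paradigm]
            ts.to_tsv(out / f"{sub.subject_id}_{paradigm}_timeseries.tsv")
            _trials_frame(sub.trials[paradigm]).to_csv(
                out / f"{sub.subject_id}_{paradigm}_trials.tsv", sep="\t", index=False
            )
    pd.DataFrame(participants).to_csv(out / "participants.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(dataset.spec.to_dict(), fh, indent=1, sort_keys=True)
    return out


def read_cohort(in_dir, tr: float = 2.0) -> CohortDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    with open(root / "ground_truth.json") as fh:
        spec = GroundTruthSpec.from_dict(json.load(fh))
    participants = pd.read_csv(root / "participants.tsv", sep="\t")
    subjects = []
    for _, row in participants.iterrows():
        sid = row["participant_id"]
        timeseries = {}
        trials = {}
        for paradigm in PARADIGMS:
            timeseries[paradigm] = RoiTimeSeriesSet.from_tsv(
                root / f"{sid}_{paradigm}_timeseries.tsv", sid, paradigm, tr
            )
            trials[paradigm] = _trials_from_frame(
                pd.read_csv(root / f"{sid}_{paradigm}_trials.tsv", sep="\t")
            )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=row["group"],
                rating=float(row["rating"]),
                timeseries=timeseries,
                trials=trials,
            )
        )
    return CohortDataset(subjects=subjects, spec=spec)
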