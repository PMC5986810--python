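"""Signed-modularity communities, thresholded node metrics and hubs.

The quality function for a signed weighted graph splits the weights
into positive and negative parts w+ and w-, each with its own
degree-matched null e+/e- and resolution parameter:

    Q = (1/v+) sum_ij (w+_ij - gamma+ e+_ij) delta(c_i, c_j)
        - (1/(v+ + v-)) sum_ij (w-_ij - gamma- e-_ij) delta(c_i, c_j)

with s+-_i the signed strengths, v+- their totals and
e+-_ij = s+-_i s+-_j / v+-.  With all-nonnegative weights and
gamma+ = 1 this reduces to classical Newman-Girvan modularity.

Because Q is a sum of a fixed pairwise "gain matrix" B over
same-community pairs (Q = sum_ij B_ij delta(c_i,c_j)), both the greedy
optimizer and the exhaustive oracle evaluate partitions exactly and
cheaply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "ModularityResult",
    "HubReport",
    "signed_modularity",
    "modularity_gain_matrix",
    "exhaustive_best_partition",
    "detect_communities",
    "scan_gamma_neg",
    "threshold_matrix",
    "degree",
    "participation_coefficient",
    "select_threshold",
    "node_metrics",
    "identify_hubs",
    "hub_permutation_check",
]


def _as_weight_matrix(matrix) -> np.ndarray:
    """Coerce input to a symmetric zero-diagonal weight matrix."""
    if isinstance(matrix, ConnectivityMatrix):
        return matrix.off_diagonal()
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.abs(np.diag(w)).max(initial=0.0) > 1e-10:
        raise ValueError("weight matrix must have zero diagonal (drop self-weights first)")
    return 0.5 * (w + w.T)


def modularity_gain_matrix(matrix, gamma_pos: float = 1.0, gamma_neg: float = 1.0) -> np.ndarray:
    """Pairwise contribution matrix B with Q = sum of B over same-community pairs."""
    w = _as_weight_matrix(matrix)
    w_pos = np.clip(w, 0.0, None)
    w_neg = np.clip(-w, 0.0, None)
    v_pos = w_pos.sum()
    v_neg = w_neg.sum()
    if v_pos <= 0:
        raise ValueError("no positive weights: signed modularity is undefined (v+ = 0)")
    s_pos = w_pos.sum(axis=1)
    s_neg = w_neg.sum(axis=1)
    e_pos = np.outer(s_pos, s_pos) / v_pos
    e_neg = np.outer(s_neg, s_neg) / v_neg if v_neg > 0 else np.zeros_like(w)
    return (w_pos - gamma_pos * e_pos) / v_pos - (w_neg - gamma_neg * e_neg) / (v_pos + v_neg)


def signed_modularity(matrix, partition, gamma_pos: float = 1.0, gamma_neg: float = 1.0) -> float:
    """Quality Q of a partition of a signed weighted graph."""
    labels = np.asarray(partition)
    gain = modularity_gain_matrix(matrix, gamma_pos, gamma_neg)
    if labels.shape != (gain.shape[0],):
        raise ValueError("partition must label every node exactly once")
    same = labels[:, None] == labels[None, :]
    return float(gain[same].sum())


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Renumber community labels by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class ModularityResult:
    """Best partition found, its Q, and the settings that produced it."""

    partition: np.ndarray
    Q: float
    gamma_pos: float
    gamma_neg: float
    n_restarts: int
    seed: int | None = None
    roi_order: list[str] | None = None

    def __post_init__(self):
        self.partition = np.asarray(self.partition, dtype=np.int64)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.partition))

    def communities(self) -> dict[int, list]:
        nodes = self.roi_order if self.roi_order is not None else list(range(len(self.partition)))
        out: dict[int, list] = {}
        for node, lab in zip(nodes, self.partition):
            out.setdefault(int(lab), []).append(node)
        return out


# ---------------------------------------------------------------------------
# optimizers


def _partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=np.int64)
    maxima = np.zeros(n, dtype=np.int64)  # maxima[i] = max(labels[:i+1])
    yield labels.copy()
    while True:
        # find rightmost position that can be incremented
        i = n - 1
        while i > 0 and labels[i] > maxima[i - 1]:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxima[i] = max(maxima[i - 1], labels[i])
        labels[i + 1 :] = 0
        for j in range(i + 1, n):
            maxima[j] = maxima[j - 1]
        yield labels.copy()


def exhaustive_best_partition(
    matrix, gamma_pos: float = 1.0, gamma_neg: float = 1.0, max_nodes: int = 12
) -> tuple[np.ndarray, float]:
    """Globally optimal partition by enumerating all set partitions.

    Intended as an independent oracle for small graphs (Bell numbers
    explode; the default cap is 12 nodes).
    """
    gain = modularity_gain_matrix(matrix, gamma_pos, gamma_neg)
    n = gain.shape[0]
    if n > max_nodes:
        raise ValueError(f"exhaustive enumeration capped at {max_nodes} nodes, got {n}")
    best_q = -np.inf
    best_labels = None
    for labels in _partitions(n):
        same = labels[:, None] == labels[None, :]
        q = gain[same].sum()
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    return _canonical(best_labels), float(best_q)


def _greedy_once(gain: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One seeded greedy run: local moves (first improvement over a
    random node and candidate order) alternated with community merges."""
    n = gain.shape[0]
    labels = np.arange(n)

    def q_of(lab: np.ndarray) -> float:
        same = lab[:, None] == lab[None, :]
        return float(gain[same].sum())

    q = q_of(labels)
    changed = True
    while changed:
        changed = False
        # --- local node moves
        moved = True
        while moved:
            moved = False
            for i in rng.permutation(n):
                current = labels[i]
                # gain of i toward each community: row sums of B
                comms = np.unique(labels)
                attach = {c: gain[i, labels == c].sum() for c in comms}
                stay = attach[current] - gain[i, i]
                candidates = [c for c in comms if c != current]
                if (labels == current).sum() > 1:
                    candidates.append(int(labels.max()) + 1)  # fresh singleton
                rng.shuffle(candidates)
                for c in candidates:
                    move = attach.get(c, 0.0)
                    delta = 2.0 * (move - stay)
                    if delta > 1e-12:
                        labels[i] = c
                        q += delta
                        moved = changed = True
                        break
        # --- merge phase: apply the best strictly improving merge
        merged = True
        while merged:
            merged = False
            comms = np.unique(labels)
            best_delta, best_pair = 0.0, None
            for a_i in range(len(comms)):
                in_a = labels == comms[a_i]
                for b_i in range(a_i + 1, len(comms)):
                    in_b = labels == comms[b_i]
                    delta = 2.0 * gain[np.ix_(in_a, in_b)].sum()
                    if delta > best_delta + 1e-12:
                        best_delta, best_pair = delta, (comms[a_i], comms[b_i])
            if best_pair is not None:
                labels[labels == best_pair[1]] = best_pair[0]
                q += best_delta
                merged = changed = True
    return _canonical(labels), q_of(labels)


def detect_communities(
    matrix,
    gamma_pos: float = 1.0,
    gamma_neg: float = 0.45,
    n_restarts: int = 20,
    seed: int = 0,
    candidates: list[np.ndarray] | None = None,
) -> ModularityResult:
    """Greedy maximization of signed modularity, best of seeded restarts.

    ``candidates`` may carry known partitions (e.g. an anatomical
    grouping); they are evaluated alongside the restarts so the result
    is never worse than a supplied candidate.  Deterministic given
    ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    gain = modularity_gain_matrix(matrix, gamma_pos, gamma_neg)
    roi_order = matrix.roi_order if isinstance(matrix, ConnectivityMatrix) else None
    rng = np.random.default_rng(seed)
    best_labels, best_q = None, -np.inf
    for _ in range(n_restarts):
        labels, q = _greedy_once(gain, rng)
        if q > best_q + 1e-12:
            best_labels, best_q = labels, q
    for cand in candidates or []:
        cand = np.asarray(cand)
        same = cand[:, None] == cand[None, :]
        q = float(gain[same].sum())
        if q > best_q + 1e-12:
            best_labels, best_q = _canonical(cand), q
    return ModularityResult(
        partition=best_labels,
        Q=best_q,
        gamma_pos=gamma_pos,
        gamma_neg=gamma_neg,
        n_restarts=n_restarts,
        seed=seed,
        roi_order=roi_order,
    )


def _separates(labels: np.ndarray, grouping: np.ndarray) -> bool:
    """True if no community mixes nodes from different anatomical groups."""
    for c in np.unique(labels):
        if len(np.unique(grouping[labels == c])) > 1:
            return False
    return True


def scan_gamma_neg(
    mean_matrix_by_paradigm: dict,
    gamma_neg_grid,
    gamma_pos: float = 1.0,
    n_restarts: int = 20,
    seed: int = 0,
    anatomical_grouping: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan the negative resolution parameter over group-mean matrices.

    One row per gamma- value (sorted), with per-paradigm partition and
    Q, the Q contrast between the two paradigms, and - when an
    anatomical grouping is supplied - a flag per paradigm marking
    partitions that keep the anatomical groups separate.  The attribute
    ``selected_gamma_neg`` holds the grid value with the largest
    absolute Q contrast.
    """
    grid = sorted(float(g) for g in np.atleast_1d(gamma_neg_grid))
    if not grid:
        raise ValueError("gamma_neg_grid must be nonempty")
    paradigms = list(mean_matrix_by_paradigm)
    rows = []
    for g_neg in grid:
        row: dict = {"gamma_neg": g_neg}
        q_values = []
        for paradigm in paradigms:
            res = detect_communities(
                mean_matrix_by_paradigm[paradigm],
                gamma_pos=gamma_pos,
                gamma_neg=g_neg,
                n_restarts=n_restarts,
                seed=seed,
            )
            row[f"Q_{paradigm}"] = res.Q
            row[f"partition_{paradigm}"] = tuple(int(v) for v in res.partition)
            if anatomical_grouping is not None:
                row[f"separates_anatomical_{paradigm}"] = _separates(
                    res.partition, np.asarray(anatomical_grouping)
                )
            q_values.append(res.Q)
        if len(paradigms) == 2:
            row["q_contrast"] = q_values[1] - q_values[0]
        rows.append(row)
    table = pd.DataFrame(rows)
    if "q_contrast" in table:
        best = table.loc[table["q_contrast"].abs().idxmax(), "gamma_neg"]
        table.attrs["selected_gamma_neg"] = float(best)
    return table


# ---------------------------------------------------------------------------
# thresholded node metrics


def threshold_matrix(matrix, threshold_pct: float) -> np.ndarray:
    """Binarize: keep edge (i, j) iff |w_ij| >= (pct/100) * max |w|.

    The reference maximum is the matrix's own largest absolute
    off-diagonal weight, so the threshold adapts per subject.
    """
    if not (0.0 < threshold_pct < 100.0):
        raise ValueError("threshold_pct must lie strictly between 0 and 100")
    w = _as_weight_matrix(matrix)
    strongest = np.abs(w).max()
    if strongest <= 0:
        raise ValueError("all-zero matrix: no edges to threshold")
    cutoff = (threshold_pct / 100.0) * strongest
    adjacency = (np.abs(w) >= cutoff).astype(np.int64)
    np.fill_diagonal(adjacency, 0)
    return adjacency


def degree(adjacency: np.ndarray) -> np.ndarray:
    """Binary degree: row sums of the 0/1 adjacency matrix."""
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
        raise ValueError("adjacency must be symmetric 0/1 with zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return a.sum(axis=1).astype(np.int64)


def participation_coefficient(adjacency: np.ndarray, partition) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2 over communities s; P_i = 0 if k_i = 0."""
    labels = np.asarray(partition)
    a = np.asarray(adjacency, dtype=float)
    if labels.shape != (a.shape[0],):
        raise ValueError("partition must cover all nodes")
    k = a.sum(axis=1)
    onehot = (labels[None, :] == np.unique(labels)[:, None]).astype(float)  # (m, n)
    k_is = a @ onehot.T  # (n, m): edges from i into community s
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_is / k[:, None], 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    p[k == 0] = 0.0
    return np.clip(p, 0.0, 1.0)


def select_threshold(matrices, grid_pct=None) -> tuple[float, pd.DataFrame]:
    """Pick the threshold maximizing across-node variance of mean degree.

    For each grid value every subject matrix is thresholded, per-node
    degrees averaged across subjects, and the across-node variance of
    these averages recorded.  Ties break toward the smaller threshold.
    Returns the winning percentage and the full grid table.
    """
    if grid_pct is None:
        grid_pct = np.arange(5, 100, 5)
    grid = [float(g) for g in np.atleast_1d(grid_pct)]
    if any(not (0.0 < g < 100.0) for g in grid):
        raise ValueError("grid values must lie strictly between 0 and 100")
    grid = sorted(grid)
    rows = []
    for pct in grid:
        degrees = np.stack([degree(threshold_matrix(m, pct)) for m in matrices])
        node_means = degrees.mean(axis=0)
        rows.append({"threshold_pct": pct, "degree_variance": float(node_means.var(ddof=1))})
    table = pd.DataFrame(rows)
    if np.allclose(table["degree_variance"], table["degree_variance"].iloc[0]):
        warnings.warn("degree variance is flat across the grid; returning the smallest threshold")
    best = float(table.loc[table["degree_variance"].idxmax(), "threshold_pct"])
    return best, table


def node_metrics(
    matrices: list[ConnectivityMatrix],
    partition,
    threshold_pct: float,
) -> pd.DataFrame:
    """Per-subject, per-node degree and participation at one threshold.

    The partition (typically detected on the group-mean matrix) is
    applied to every subject's thresholded graph.
    """
    labels = np.asarray(partition)
    frames = []
    for mat in matrices:
        adjacency = threshold_matrix(mat, threshold_pct)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": mat.subject_id,
                    "paradigm": mat.paradigm,
                    "roi": mat.roi_order,
                    "degree": degree(adjacency),
                    "participation": participation_coefficient(adjacency, labels),
                    "threshold_pct": threshold_pct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class HubReport:
    """Connector-hub flags and the statistics behind them.

    A node is flagged iff its across-subject mean degree exceeds the
    network mean degree by more than one SD (mean and SD taken across
    nodes of the node means) AND its mean participation exceeds the
    network mean participation.
    """

    paradigm: str
    roi_order: list[str]
    mean_degree: np.ndarray
    network_mean_degree: float
    network_degree_sd: float
    mean_participation: np.ndarray
    network_mean_participation: float
    hubs: list[str]
    p_values: np.ndarray
    threshold_pct: float | None = None
    hub_flags: np.ndarray = field(init=False)

    def __post_init__(self):
        self.hub_flags = np.array([roi in set(self.hubs) for roi in self.roi_order])

    def to_dict(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "roi_order": list(self.roi_order),
            "mean_degree": [float(v) for v in self.mean_degree],
            "network_mean_degree": self.network_mean_degree,
            "network_degree_sd": self.network_degree_sd,
            "mean_participation": [float(v) for v in self.mean_participation],
            "network_mean_participation": self.network_mean_participation,
            "hubs": list(self.hubs),
            "p_values": [float(v) for v in self.p_values],
            "threshold_pct": self.threshold_pct,
        }


def hub_permutation_check(subject_degrees: np.ndarray, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Per-node p for 'mean degree this high by chance' under exchangeability.

    The null shuffles each subject's degree values across nodes, which
    preserves every subject's degree distribution while destroying node
    identity.  p = (b + 1) / (n_perm + 1) with b the number of
    resamples whose node mean meets or exceeds the observed node mean.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    degrees = np.asarray(subject_degrees, dtype=float)
    if degrees.ndim != 2:
        raise ValueError("subject_degrees must be (n_subjects, n_nodes)")
    rng = np.random.default_rng(seed)
    observed = degrees.mean(axis=0)
    exceed = np.zeros(degrees.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        shuffled = np.stack([rng.permutation(row) for row in degrees])
        exceed += shuffled.mean(axis=0) >= observed - 1e-12
    return (exceed + 1) / (n_perm + 1)


def identify_hubs(
    metrics: pd.DataFrame,
    paradigm: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> HubReport:
    """Flag connector hubs from a per-subject node-metrics table.

    Expects the frame produced by :func:`node_metrics` (columns
    subject_id, paradigm, roi, degree, participation).  Degrees are
    averaged per node across subjects; the hub rule compares each node
    mean against the across-node mean + 1 SD of those means, and the
    node's mean participation against the across-node mean
    participation.  A permutation check on the degree table is reported
    alongside.
    """
    frame = metrics if paradigm is None else metrics[metrics["paradigm"] == paradigm]
    if frame.empty:
        raise ValueError(f"no rows for paradigm {paradigm!r}")
    if frame["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects to identify hubs")
    deg = frame.pivot_table(index="subject_id", columns="roi", values="degree", sort=False)
    part = frame.pivot_table(index="subject_id", columns="roi", values="participation", sort=False)
    roi_order = list(dict.fromkeys(frame["roi"]))
    deg = deg[roi_order]
    part = part[roi_order]

    mean_degree = deg.mean(axis=0).to_numpy()
    mean_participation = part.mean(axis=0).to_numpy()
    net_mean_deg = float(mean_degree.mean())
    net_sd_deg = float(mean_degree.std(ddof=1))
    net_mean_part = float(mean_participation.mean())

    flags = (mean_degree > net_mean_deg + net_sd_deg) & (mean_participation > net_mean_part)
    p_values = hub_permutation_check(deg.to_numpy(), n_perm=n_perm, seed=seed)

    thr = frame["threshold_pct"].iloc[0] if "threshold_pct" in frame else None
    return HubReport(
        paradigm=paradigm if paradigm is not None else "all",
        roi_order=roi_order,
        mean_degree=mean_degree,
        network_mean_degree=net_mean_deg,
        network_degree_sd=net_sd_deg,
        mean_participation=mean_participation,
        network_mean_participation=net_mean_part,
        hubs=[roi for roi, f in zip(roi_order, flags) if f],
        p_values=p_values,
        threshold_pct=float(thr) if thr is not None else None,
    )
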