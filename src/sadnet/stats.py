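"""Condition x group statistics: mixed ANOVA, FDR, permutation tests.

The workhorse is a balanced two-paradigm repeated-measures ANOVA with
subject as a blocking (random) factor nested in a two-level
between-subject group.  The paradigm x group interaction is the
quantity of interest throughout: it is what ties an effect to the
sadness-intensity report rather than to task order.  A subject-wise
permutation version of the interaction test is available as a
distribution-free fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

__all__ = [
    "PermutationResult",
    "interaction_anova",
    "permutation_interaction_test",
    "fdr_adjust",
    "permutation_group_diff",
    "edge_condition_tests",
    "compare_group_correlations",
]


@dataclass
class PermutationResult:
    """Observed statistic plus its add-one permutation p-value."""

    observed: float
    n_perm: int
    p: float
    seed: int | None
    tail: str

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")


def _check_layout(subject, paradigm, group):
    """Validate the repeated-measures layout; return wide-format pieces."""
    frame = pd.DataFrame(
        {"subject": subject, "paradigm": paradigm, "group": group}
    )
    bad = []
    for sid, sub in frame.groupby("subject", sort=False):
        if sorted(sub["paradigm"].unique()) != sorted(frame["paradigm"].unique()) or len(sub) != len(
            frame["paradigm"].unique()
        ):
            bad.append(sid)
        if sub["group"].nunique() != 1:
            raise ValueError(f"group label changes within subject {sid!r}")
    if bad:
        raise ValueError(f"subjects without both paradigms: {bad}")
    paradigms = list(dict.fromkeys(frame["paradigm"]))
    if len(paradigms) != 2:
        raise ValueError(f"expected exactly 2 paradigms, got {paradigms}")
    groups = list(dict.fromkeys(frame["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    return frame, paradigms, groups


def interaction_anova(values, subject, paradigm, group) -> pd.DataFrame:
    """Mixed (split-plot) ANOVA for a 2-paradigm x 2-group design.

    Subject is the blocking random factor: the group effect is tested
    against between-subject variation, paradigm and the paradigm x
    group interaction against the within-subject residual.  Returns a
    table with one row per effect (``group``, ``paradigm``,
    ``interaction``) carrying sums of squares, dfs, F and p.
    """
    values = np.asarray(values, dtype=float)
    frame, paradigms, groups = _check_layout(subject, paradigm, group)
    frame = frame.assign(y=values)

    k = 2  # paradigms
    n_subjects = frame["subject"].nunique()
    n_groups = len(groups)
    grand = frame["y"].mean()

    subj_means = frame.groupby("subject", sort=False)["y"].mean()
    group_of = frame.groupby("subject", sort=False)["group"].first()
    group_means = frame.groupby("group", sort=False)["y"].mean()
    group_sizes = group_of.value_counts()
    paradigm_means = frame.groupby("paradigm", sort=False)["y"].mean()
    cell_means = frame.groupby(["group", "paradigm"], sort=False)["y"].mean()

    ss_subjects = k * float(((subj_means - grand) ** 2).sum())
    ss_group = k * float(
        sum(group_sizes[g] * (group_means[g] - grand) ** 2 for g in groups)
    )
    ss_error_between = ss_subjects - ss_group
    ss_paradigm = n_subjects * float(((paradigm_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            group_sizes[g] * (cell_means[(g, p)] - grand) ** 2
            for g in groups
            for p in paradigms
        )
    )
    ss_interaction = ss_cells - ss_group - ss_paradigm
    ss_total = float(((frame["y"] - grand) ** 2).sum())
    ss_error_within = ss_total - ss_subjects - ss_paradigm - ss_interaction

    df_group = n_groups - 1
    df_eb = n_subjects - n_groups
    df_paradigm = k - 1
    df_interaction = (n_groups - 1) * (k - 1)
    df_ew = (n_subjects - n_groups) * (k - 1)

    ms_eb = ss_error_between / df_eb
    ms_ew = ss_error_within / df_ew

    rows = []
    for name, ss, df, ms_err, df_err in [
        ("group", ss_group, df_group, ms_eb, df_eb),
        ("paradigm", ss_paradigm, df_paradigm, ms_ew, df_ew),
        ("interaction", ss_interaction, df_interaction, ms_ew, df_ew),
    ]:
        ms = ss / df
        f_stat = ms / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(f_stat, df, df_err)) if np.isfinite(f_stat) else 0.0
        rows.append(
            {"effect": name, "ss": ss, "df": df, "df_error": df_err, "F": f_stat, "p": p}
        )
    return pd.DataFrame(rows).set_index("effect")


def _paradigm_differences(values, subject, paradigm, group, paradigms):
    """Per-subject difference (paradigm 2 - paradigm 1) and group labels."""
    frame = pd.DataFrame(
        {"subject": subject, "paradigm": paradigm, "group": group, "y": np.asarray(values, dtype=float)}
    )
    wide = frame.pivot_table(index="subject", columns="paradigm", values="y", sort=False)
    group_of = frame.groupby("subject", sort=False)["group"].first()
    d = (wide[paradigms[1]] - wide[paradigms[0]]).to_numpy()
    return d, group_of.to_numpy()


def permutation_interaction_test(
    values, subject, paradigm, group, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Permutation version of the paradigm x group interaction.

    The interaction reduces to a two-sample comparison of per-subject
    paradigm differences; the null flips each subject's paradigm labels
    independently (a sign flip of the difference), which respects the
    within-subject pairing.  Two-tailed.
    """
    frame, paradigms, _ = _check_layout(subject, paradigm, group)
    d, glabels = _paradigm_differences(values, subject, paradigm, group, paradigms)
    gnames = list(dict.fromkeys(glabels))
    in_a = glabels == gnames[0]

    def stat(diff):
        return abs(diff[in_a].mean() - diff[~in_a].mean())

    observed = stat(d)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=d.shape)
        b += stat(d * signs) >= observed - 1e-15
    return PermutationResult(
        observed=float(observed), n_perm=n_perm, p=(b + 1) / (n_perm + 1), seed=seed, tail="two"
    )


def fdr_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def permutation_group_diff(
    stat_fn, data, labels, n_perm: int = 1000, tail: str = "two", seed: int = 0
) -> PermutationResult:
    """Label-shuffling null for an arbitrary two-group statistic.

    ``stat_fn(data, labels) -> float`` is evaluated on the observed
    labels and on ``n_perm`` random relabelings.  ``tail="two"``
    compares absolute values, ``tail="one"`` counts resamples at or
    above the observed statistic.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) != 2 or counts.min() < 2:
        raise ValueError("need two groups with at least 2 members each")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = float(stat_fn(data, labels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat_fn(data, rng.permutation(labels))
    if np.ptp(null) == 0 and null[0] == observed:
        warnings.warn("statistic is constant under permutation; p = 1")
    if tail == "two":
        b = int(np.sum(np.abs(null) >= abs(observed) - 1e-15))
    else:
        b = int(np.sum(null >= observed - 1e-15))
    return PermutationResult(
        observed=observed, n_perm=n_perm, p=(b + 1) / (n_perm + 1), seed=seed, tail=tail
    )


def edge_condition_tests(
    subject_matrices: dict[str, dict[str, ConnectivityMatrix]],
    hub_node: str,
    groups: dict[str, str],
    alpha: float = 0.05,
    followup: bool = True,
) -> pd.DataFrame:
    """Interaction tests on every edge incident to a connector hub.

    ``subject_matrices`` maps subject -> paradigm -> connectivity
    matrix; each of the hub's n-1 edges gets a mixed ANOVA on its r
    values with factors paradigm and group, FDR-corrected across the
    n-1 tests.  For FDR-significant edges a follow-up paired t-test
    across paradigms is run within each group.
    """
    subjects = list(subject_matrices)
    first = next(iter(subject_matrices.values()))
    paradigms = list(first)
    roi_order = first[paradigms[0]].roi_order
    if hub_node not in roi_order:
        raise ValueError(f"hub node {hub_node!r} not among ROIs")
    hub_idx = roi_order.index(hub_node)
    others = [r for r in roi_order if r != hub_node]
    group_names = list(dict.fromkeys(groups[s] for s in subjects))

    rows = []
    for other in others:
        other_idx = roi_order.index(other)
        values, subj_col, para_col, group_col = [], [], [], []
        for sid in subjects:
            for paradigm in paradigms:
                values.append(subject_matrices[sid][paradigm].values[hub_idx, other_idx])
                subj_col.append(sid)
                para_col.append(paradigm)
                group_col.append(groups[sid])
        table = interaction_anova(values, subj_col, para_col, group_col)
        row = {
            "hub": hub_node,
            "roi": other,
            "F_interaction": table.loc["interaction", "F"],
            "p_interaction": table.loc["interaction", "p"],
        }
        arr = np.asarray(values).reshape(len(subjects), len(paradigms))
        glabels = np.array([groups[s] for s in subjects])
        for gi, g in enumerate(group_names):
            for pi, p in enumerate(paradigms):
                row[f"mean_r[{g}|{p}]"] = float(arr[glabels == g, pi].mean())
        rows.append((row, arr, glabels))

    frame = pd.DataFrame([r for r, _, _ in rows])
    adjusted, reject = fdr_adjust(frame["p_interaction"].to_numpy(), alpha=alpha)
    frame["p_fdr"] = adjusted
    frame["significant"] = reject

    if followup:
        for g in group_names:
            frame[f"paired_t_p[{g}]"] = np.nan
        for i, (_, arr, glabels) in enumerate(rows):
            if not frame.loc[i, "significant"]:
                continue
            for g in group_names:
                sel = arr[glabels == g]
                t_res = sps.ttest_rel(sel[:, 1], sel[:, 0])
                frame.loc[i, f"paired_t_p[{g}]"] = float(t_res.pvalue)
    return frame


def compare_group_correlations(
    x,
    y,
    groups,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> dict:
    """Compare the x-y Pearson correlation between two subject groups.

    Returns per-group r and a permutation p for the difference
    r(first group) - r(second group), where group order follows first
    appearance in ``groups``.  ``alternative`` is "two-sided",
    "greater" or "less" on that difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(groups)
    gnames = list(dict.fromkeys(labels))
    if len(gnames) != 2:
        raise ValueError("need exactly two groups")
    for g in gnames:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")

    def r_of(mask):
        return float(np.corrcoef(x[mask], y[mask])[0, 1])

    def diff(lab):
        return r_of(lab == gnames[0]) - r_of(lab == gnames[1])

    observed = diff(labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        d = diff(perm)
        if alternative == "two-sided":
            b += abs(d) >= abs(observed) - 1e-15
        elif alternative == "greater":
            b += d >= observed - 1e-15
        else:
            b += d <= observed + 1e-15
    return {
        "r": {g: r_of(labels == g) for g in gnames},
        "observed_diff": observed,
        "p": (b + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "alternative": alternative,
        "seed": seed,
    }
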