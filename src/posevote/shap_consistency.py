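"""Per-feature Shapley probability contributions and class-consistency filtering.

Contributions are interventional Shapley values on the model's class
*probability* output, computed against a k-means-summarised background sample.
For small feature counts all coalitions are enumerated exactly; larger models
use an antithetic permutation estimator.  Both routes telescope, so local
accuracy — contributions sum to (predicted probability − baseline) — holds
exactly for every row.

A descriptor is *consistent* when its average contribution is positive toward
"active" among active testing poses and positive toward "inactive" among
inactive testing poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io_model import ACTIVE, INACTIVE

EXACT_FEATURE_LIMIT = 12
DEFAULT_KMEANS_K = 100


@dataclass
class ShapSummary:
    feature_name: str
    mean_contrib_active: float
    mean_contrib_inactive: float
    stderr_active: float
    stderr_inactive: float

    def __post_init__(self) -> None:
        for v in (
            self.mean_contrib_active,
            self.mean_contrib_inactive,
            self.stderr_active,
            self.stderr_inactive,
        ):
            if not math.isfinite(v):
                raise ValueError(f"non-finite summary value for {self.feature_name}")


@dataclass(frozen=True)
class ConsistencyVerdict:
    feature_name: str
    consistent: bool


# ---------------------------------------------------------------------------
# background summarisation
# ---------------------------------------------------------------------------


def kmeans_background(
    X: np.ndarray, k: int = DEFAULT_KMEANS_K, seed: int = 0
) -> np.ndarray:
    """Summarise rows into (at most) ``k`` k-means centroids (k clamped to n)."""
    from sklearn.cluster import KMeans

    X = np.asarray(X, dtype=float)
    k = min(k, X.shape[0])
    if k == X.shape[0]:
        return X.copy()
    model = KMeans(n_clusters=k, random_state=seed, n_init=4)
    model.fit(X)
    return model.cluster_centers_


# ---------------------------------------------------------------------------
# Shapley engine
# ---------------------------------------------------------------------------


def probability_fn(model, class_label) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap a fitted classifier into ``X -> P(class_label)``."""
    classes = list(model.classes_)
    idx = classes.index(class_label)
    return lambda X: model.predict_proba(X)[:, idx]


def _subset_values(
    f: Callable[[np.ndarray], np.ndarray],
    rows: np.ndarray,
    background: np.ndarray,
    subsets: Sequence[tuple[int, ...]],
    chunk_rows: int = 64,
) -> np.ndarray:
    """v[r, s] = mean over background b of f(rows[r] on subset s, b elsewhere)."""
    n_rows, n_feat = rows.shape
    n_bg = background.shape[0]
    values = np.empty((n_rows, len(subsets)))
    for start in range(0, n_rows, chunk_rows):
        block = rows[start : start + chunk_rows]
        hybrids = []
        for x in block:
            for subset in subsets:
                h = background.copy()
                if subset:
                    h[:, list(subset)] = x[list(subset)]
                hybrids.append(h)
        stacked = np.concatenate(hybrids, axis=0)
        preds = np.asarray(f(stacked), dtype=float)
        preds = preds.reshape(len(block), len(subsets), n_bg)
        values[start : start + chunk_rows] = preds.mean(axis=2)
    return values


def _exact_shapley(
    f: Callable[[np.ndarray], np.ndarray],
    rows: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    n_feat = rows.shape[1]
    subsets = []
    index_of = {}
    for mask in range(1 << n_feat):
        subset = tuple(i for i in range(n_feat) if mask & (1 << i))
        index_of[subset] = len(subsets)
        subsets.append(subset)
    values = _subset_values(f, rows, background, subsets)
    fact = [math.factorial(i) for i in range(n_feat + 1)]
    contribs = np.zeros_like(rows, dtype=float)
    for subset in subsets:
        s = len(subset)
        if s == n_feat:
            continue
        weight = fact[s] * fact[n_feat - s - 1] / fact[n_feat]
        in_subset = set(subset)
        base = values[:, index_of[subset]]
        for i in range(n_feat):
            if i in in_subset:
                continue
            with_i = tuple(sorted(subset + (i,)))
            contribs[:, i] += weight * (values[:, index_of[with_i]] - base)
    return contribs


def _permutation_shapley(
    f: Callable[[np.ndarray], np.ndarray],
    rows: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    n_feat = rows.shape[1]
    rng = np.random.default_rng(seed)
    perms: list[tuple[int, ...]] = []
    for _ in range(max(1, n_permutations // 2)):
        p = tuple(rng.permutation(n_feat))
        perms.append(p)
        perms.append(tuple(reversed(p)))  # antithetic pair
    # unique prefix subsets across all permutations, shared by every row
    subset_index: dict[tuple[int, ...], int] = {(): 0}
    subsets: list[tuple[int, ...]] = [()]
    for p in perms:
        acc: tuple[int, ...] = ()
        for i in p:
            acc = tuple(sorted(acc + (i,)))
            if acc not in subset_index:
                subset_index[acc] = len(subsets)
                subsets.append(acc)
    values = _subset_values(f, rows, background, subsets)
    contribs = np.zeros_like(rows, dtype=float)
    for p in perms:
        acc: tuple[int, ...] = ()
        prev = values[:, 0]
        for i in p:
            acc = tuple(sorted(acc + (i,)))
            cur = values[:, subset_index[acc]]
            contribs[:, i] += cur - prev
            prev = cur
    return contribs / len(perms)


def shap_values(
    model,
    X: np.ndarray,
    background: np.ndarray,
    class_label=ACTIVE,
    n_permutations: int = 16,
    seed: int = 0,
    exact_limit: int = EXACT_FEATURE_LIMIT,
) -> tuple[np.ndarray, float]:
    """Per-row, per-feature contributions to P(class_label), plus the baseline.

    Returns ``(contribs, baseline)`` with
    ``contribs[r].sum() + baseline == P(class_label | X[r])`` exactly.
    Feature counts up to ``exact_limit`` are enumerated exactly; beyond that
    an antithetic permutation estimator is used (local accuracy still exact).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if X.shape[1] != background.shape[1]:
        raise ValueError("model features and background width differ")
    f = probability_fn(model, class_label)
    baseline = float(np.mean(f(background)))
    if X.shape[1] <= exact_limit:
        contribs = _exact_shapley(f, X, background)
    else:
        contribs = _permutation_shapley(f, X, background, n_permutations, seed)
    return contribs, baseline


# ---------------------------------------------------------------------------
# class summaries and the consistency filter
# ---------------------------------------------------------------------------


def summarize_by_class(
    contributions: np.ndarray,
    feature_names: Sequence[str],
    row_labels: Sequence[str],
) -> list[ShapSummary]:
    """Class-conditional means ± standard errors of per-feature contributions.

    ``contributions`` are toward the *active* class; the contribution toward
    "inactive" is its negation (binary complement).  Rows should be the poses
    of testing compounds.  Raises when either class is empty; a single-row
    class gets stderr 0.
    """
    contributions = np.asarray(contributions, dtype=float)
    labels = np.asarray(row_labels)
    active_rows = contributions[labels == ACTIVE]
    inactive_rows = -contributions[labels == INACTIVE]
    if active_rows.shape[0] == 0 or inactive_rows.shape[0] == 0:
        raise ValueError("both classes must be present among the summarised rows")

    def _stderr(block: np.ndarray) -> np.ndarray:
        if block.shape[0] < 2:
            return np.zeros(block.shape[1])
        return block.std(axis=0, ddof=1) / math.sqrt(block.shape[0])

    se_a, se_i = _stderr(active_rows), _stderr(inactive_rows)
    mean_a, mean_i = active_rows.mean(axis=0), inactive_rows.mean(axis=0)
    return [
        ShapSummary(
            feature_name=name,
            mean_contrib_active=float(mean_a[j]),
            mean_contrib_inactive=float(mean_i[j]),
            stderr_active=float(se_a[j]),
            stderr_inactive=float(se_i[j]),
        )
        for j, name in enumerate(feature_names)
    ]


def verdicts(summaries: Sequence[ShapSummary], min_z: float = 0.0) -> list[ConsistencyVerdict]:
    """Consistency verdict per feature; ``min_z > 0`` gates on mean − z·stderr."""
    out = []
    for s in summaries:
        lo_a = s.mean_contrib_active - min_z * s.stderr_active
        lo_i = s.mean_contrib_inactive - min_z * s.stderr_inactive
        out.append(ConsistencyVerdict(s.feature_name, bool(lo_a > 0 and lo_i > 0)))
    return out


def filter_consistent(
    summaries: Sequence[ShapSummary], min_z: float = 0.0
) -> list[str]:
    """Features whose class-conditional means are both positive, order kept."""
    if not summaries:
        raise ValueError("no summaries to filter")
    return [
        v.feature_name
        for v in verdicts(summaries, min_z=min_z)
        if v.consistent
    ]


def select_template_pose(
    compound_id: str,
    pose_ids: Sequence[str],
    compound_of: dict[str, str],
    contributions: np.ndarray,
    feature_names: Sequence[str],
    consistent_features: Sequence[str],
) -> str:
    """The compound's pose with the largest summed active-class contribution
    over the consistent features; ties break to the smaller pose_id."""
    cols = [i for i, n in enumerate(feature_names) if n in set(consistent_features)]
    candidates = [
        (i, p) for i, p in enumerate(pose_ids) if compound_of[p] == compound_id
    ]
    if not candidates:
        raise ValueError(f"compound {compound_id!r} has no poses")
    contributions = np.asarray(contributions, dtype=float)
    scored = [
        (float(contributions[i, cols].sum()) if cols else 0.0, p)
        for i, p in candidates
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return scored[0][1]


def write_summary_csv(
    summaries: Sequence[ShapSummary],
    path,
    min_z: float = 0.0,
) -> None:
    import csv

    flags = {v.feature_name: v.consistent for v in verdicts(summaries, min_z)}
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "feature",
                "mean_contrib_active",
                "stderr_active",
                "mean_contrib_inactive",
                "stderr_inactive",
                "consistent",
            ]
        )
        for s in summaries:
            writer.writerow(
                [
                    s.feature_name,
                    f"{s.mean_contrib_active:.6g}",
                    f"{s.stderr_active:.6g}",
                    f"{s.mean_contrib_inactive:.6g}",
                    f"{s.stderr_inactive:.6g}",
                    int(flags[s.feature_name]),
                ]
            )


def plot_summaries(summaries: Sequence[ShapSummary], path) -> None:
    """Paired-bar chart of class-conditional contributions with error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.feature_name for s in summaries]
    x = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(names)), 4))
    ax.bar(
        x - 0.2,
        [s.mean_contrib_active for s in summaries],
        width=0.4,
        yerr=[s.stderr_active for s in summaries],
        label="toward active (active poses)",
        color="tab:blue",
    )
    ax.bar(
        x + 0.2,
        [s.mean_contrib_inactive for s in summaries],
        width=0.4,
        yerr=[s.stderr_inactive for s in summaries],
        label="toward inactive (inactive poses)",
        color="tab:red",
    )
    ax.axhline(0, color="k", linewidth=0.5)
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=75, ha="right", fontsize=7)
    ax.set_ylabel("mean probability contribution")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
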