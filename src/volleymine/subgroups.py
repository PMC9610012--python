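"""Subgroup discovery with z-score quality and swap-randomized FDR control.

For one action type's feature matrix, the search enumerates every
single-predictor threshold condition (``feature >= t`` and ``feature <= t``
for every observed value ``t``) whose subgroup covers between 10% and 90%
of the rows, and scores each candidate with the signed z-score quality

    z = (mean_subgroup - mean_all) * sqrt(n_subgroup) / sd_all ,

where ``sd_all`` is the n-1 standard deviation of all targets for the
action type.  A positive sign means better-than-average performance.

Because thousands of conditions are tested, significance is assessed
against the null distribution of the *best* discoverable quality: the
target column is permuted uniformly at random against the fixed feature
rows (swap randomization), the full search is re-run, and the maximum
|z| recorded, typically 1000 times.  The false-discovery probability of
an observed subgroup is the add-one empirical tail probability

    p = (1 + #{runs with max |z| >= |z_observed|}) / (n_runs + 1) ,

significant when p < 0.05.  Effect sizes are reported as |Cohen's d|
between subgroup and complement with a 95% normal-approximation CI.

Rows with a missing feature value never satisfy a condition on that
feature; the subgroup mean is taken over member rows while ``mean_all``
and ``sd_all`` always cover every row of the action type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import predictor_columns

MIN_SIZE_FRACTION = 0.10
MAX_SIZE_FRACTION = 0.90
SIGNIFICANCE_LEVEL = 0.05

#: thresholds of |Cohen's d| for the qualitative effect-size labels
EFFECT_LABELS = ((0.20, "negligible"), (0.50, "small"), (0.80, "medium"), (np.inf, "large"))


def effect_label(d: float) -> str:
    if np.isnan(d):
        return "undefined"
    for bound, label in EFFECT_LABELS:
        if abs(d) < bound:
            return label
    return "large"


def z_quality(subgroup_targets, all_targets) -> float:
    """Signed z-score quality of a subgroup against the whole collection."""
    s = np.asarray(subgroup_targets, dtype=float)
    a = np.asarray(all_targets, dtype=float)
    if s.size == 0:
        raise ValueError("subgroup is empty")
    sd = a.std(ddof=1)
    if not sd > 0:
        raise ValueError("overall standard deviation is zero; z-quality undefined")
    return float((s.mean() - a.mean()) * np.sqrt(s.size) / sd)


def subgroup_effect_size(subgroup_targets, complement_targets) -> tuple[float, float, float, str]:
    """|Cohen's d| between subgroup and complement, 95% CI and label.

    Pooled SD with n-1 weights; CI via d +/- 1.96 * SE with
    SE = sqrt((nS+nC)/(nS*nC) + d^2 / (2*(nS+nC))).  Degenerate groups
    (pooled SD zero, or fewer than two observations in either group)
    yield NaN with label 'undefined'.
    """
    s = np.asarray(subgroup_targets, dtype=float)
    c = np.asarray(complement_targets, dtype=float)
    if s.size < 2 or c.size < 2:
        return float("nan"), float("nan"), float("nan"), "undefined"
    ns, nc = s.size, c.size
    pooled = np.sqrt(((ns - 1) * s.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / (ns + nc - 2))
    if not pooled > 0:
        return float("nan"), float("nan"), float("nan"), "undefined"
    d = abs(s.mean() - c.mean()) / pooled
    se = np.sqrt((ns + nc) / (ns * nc) + d * d / (2 * (ns + nc)))
    return float(d), float(d - 1.96 * se), float(d + 1.96 * se), effect_label(d)


def false_discovery_probability(observed_z: float, null_maxima) -> float:
    """Add-one empirical probability that the best null search beats |z|."""
    null_maxima = np.asarray(null_maxima, dtype=float)
    if null_maxima.size == 0:
        raise ValueError("null distribution is empty")
    hits = int(np.sum(null_maxima >= abs(observed_z)))
    return float((1 + hits) / (null_maxima.size + 1))


# ---------------------------------------------------------------------------
# search machinery
# ---------------------------------------------------------------------------

@dataclass
class _FeatureCuts:
    """Pre-sorted threshold structure for one feature (shared by the
    observed search and every swap-randomized re-run)."""

    name: str
    row_order: np.ndarray      # row indices (into the action matrix) sorted by value
    le_pos: np.ndarray         # cut positions for '<=' (last occurrence of a distinct value)
    le_thresholds: np.ndarray
    ge_pos: np.ndarray         # cut positions for '>=' (first occurrence)
    ge_thresholds: np.ndarray


def _prepare_matrix(matrix: pd.DataFrame, action_type: str):
    sub = matrix[matrix["action_type"] == action_type]
    if not len(sub):
        raise ValueError(f"no rows for action type {action_type!r}")
    feats = predictor_columns(sub)
    X = sub[feats].to_numpy(dtype=float)
    y = sub["target"].to_numpy(dtype=float)
    return sub.reset_index(drop=True), X, y, feats


def _feature_cuts(X: np.ndarray, n_all: int, feature_names) -> list[_FeatureCuts]:
    lo = int(np.ceil(MIN_SIZE_FRACTION * n_all - 1e-9))
    hi = int(np.floor(MAX_SIZE_FRACTION * n_all + 1e-9))
    lo = max(lo, 1)
    cuts = []
    for f, name in enumerate(feature_names):
        v = X[:, f]
        valid = np.flatnonzero(~np.isnan(v))
        if valid.size == 0:
            continue
        order = valid[np.argsort(v[valid], kind="stable")]
        vs = v[order]
        nm = vs.size
        distinct = np.flatnonzero(np.diff(vs) != 0)
        first = np.concatenate(([0], distinct + 1))          # first occurrence positions
        last = np.concatenate((distinct, [nm - 1]))          # last occurrence positions
        le_sizes = last + 1
        le_keep = (le_sizes >= lo) & (le_sizes <= hi)
        ge_sizes = nm - first
        ge_keep = (ge_sizes >= lo) & (ge_sizes <= hi)
        if not le_keep.any() and not ge_keep.any():
            continue
        cuts.append(_FeatureCuts(
            name=name, row_order=order,
            le_pos=last[le_keep], le_thresholds=vs[last[le_keep]],
            ge_pos=first[ge_keep], ge_thresholds=vs[first[ge_keep]],
        ))
    return cuts


def _cut_z(Y: np.ndarray, cut: _FeatureCuts, mean_all: float, sd_all: float):
    """z-scores at every retained cut for each row-permutation in Y.

    Y has shape (R, n_rows_action); returns (z_le, z_ge) with shapes
    (R, n_le_cuts) and (R, n_ge_cuts).
    """
    Ys = Y[:, cut.row_order]
    cs = np.cumsum(Ys, axis=1)
    tot = cs[:, -1]
    z_le = z_ge = None
    if cut.le_pos.size:
        sizes = cut.le_pos + 1
        means = cs[:, cut.le_pos] / sizes
        z_le = (means - mean_all) * np.sqrt(sizes) / sd_all
    if cut.ge_pos.size:
        nm = cut.row_order.size
        sizes = nm - cut.ge_pos
        sums = tot[:, None] - np.where(cut.ge_pos > 0, cs[:, np.maximum(cut.ge_pos - 1, 0)], 0.0)
        z_ge = (sums / sizes - mean_all) * np.sqrt(sizes) / sd_all
    return z_le, z_ge


def enumerate_conditions(matrix: pd.DataFrame, action_type: str) -> pd.DataFrame:
    """All candidate single-feature threshold conditions for one action type.

    Both operators at every distinct observed value whose subgroup size is
    within [10%, 90%] of the action type's rows; constant features yield
    no candidates.
    """
    _, X, y, feats = _prepare_matrix(matrix, action_type)
    n = len(y)
    rows = []
    for cut in _feature_cuts(X, n, feats):
        for thr, size in zip(cut.le_thresholds, cut.le_pos + 1):
            rows.append({"feature": cut.name, "operator": "<=", "threshold": float(thr),
                         "size": int(size), "size_fraction": size / n})
        nm = cut.row_order.size
        for thr, size in zip(cut.ge_thresholds, nm - cut.ge_pos):
            rows.append({"feature": cut.name, "operator": ">=", "threshold": float(thr),
                         "size": int(size), "size_fraction": size / n})
    return pd.DataFrame(rows, columns=["feature", "operator", "threshold", "size", "size_fraction"])


def discover(matrix: pd.DataFrame, action_type: str) -> pd.DataFrame:
    """Score every candidate condition and rank subgroups by |z|.

    Dominated thresholds are collapsed: one result per (feature,
    operator), keeping the best-|z| threshold.  Returns a DataFrame with
    columns feature, operator, threshold, size, size_fraction,
    subgroup_mean and quality (the signed z), sorted by |quality|
    descending (ties broken by feature name and operator for
    determinism).
    """
    _, X, y, feats = _prepare_matrix(matrix, action_type)
    n = len(y)
    sd_all = y.std(ddof=1)
    if not sd_all > 0:
        raise ValueError("targets are constant; subgroup quality undefined")
    mean_all = y.mean()
    Y = y[None, :]
    rows = []
    for cut in _feature_cuts(X, n, feats):
        z_le, z_ge = _cut_z(Y, cut, mean_all, sd_all)
        for op, z, pos, thrs in (("<=", z_le, cut.le_pos, cut.le_thresholds),
                                 (">=", z_ge, cut.ge_pos, cut.ge_thresholds)):
            if z is None:
                continue
            z = z[0]
            k = int(np.argmax(np.abs(z)))
            size = int(pos[k] + 1) if op == "<=" else int(cut.row_order.size - pos[k])
            rows.append({
                "feature": cut.name, "operator": op, "threshold": float(thrs[k]),
                "size": size, "size_fraction": size / n,
                "subgroup_mean": float(mean_all + z[k] * sd_all / np.sqrt(size)),
                "quality": float(z[k]),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["quality", "feature", "operator"],
                              key=lambda s: -s.abs() if s.name == "quality" else s,
                              kind="mergesort").reset_index(drop=True)
    return out


def swap_randomized_null(matrix: pd.DataFrame, action_type: str,
                         n_runs: int = 1000, seed: int = 0) -> np.ndarray:
    """Null distribution of the best |z| under target permutation.

    Each run permutes the target column uniformly at random against the
    fixed feature rows, re-runs the full candidate search (same
    candidate-generation settings as :func:`discover`) and records the
    maximum |z|.
    """
    _, X, y, feats = _prepare_matrix(matrix, action_type)
    n = len(y)
    sd_all = y.std(ddof=1)
    if not sd_all > 0:
        raise ValueError("targets are constant; null distribution undefined")
    mean_all = y.mean()
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_runs, n)), axis=1)
    Y = y[perms]                      # (R, n)
    best = np.zeros(n_runs)
    for cut in _feature_cuts(X, n, feats):
        z_le, z_ge = _cut_z(Y, cut, mean_all, sd_all)
        if z_le is not None:
            np.maximum(best, np.abs(z_le).max(axis=1), out=best)
        if z_ge is not None:
            np.maximum(best, np.abs(z_ge).max(axis=1), out=best)
    return best


def subgroup_analysis(matrix: pd.DataFrame, action_type: str,
                      n_runs: int = 1000, seed: int = 0,
                      top_k: int | None = 10) -> pd.DataFrame:
    """Full per-action-type analysis: search, FDR control, effect sizes.

    Returns the top subgroups (by |z|) with columns of :func:`discover`
    plus ``fd_probability``, ``significant``, ``cohens_d``, ``d_ci_low``,
    ``d_ci_high`` and ``effect``.
    """
    results = discover(matrix, action_type)
    if not len(results):
        return results
    if top_k is not None:
        results = results.head(top_k).copy()
    null = swap_randomized_null(matrix, action_type, n_runs=n_runs, seed=seed)
    sub, X, y, feats = _prepare_matrix(matrix, action_type)
    fd, dvals, dlo, dhi, labels = [], [], [], [], []
    for r in results.itertuples():
        fd.append(false_discovery_probability(r.quality, null))
        v = sub[r.feature].to_numpy(dtype=float)
        mask = (v <= r.threshold) if r.operator == "<=" else (v >= r.threshold)
        mask &= ~np.isnan(v)
        d, lo, hi, lab = subgroup_effect_size(y[mask], y[~mask])
        dvals.append(d); dlo.append(lo); dhi.append(hi); labels.append(lab)
    results["fd_probability"] = fd
    results["significant"] = results["fd_probability"] < SIGNIFICANCE_LEVEL
    results["cohens_d"] = dvals
    results["d_ci_low"] = dlo
    results["d_ci_high"] = dhi
    results["effect"] = labels
    return results
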