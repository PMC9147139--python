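"""Cross-site analysis: availability accounting, rank-based score
comparisons, and a permutation-based conditional inference tree that
predicts a patient's site from score features.

The rank statistics are implemented here from first principles (average
ranks computed with numpy); the test suite checks them against an
independent reference implementation.  The tree follows the conditional
inference recipe in simplified form: at each node, per-feature
permutation p-values (Kruskal-Wallis for numeric/ordinal features,
chi-square for categorical ones) are Bonferroni-adjusted, recursion
stops when the smallest adjusted p exceeds alpha, and the winning
feature is split at the threshold maximizing the association of the
induced binary partition with the site labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hfscores.errors import ConfigurationError, InvalidInputError

# ---------------------------------------------------------------------------
# rank helpers (deliberately independent of scipy's rank-test routines)
# ---------------------------------------------------------------------------


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """1-based average (midrank) ranks with ties."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_correction(values: np.ndarray) -> float:
    """1 - sum(t^3 - t) / (N^3 - N) over tie groups."""
    n = len(values)
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(np.sum(counts ** 3 - counts)) / float(n ** 3 - n)


def _kw_from_ranks(ranks: np.ndarray, labels: np.ndarray, k: int,
                   correction: float) -> float:
    n = len(ranks)
    sums = np.bincount(labels, weights=ranks, minlength=k)
    sizes = np.bincount(labels, minlength=k)
    nz = sizes > 0
    h = 12.0 / (n * (n + 1)) * np.sum(sums[nz] ** 2 / sizes[nz]) - 3.0 * (n + 1)
    if correction <= 0.0:
        return 0.0  # every value tied
    return float(h / correction)


def compare_sites_kw(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise InvalidInputError("need at least two non-empty groups")
    values = np.concatenate(groups)
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    ranks = _average_ranks(values)
    h = _kw_from_ranks(ranks, labels, len(groups), _tie_correction(values))
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
    return h, p


def rank_sum_test(x: Sequence[float], y: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum z statistic and two-sided p-value
    (large-sample normal approximation, no continuity or tie correction,
    matching the classical test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = _average_ranks(np.concatenate([x, y]))
    r1 = float(np.sum(ranks[:n1]))
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (r1 - expected) / sd
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


def compare_imputed_complete(complete: Sequence[float],
                             imputed: Sequence[float]
                             ) -> tuple[float, float, str]:
    """Unpaired rank-sum comparison of complete-data vs imputed-only
    scores, with the direction of the median difference."""
    z, p = rank_sum_test(np.asarray(complete, dtype=float),
                         np.asarray(imputed, dtype=float))
    med_c = float(np.median(complete))
    med_i = float(np.median(imputed))
    if med_i > med_c:
        direction = "imputed_higher"
    elif med_i < med_c:
        direction = "complete_higher"
    else:
        direction = "none"
    return z, p, direction


# ---------------------------------------------------------------------------
# permutation association tests
# ---------------------------------------------------------------------------


def _chi2_stat(codes: np.ndarray, labels: np.ndarray, n_codes: int,
               k: int) -> float:
    table = np.bincount(labels * n_codes + codes,
                        minlength=k * n_codes).reshape(k, n_codes).astype(float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum @ colsum / table.sum()
    mask = expected > 0
    return float(np.sum((table[mask] - expected[mask]) ** 2 / expected[mask]))


def permutation_association(x: Sequence, labels: Sequence, n_perm: int = 999,
                            seed: int = 0, kind: str = "continuous",
                            rng: Optional[np.random.Generator] = None,
                            ) -> float:
    """Permutation p-value for association between a feature and site
    labels: p = (1 + #{permuted stat >= observed}) / (n_perm + 1).

    Statistic: tie-corrected Kruskal-Wallis H for continuous/ordinal
    features, Pearson chi-square for categorical ones.  A constant
    feature returns 1.0 by convention.
    """
    if n_perm < 99:
        raise InvalidInputError("n_perm must be >= 99")
    x = np.asarray(x)
    codes, _ = pd.factorize(pd.Series(labels), sort=True)
    labels = codes.astype(np.int64)
    k = int(labels.max()) + 1
    if len(np.unique(x)) < 2:
        return 1.0
    if rng is None:
        rng = np.random.default_rng(seed)

    if kind == "categorical":
        xcodes, uniques = pd.factorize(pd.Series(x), sort=True)
        xcodes = xcodes.astype(np.int64)
        nc = len(uniques)
        observed = _chi2_stat(xcodes, labels, nc, k)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _chi2_stat(xcodes, perm, nc, k) >= observed - 1e-12:
                count += 1
    else:
        values = x.astype(float)
        ranks = _average_ranks(values)
        correction = _tie_correction(values)
        observed = _kw_from_ranks(ranks, labels, k, correction)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _kw_from_ranks(ranks, perm, k, correction) >= observed - 1e-12:
                count += 1
    return (1.0 + count) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# conditional inference tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    node_id: int
    n: int
    proportions: dict[str, float]
    split_variable: Optional[str] = None
    split_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"id": self.node_id, "n": self.n,
             "proportions": self.proportions}
        if not self.is_terminal:
            d.update({"split_variable": self.split_variable,
                      "split_value": self.split_value,
                      "p_adjusted": self.p_adjusted,
                      "left": self.left.to_dict(),
                      "right": self.right.to_dict()})
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        props = ", ".join(f"{s}: {p:.2f}" for s, p in self.proportions.items())
        if self.is_terminal:
            return f"{pad}[{self.node_id}] n={self.n} ({props})\n"
        out = (f"{pad}[{self.node_id}] {self.split_variable} <= "
               f"{self.split_value:g} (p_adj={self.p_adjusted:.4g}, "
               f"n={self.n})\n")
        return out + self.left.to_text(indent + 1) \
                   + self.right.to_text(indent + 1)

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_terminal:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()


def _proportions(labels: np.ndarray, sites: list[str]) -> dict[str, float]:
    n = len(labels)
    return {site: float(np.sum(labels == i)) / n
            for i, site in enumerate(sites)}


def _best_threshold(x: np.ndarray, labels: np.ndarray, k: int,
                    minbucket: int) -> tuple[Optional[float], float]:
    """Threshold (split at x <= t) maximizing the chi-square association of
    the induced binary partition with the labels."""
    uniques = np.unique(x)
    best_t, best_stat = None, -1.0
    for left_edge, right_edge in zip(uniques, uniques[1:]):
        t = (left_edge + right_edge) / 2.0
        mask = x <= t
        n_left = int(mask.sum())
        if n_left < minbucket or len(x) - n_left < minbucket:
            continue
        stat = _chi2_stat(mask.astype(np.int64), labels, 2, k)
        if stat > best_stat + 1e-12:
            best_t, best_stat = float(t), stat
    return best_t, best_stat


def grow_conditional_tree(features: pd.DataFrame, labels: Sequence,
                          kinds: Optional[dict[str, str]] = None,
                          alpha: float = 0.05, n_perm: int = 999,
                          seed: int = 0, min_node: int = 20,
                          minbucket: int = 7) -> TreeNode:
    """Grow a permutation-based conditional inference tree.

    *features* must be complete (no missing values); categorical and
    boolean columns should be numerically coded (the split is always a
    threshold).  *kinds* maps feature name to "continuous" or
    "categorical" (default continuous) and selects the node test
    statistic.  Rows are canonically sorted before growth so the result
    is invariant to patient order.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError(f"alpha outside (0, 1]: {alpha}")
    kinds = kinds or {}
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise InvalidInputError("features must be complete (no NaN)")
    codes, uniques = pd.factorize(pd.Series(list(labels)), sort=True)
    sites = [str(u) for u in uniques]
    if len(sites) < 2:
        raise InvalidInputError("need at least two sites")
    y = codes.astype(np.int64)

    # canonical row order => patient-order invariance of permutation draws
    order = np.lexsort(tuple(x[:, j] for j in range(x.shape[1] - 1, -1, -1))
                       + (y,))
    x, y = x[order], y[order]

    names = list(features.columns)
    rng = np.random.default_rng(seed)
    counter = [0]

    def grow(xs: np.ndarray, ys: np.ndarray) -> TreeNode:
        node = TreeNode(node_id=counter[0], n=len(ys),
                        proportions=_proportions(ys, sites))
        counter[0] += 1
        if len(ys) < min_node or len(np.unique(ys)) < 2:
            return node
        tested = []
        for j, name in enumerate(names):
            if len(np.unique(xs[:, j])) < 2:
                continue
            p = permutation_association(
                xs[:, j], ys, n_perm=n_perm, rng=rng,
                kind=kinds.get(name, "continuous"))
            tested.append((j, p))
        if not tested:
            return node
        m = len(tested)
        j_best, p_best = min(tested, key=lambda t: (t[1], t[0]))
        p_adj = min(1.0, p_best * m)  # Bonferroni over features tested
        if p_adj > alpha:
            return node
        k = int(y.max()) + 1
        threshold, _ = _best_threshold(xs[:, j_best], ys, k, minbucket)
        if threshold is None:
            return node
        node.split_variable = names[j_best]
        node.split_value = threshold
        node.p_adjusted = p_adj
        mask = xs[:, j_best] <= threshold
        node.left = grow(xs[mask], ys[mask])
        node.right = grow(xs[~mask], ys[~mask])
        return node

    return grow(x, y)


# ---------------------------------------------------------------------------
# availability accounting
# ---------------------------------------------------------------------------

#: data item -> template, for the availability table
ITEM_TEMPLATES = {
    "age": "personal", "sex": "personal",
    "bmi": "history", "systolic_bp": "history", "nyha": "history",
    "current_smoker": "history", "diabetes": "history",
    "copd_proxy": "history", "hf_duration": "history",
    "hf_duration_ge_18": "history",
    "beta_blocker": "medication", "acei_arb": "medication",
    "statin": "medication", "loop_diuretic": "medication",
    "furosemide_equiv_dose": "medication",
    "lvef": "echo",
    "creatinine": "labs", "sodium": "labs", "hemoglobin": "labs",
    "egfr": "labs",
}


@dataclass
class AvailabilityTable:
    items: pd.DataFrame  # columns: site, template, item, available
    enrolled: dict[str, int]
    scores: pd.DataFrame  # columns: site, score_id, variant, computed

    def item_count(self, site: str, item: str) -> int:
        sel = self.items[(self.items["site"] == site)
                         & (self.items["item"] == item)]
        return int(sel["available"].iloc[0])

    def computed_count(self, site: str, score_id: str, variant: str) -> int:
        sel = self.scores[(self.scores["site"] == site)
                          & (self.scores["score_id"] == score_id)
                          & (self.scores["variant"] == variant)]
        return int(sel["computed"].iloc[0]) if len(sel) else 0


def availability_counts(cleaned: pd.DataFrame,
                        results: pd.DataFrame) -> AvailabilityTable:
    """Per (site, item) usable-value counts (after plausibility; flagged
    values count as unavailable) plus per-score computed counts."""
    item_rows = []
    enrolled = {}
    for site, sub in cleaned.groupby("site", sort=True):
        enrolled[site] = len(sub)
        for item, template in ITEM_TEMPLATES.items():
            if item not in sub.columns:
                continue
            item_rows.append({"site": site, "template": template,
                              "item": item,
                              "available": int(sub[item].notna().sum())})
    score_rows = []
    computed = results[results["status"].isin(["complete", "imputed"])]
    for (site, score_id, variant), sub in results.groupby(
            ["site", "score_id", "variant"], sort=True):
        n = int(((computed["site"] == site)
                 & (computed["score_id"] == score_id)
                 & (computed["variant"] == variant)).sum())
        score_rows.append({"site": site, "score_id": score_id,
                           "variant": variant, "computed": n})
    return AvailabilityTable(
        items=pd.DataFrame(item_rows,
                           columns=["site", "template", "item", "available"]),
        enrolled=enrolled,
        scores=pd.DataFrame(score_rows,
                            columns=["site", "score_id", "variant",
                                     "computed"]))
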