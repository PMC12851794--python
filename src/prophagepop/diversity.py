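"""Information-theoretic association, group tests and rarefaction.

* Theil's uncertainty coefficient ``U(X|Y) = (H(X) - H(X|Y)) / H(X)``
  quantifies how much of the categorical uncertainty in one variable
  (e.g. phage species) is explained by another (e.g. country of origin).
  Entropies are plug-in estimates in nats; U is scale-free so the base is
  immaterial.
* Group differences in prophage burden use the Kruskal–Wallis H test and
  pairwise two-sided Mann–Whitney U tests with Holm–Bonferroni step-down
  adjustment.
* Expected species richness in a random subsample of fixed depth m is the
  exact hypergeometric rarefaction formula
  ``E[S_m] = sum_i (1 - C(N - N_i, m) / C(N, m))``.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "GroupTestResult",
    "uncertainty_coefficient",
    "kruskal_wallis",
    "mann_whitney_pairwise_holm",
    "holm_adjust",
    "rarefy_expected_richness",
    "rarefaction_depth_rule",
    "rarefaction_curve",
    "community_matrix",
]


# ---------------------------------------------------------------------------
# Uncertainty coefficient

@dataclass
class AssociationResult:
    H_x: float
    H_y: float
    H_x_given_y: float
    H_y_given_x: float
    mutual_information: float
    U_x_given_y: float
    U_y_given_x: float


def _entropy(freqs: np.ndarray) -> float:
    p = freqs[freqs > 0]
    return float(-(p * np.log(p)).sum())


def uncertainty_coefficient(
    x_labels: Sequence[str], y_labels: Sequence[str]
) -> AssociationResult:
    """Theil's U in both directions, with the underlying entropies and
    mutual information (nats).

    A degenerate variable (zero entropy) is treated as fully explained:
    ``U = 1``.
    """
    if len(x_labels) != len(y_labels):
        raise ValueError("label lists must have equal length")
    n = len(x_labels)
    if n == 0:
        raise ValueError("empty input")
    joint = Counter(zip(x_labels, y_labels))
    pj = np.array(list(joint.values()), dtype=float) / n
    px = np.array(list(Counter(x_labels).values()), dtype=float) / n
    py = np.array(list(Counter(y_labels).values()), dtype=float) / n
    h_x, h_y, h_xy = _entropy(px), _entropy(py), _entropy(pj)
    mi = max(0.0, h_x + h_y - h_xy)
    h_x_given_y = h_xy - h_y
    h_y_given_x = h_xy - h_x
    u_x = mi / h_x if h_x > 0 else 1.0
    u_y = mi / h_y if h_y > 0 else 1.0
    return AssociationResult(
        H_x=h_x,
        H_y=h_y,
        H_x_given_y=h_x_given_y,
        H_y_given_x=h_y_given_x,
        mutual_information=mi,
        U_x_given_y=min(u_x, 1.0),
        U_y_given_x=min(u_y, 1.0),
    )


# ---------------------------------------------------------------------------
# Group tests

@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Kruskal–Wallis H with mid-rank tie correction; chi-square p with
    k - 1 degrees of freedom.  All-identical data give H = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return GroupTestResult(statistic=0.0, p_value=1.0)
    h, p = sps.kruskal(*groups)
    return GroupTestResult(statistic=float(h), p_value=float(p))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, in input order."""
    return multipletests(list(p_values), method="holm")[1]


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(a) + len(b) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mann_whitney_pairwise_holm(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> GroupTestResult:
    """All pairwise two-sided Mann–Whitney U tests with Holm adjustment.

    Exact p-values by enumeration for small tie-free samples
    (n1 + n2 <= 12), otherwise the normal approximation with tie and
    continuity corrections.
    """
    if not isinstance(groups, Mapping):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"empty group {k!r}")
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        u, p = _mann_whitney_p(arrays[g1], arrays[g2])
        rows.append({"group1": g1, "group2": g2, "U": u, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"])
    return GroupTestResult(
        statistic=float("nan"),
        p_value=float(table["p_holm"].min()),
        pairwise=table,
    )


# ---------------------------------------------------------------------------
# Rarefaction

def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_expected_richness(counts: Sequence[int], m: int) -> float:
    """Hypergeometric expected species richness at subsample depth ``m``.

    ``E[S_m] = sum_i (1 - C(N - N_i, m) / C(N, m))``; species whose removal
    leaves fewer than m individuals are certain to appear and contribute 1.
    """
    counts = np.asarray([c for c in counts], dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if m < 0:
        raise ValueError("depth m must be >= 0")
    if m > n_total:
        raise ValueError(f"depth m={m} exceeds total count {n_total}")
    if m == 0:
        return 0.0
    log_denom = _log_comb(n_total, m)
    expected = 0.0
    for c in counts:
        if n_total - c < m:
            expected += 1.0
        else:
            expected += 1.0 - math.exp(_log_comb(n_total - c, m) - log_denom)
    return expected


def rarefaction_depth_rule(
    group_totals: Mapping[str, int],
    fraction: float = 0.75,
    min_total: int | None = None,
) -> tuple[int, list[str]]:
    """Fixed subsampling depth for cross-group comparison.

    Groups with totals below ``min_total`` (if given) are dropped; the
    depth is ``floor(fraction * min(retained totals))`` — i.e. a fixed
    share of the least-sampled retained group.
    """
    if any(t <= 0 for t in group_totals.values()):
        raise ValueError("group totals must be positive")
    retained = sorted(
        g for g, t in group_totals.items() if min_total is None or t >= min_total
    )
    if not retained:
        raise ValueError("no group survives the min_total filter")
    depth = math.floor(fraction * min(group_totals[g] for g in retained))
    return depth, retained


def rarefaction_curve(
    counts: Sequence[int], depths: Sequence[int]
) -> list[tuple[int, float]]:
    """Expected richness at each depth; non-decreasing and concave in m."""
    depths = list(depths)
    if depths != sorted(depths):
        raise ValueError("depths must be sorted")
    return [(m, rarefy_expected_richness(counts, m)) for m in depths]


def community_matrix(
    species_label: Mapping[str, str], group_of_phage: Mapping[str, str]
) -> pd.DataFrame:
    """Groups x phage-species count matrix from per-phage labels."""
    rows: dict[str, Counter] = {}
    for phage, sp in species_label.items():
        group = group_of_phage[phage]
        rows.setdefault(group, Counter())[sp] += 1
    df = pd.DataFrame(rows).T.fillna(0).astype(int)
    df.index.name = "group"
    return df.sort_index()
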