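"""One-way ANOVA, Tukey HSD, and compact letter displays for model comparison.

Per-image metric values from the test set are grouped by model and
compared with a classical one-way ANOVA; pairwise differences are then
assessed with Tukey's honestly-significant-difference test (the
Tukey-Kramer form, valid for unequal group sizes, via statsmodels).
Letter groups summarize the pairwise decisions the way comparison tables
annotate them: models sharing a letter are not significantly different.

Per-image values are treated as independent observations; multiple
slices from one subject violate that assumption, which is noted as a
limitation rather than corrected, to keep the procedure comparable with
common practice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class PairwiseResult:
    """One Tukey HSD pair: labels, mean difference, adjusted p, decision."""

    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    reject: bool


@dataclass
class ComparisonResult:
    """Full model comparison for one metric."""

    metric: str
    group_labels: list[str]
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    alpha: float
    tukey_pairs: list[PairwiseResult]
    letters: dict[str, str]


def _validate_groups(groups: dict[str, np.ndarray] | list) -> dict[str, np.ndarray]:
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    out = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    if all(np.var(v) == 0.0 for v in out.values()):
        raise ValueError("all within-group variances are zero; F is undefined")
    return out


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over lists/dict of value arrays.

    F = (SSB / (k-1)) / (SSW / (N-k)) with p from the F(k-1, N-k)
    distribution.
    """
    g = list(_validate_groups(groups).values())
    k = len(g)
    n_total = sum(v.size for v in g)
    grand = np.concatenate(g).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in g)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in g)
    df_b, df_w = k - 1, n_total - k
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_hsd(groups, alpha: float = 0.05) -> list[PairwiseResult]:
    """All-pairs Tukey HSD (Tukey-Kramer for unequal sizes) at level alpha."""
    g = _validate_groups(groups)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    values = np.concatenate(list(g.values()))
    labels = np.concatenate([[k] * v.size for k, v in g.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    out = []
    for (a, b), diff, p_adj, rej in zip(
        itertools.combinations(res.groupsunique, 2),
        res.meandiffs,
        res.pvalues,
        res.reject,
    ):
        out.append(PairwiseResult(str(a), str(b), float(diff), float(p_adj), bool(rej)))
    return out


def letter_groups(pairwise: list[PairwiseResult], means: dict[str, float]) -> dict[str, str]:
    """Compact letter display from pairwise decisions (insert-and-absorb).

    Starts with one column holding every model; each significant pair
    splits the columns containing both members; columns that become
    subsets of others are absorbed. Letters are assigned ``a``, ``b``, ...
    in order of the best (largest) group mean each column contains, so
    the top-performing models carry ``a``.
    """
    labels = sorted(means, key=lambda k: -means[k])
    known = {frozenset((p.group_a, p.group_b)) for p in pairwise}
    needed = {frozenset(pair) for pair in itertools.combinations(labels, 2)}
    if needed - known:
        raise ValueError("pairwise results must cover all model pairs")

    columns: list[set[str]] = [set(labels)]
    for p in pairwise:
        if not p.reject:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if p.group_a in col and p.group_b in col:
                new_cols.append(col - {p.group_a})
                new_cols.append(col - {p.group_b})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_cols:
            if not col:
                continue
            if any(col < other for other in new_cols if other is not col):
                continue
            if col not in columns:
                columns.append(col)

    columns.sort(key=lambda col: min(labels.index(m) for m in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {m: [] for m in labels}
    for letter, col in zip(alphabet, columns):
        for m in col:
            out[m].append(letter)
    return {m: "".join(sorted(v)) for m, v in out.items()}


def compare_models(
    metric: str,
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> ComparisonResult:
    """ANOVA + Tukey HSD + letter groups for one metric across models."""
    g = _validate_groups(groups)
    f, p = anova_oneway(g)
    pairs = tukey_hsd(g, alpha=alpha)
    means = {k: float(v.mean()) for k, v in g.items()}
    letters = letter_groups(pairs, means)
    return ComparisonResult(
        metric=metric,
        group_labels=list(g),
        group_means=means,
        f_statistic=f,
        p_value=p,
        alpha=alpha,
        tukey_pairs=pairs,
        letters=letters,
    )
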