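"""Closing statistics: expression hierarchy, clustering, clinical association.

The expression hierarchy compares mean expression of genes under
super-enhancers, cooperative enhancers and classical enhancers with pairwise
Wilcoxon rank-sum tests (BH-adjusted across the three comparisons).  Sample
clustering is average-linkage hierarchical clustering on 1 - Pearson
correlation of log-transformed consensus signal.  Clinical features are
tested per 2x2 table with the two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from coopenh.motifscan import benjamini_hochberg

HIERARCHY_CLASSES = ("SE", "cooperative", "classical")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = feature level, columns = cluster."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class HierarchyResult:
    class_means: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_q: dict[tuple[str, str], float]
    ordered: bool  # mean(SE) > mean(cooperative) > mean(classical)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood criterion.

    Sums hypergeometric probabilities of every table sharing the observed
    margins whose probability does not exceed the observed table's.
    """
    return float(sps.fisher_exact(table.matrix, alternative="two-sided")[1])


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact null enumeration for small tie-free samples (both n <= 25);
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(1.0, res.pvalue))


def expressed_filter(
    expression: pd.DataFrame,
    group_samples: Sequence[str] | None = None,
    min_mean: float = 0.0,
) -> set[str]:
    """Genes whose mean normalised abundance over the group exceeds min_mean.

    ``expression`` is genes x samples; ``group_samples=None`` uses all
    columns.  With the default threshold of 0 a gene survives iff it has any
    positive value in the group.
    """
    cols = list(expression.columns) if group_samples is None else list(group_samples)
    missing = [c for c in cols if c not in expression.columns]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    means = expression[cols].mean(axis=1)
    return set(expression.index[means > min_mean])


def expression_hierarchy(
    expression: pd.DataFrame,
    se_genes: set[str],
    coop_genes: set[str],
    classical_genes: set[str],
    group_samples: Sequence[str] | None = None,
    precedence: Sequence[str] = HIERARCHY_CLASSES,
) -> HierarchyResult:
    """Expression hierarchy across regulatory-element classes.

    Per-gene means over the group samples feed three pairwise Wilcoxon
    rank-sum tests, BH-adjusted.  Genes in several sets are assigned to the
    highest-precedence class (default SE > cooperative > classical), so the
    tested sets are disjoint.  The ``ordered`` flag is true iff
    mean(SE) > mean(cooperative) > mean(classical).
    """
    cols = list(expression.columns) if group_samples is None else list(group_samples)
    means = expression[cols].mean(axis=1)
    raw = {"SE": set(se_genes), "cooperative": set(coop_genes),
           "classical": set(classical_genes)}
    assigned: dict[str, set[str]] = {}
    taken: set[str] = set()
    for cls in precedence:
        assigned[cls] = (raw[cls] - taken) & set(expression.index)
        taken |= raw[cls]
    values = {}
    for cls in HIERARCHY_CLASSES:
        if not assigned[cls]:
            raise ValueError(f"class {cls!r} has no genes after precedence assignment")
        values[cls] = means.loc[sorted(assigned[cls])].to_numpy()
    pairs = [("SE", "cooperative"), ("SE", "classical"), ("cooperative", "classical")]
    p = {pair: wilcoxon_rank_sum(values[pair[0]], values[pair[1]]) for pair in pairs}
    q_arr = benjamini_hochberg([p[pair] for pair in pairs])
    class_means = {cls: float(values[cls].mean()) for cls in HIERARCHY_CLASSES}
    return HierarchyResult(
        class_means=class_means,
        pairwise_p=p,
        pairwise_q={pair: float(qv) for pair, qv in zip(pairs, q_arr)},
        ordered=(
            class_means["SE"] > class_means["cooperative"] > class_means["classical"]
        ),
    )


def cluster_samples(
    signal_matrix: pd.DataFrame, k: int = 3
) -> tuple[pd.Series, list[str]]:
    """Unsupervised sample clustering on a consensus signal matrix.

    ``signal_matrix`` is elements x samples.  Signal is log2(x+1)
    transformed, sample distance is 1 - Pearson correlation, linkage is
    average, and the tree is cut at ``k`` clusters.  Returns per-sample
    integer labels (1..k) and the dendrogram leaf order.
    """
    if signal_matrix.shape[1] < k:
        raise ValueError("need at least k samples")
    log = np.log2(signal_matrix.to_numpy(dtype=float) + 1.0)
    sds = log.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"sample {signal_matrix.columns[j]!r} has constant signal; "
                "correlation distance undefined"
            )
    corr = np.corrcoef(log.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = sch.linkage(condensed, method="average")
    labels = sch.fcluster(link, t=k, criterion="maxclust")
    order = [signal_matrix.columns[i] for i in sch.leaves_list(link)]
    return pd.Series(labels, index=signal_matrix.columns, name="cluster"), order


def clinical_association(
    clinical: pd.DataFrame, cluster_labels: Mapping[str, int]
) -> pd.DataFrame:
    """Per-feature 2x2 tables and Fisher p-values against two clusters.

    ``clinical`` is samples x binary features (two distinct levels each);
    rows are matched to ``cluster_labels`` by index.  Degenerate features
    (one observed level) are flagged and given p = 1.  Non-binary features
    raise with an instruction to dichotomise.
    """
    labels = pd.Series(cluster_labels)
    samples = [s for s in clinical.index if s in labels.index]
    labels = labels.loc[samples]
    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {clusters}")
    rows = []
    for feature in clinical.columns:
        col = clinical.loc[samples, feature]
        levels = sorted(col.unique())
        if len(levels) > 2:
            raise ValueError(
                f"feature {feature!r} has {len(levels)} levels; dichotomise it first"
            )
        degenerate = len(levels) < 2
        lv0 = levels[0]
        a = int(((col == lv0) & (labels == clusters[0])).sum())
        b = int(((col == lv0) & (labels == clusters[1])).sum())
        c = int(((col != lv0) & (labels == clusters[0])).sum())
        d = int(((col != lv0) & (labels == clusters[1])).sum())
        p = 1.0 if degenerate else fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "feature": feature,
                "level": str(lv0),
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
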