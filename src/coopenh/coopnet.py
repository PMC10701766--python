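"""Cooperative-enhancer classification and group-specific element sets.

Genes are ranked by the number of *distinct* classical enhancers converging
on their regulation (a gene reachable from one element through two relation
labels counts that element once).  Genes under >= k elements (k=5 by
default) are called cooperative; their element footprints form the regions
searched for upstream TF motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from coopenh.intervals import GenomicInterval
from coopenh.secall import GeneAssociation, StitchedElement

CLASSES = ("single", "multi", "cooperative")


@dataclass(frozen=True)
class GeneRECount:
    gene_id: str
    n_enhancers: int
    n_superenhancers: int
    re_class: str


def share_percent(numerator: int, denominator: int) -> float:
    """A count share as a percentage rounded to one decimal (e.g. 67.7)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def count_res_per_gene(
    associations: Sequence[GeneAssociation],
    element_labels: Mapping[str, str],
    k: int = 5,
) -> list[GeneRECount]:
    """Count distinct SE and classical-ENH elements per associated gene.

    ``element_labels`` maps element id to ``"SE"`` or ``"ENH"``; elements
    missing from the mapping raise.  Classes follow the enhancer count only:
    cooperative iff n_enhancers >= k, multi iff 2 <= n_enhancers < k, and
    single otherwise (including genes reached only by SEs).
    """
    per_gene: dict[str, set[str]] = {}
    for a in associations:
        if a.element_id not in element_labels:
            raise KeyError(f"element {a.element_id!r} missing from element_labels")
        per_gene.setdefault(a.gene_id, set()).add(a.element_id)
    out: list[GeneRECount] = []
    for gene in sorted(per_gene):
        elems = per_gene[gene]
        n_se = sum(1 for e in elems if element_labels[e] == "SE")
        n_enh = sum(1 for e in elems if element_labels[e] == "ENH")
        for e in elems:
            if element_labels[e] not in ("SE", "ENH"):
                raise ValueError(f"unknown element label {element_labels[e]!r}")
        if n_enh >= k:
            cls = "cooperative"
        elif n_enh >= 2:
            cls = "multi"
        else:
            cls = "single"
        out.append(GeneRECount(gene, n_enh, n_se, cls))
    return out


def classify_cooperative(
    counts: Sequence[GeneRECount], k: int = 5
) -> tuple[set[str], pd.DataFrame]:
    """Cooperative gene set plus the single/multi/cooperative histogram.

    Only genes associated with at least one classical enhancer enter the
    histogram, whose rows sum to that total.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    assoc = [c for c in counts if c.n_enhancers >= 1]
    coop = {c.gene_id for c in assoc if c.n_enhancers >= k}
    hist = {
        "single": sum(1 for c in assoc if c.n_enhancers == 1),
        "multi": sum(1 for c in assoc if 2 <= c.n_enhancers < k),
        "cooperative": len(coop),
    }
    total = len(assoc)
    df = pd.DataFrame(
        {
            "re_class": list(hist),
            "n_genes": list(hist.values()),
            "percent": [share_percent(v, total) if total else 0.0 for v in hist.values()],
        }
    )
    return coop, df


def enhancers_per_gene_table(counts: Sequence[GeneRECount]) -> pd.DataFrame:
    """Lollipop-plot data: number of associated ENHs -> number of genes."""
    tab: dict[int, int] = {}
    for c in counts:
        if c.n_enhancers >= 1:
            tab[c.n_enhancers] = tab.get(c.n_enhancers, 0) + 1
    return pd.DataFrame(
        {"n_enhancers": sorted(tab), "n_genes": [tab[n] for n in sorted(tab)]}
    )


def group_specific(
    elements_a: Sequence[StitchedElement], elements_b: Sequence[StitchedElement]
) -> list[StitchedElement]:
    """Elements of A with zero-bp overlap against any same-class element of B.

    Specificity is class-matched: SEs are compared with SEs and classical
    enhancers with classical enhancers.
    """
    b_index: dict[tuple[str, bool], list[GenomicInterval]] = {}
    for e in elements_b:
        b_index.setdefault((e.interval.chrom, e.is_super), []).append(e.interval)
    out = []
    for e in elements_a:
        others = b_index.get((e.interval.chrom, e.is_super), ())
        if not any(o.start < e.interval.end and e.interval.start < o.end for o in others):
            out.append(e)
    return out


def specificity_summary(
    elements_a: Sequence[StitchedElement],
    elements_b: Sequence[StitchedElement],
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-class specific counts and percentages for both groups."""
    rows = []
    for label, ours, theirs in (
        (label_a, elements_a, elements_b),
        (label_b, elements_b, elements_a),
    ):
        spec = group_specific(ours, theirs)
        for cls, is_super in (("SE", True), ("ENH", False)):
            total = sum(1 for e in ours if e.is_super is is_super)
            n_spec = sum(1 for e in spec if e.is_super is is_super)
            rows.append(
                {
                    "group": label,
                    "re_class": cls,
                    "n_specific": n_spec,
                    "n_total": total,
                    "percent_specific": share_percent(n_spec, total) if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def cooperative_regions(
    cooperative_genes: set[str],
    associations: Sequence[GeneAssociation],
    elements: Sequence[StitchedElement],
) -> list[GenomicInterval]:
    """Deduplicated union of element intervals linked to cooperative genes."""
    if not cooperative_genes:
        raise ValueError("cooperative gene set is empty")
    by_id = {e.element_id: e for e in elements}
    chosen: dict[str, GenomicInterval] = {}
    for a in associations:
        if a.gene_id in cooperative_genes and a.element_id in by_id:
            chosen[a.element_id] = by_id[a.element_id].interval
    return sorted(chosen.values(), key=lambda iv: (iv.chrom, iv.start, iv.end))
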