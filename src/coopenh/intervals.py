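"""Genomic interval algebra: BED I/O, merging, consensus occupancy, annotation.

Coordinates are 0-based half-open throughout.  Peaks carry two per-base signal
densities (ChIP and matched input) in arbitrary normalised units; overlap is
strand-blind because the H3K27ac mark is unstranded.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

FEATURE_CLASSES = (
    "TSS",
    "5UTR",
    "3UTR",
    "Exon",
    "Intron",
    "Downstream",
    "DistalIntergenic",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp shared, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak with per-base ChIP and input signal densities."""

    interval: GenomicInterval
    sample_id: str = ""
    name: str = "."
    chip_density: float = 0.0
    input_density: float = 0.0

    def __post_init__(self) -> None:
        if self.chip_density < 0 or self.input_density < 0:
            raise ValueError("signal densities must be >= 0")


@dataclass(frozen=True)
class ConsensusPeak:
    """Merged footprint supported by >= min_overlap samples.

    Densities are the unweighted mean over the member peaks, giving the
    cohort-average signal used downstream for element scoring.
    """

    interval: GenomicInterval
    support: int
    member_samples: tuple[str, ...]
    chip_density: float = 0.0
    input_density: float = 0.0

    def as_peak(self, sample_id: str = "consensus") -> Peak:
        return Peak(
            interval=self.interval,
            sample_id=sample_id,
            name=f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}",
            chip_density=self.chip_density,
            input_density=self.input_density,
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene model with a single canonical TSS, exons, and optional CDS span."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def tss(self) -> int:
        """TSS base position (last base of the span on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AnnotationRecord:
    peak: Peak
    feature_class: str
    nearest_gene: str | None
    distance_to_tss: int | None


ExclusiveSets = namedtuple("ExclusiveSets", ["a_only", "b_only", "shared"])


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        try:
            chrom, size = line.split("\t")
            sizes[chrom] = int(size)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed chrom.sizes line {i}: {line!r}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def _fmt_float(x: float) -> str:
    return repr(float(x))


def read_peaks(
    path: str | Path,
    sample_id: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Read a BED6+2 peak file (chrom start end name score strand chip input).

    ``score`` is ignored on input (column kept for BED compatibility).  Raises
    ``ValueError`` naming the offending line for malformed records, and for
    chromosomes absent from ``chrom_sizes`` when sizes are supplied.
    """
    peaks: list[Peak] = []
    sid = sample_id if sample_id is not None else Path(path).stem
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"{path}: line {i}: expected 8 BED6+2 columns, got {len(fields)}")
        try:
            chrom, start, end, name, _score, strand, chip, inp = fields[:8]
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            peak = Peak(iv, sample_id=sid, name=name,
                        chip_density=float(chip), input_density=float(inp))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}: line {i}: unknown chromosome {chrom!r}")
            if iv.end > chrom_sizes[chrom]:
                raise ValueError(f"{path}: line {i}: interval exceeds {chrom} size")
        peaks.append(peak)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6+2; round-trips exactly through :func:`read_peaks`."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name,
                        "0",
                        iv.strand,
                        _fmt_float(p.chip_density),
                        _fmt_float(p.input_density),
                    )
                )
                + "\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd hold the CDS span)."""
    genes: list[GeneModel] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}: line {i}: expected 12 BED12 columns, got {len(f)}")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(f"{path}: line {i}: block count mismatch")
        exons = tuple((start + s, start + s + w) for s, w in zip(starts, sizes))
        cds = (thick_start, thick_end) if thick_end > thick_start else (None, None)
        genes.append(
            GeneModel(gene_id, chrom, start, end, strand, exons, cds[0], cds[1])
        )
    return genes


def write_genes_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            ts = g.cds_start if g.cds_start is not None else g.start
            te = g.cds_end if g.cds_end is not None else g.start
            fh.write(
                "\t".join(
                    (
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(ts),
                        str(te),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra


def merge(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, joining any two within ``gap`` bp on one chromosome.

    Output is sorted and disjoint.  ``gap=0`` merges book-ended and
    overlapping intervals only; intervals exactly ``gap`` apart
    (end-to-start) are joined.
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def consensus(
    samples: Sequence[Sequence[Peak]], min_overlap: int = 2
) -> list[ConsensusPeak]:
    """Cross-sample consensus occupancy.

    Candidate regions are the merged footprint (gap=0) of all peaks from all
    samples; a region's support is the number of distinct samples contributing
    at least 1 bp of overlap, and regions with support < ``min_overlap`` are
    dropped.  Densities on the retained regions are the unweighted mean over
    all overlapping member peaks.
    """
    if len(samples) == 0:
        raise ValueError("consensus requires at least one sample")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    all_peaks = [p for sample in samples for p in sample]
    if not all_peaks:
        return []
    regions = merge([p.interval for p in all_peaks], gap=0)
    # Index peaks per chromosome sorted by start for a sweep.
    by_chrom: dict[str, list[tuple[Peak, int]]] = {}
    for si, sample in enumerate(samples):
        for p in sample:
            by_chrom.setdefault(p.interval.chrom, []).append((p, si))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[0].interval.start)
    out: list[ConsensusPeak] = []
    cursor: dict[str, int] = {c: 0 for c in by_chrom}
    for region in regions:
        lst = by_chrom[region.chrom]
        i = cursor[region.chrom]
        members: list[tuple[Peak, int]] = []
        while i < len(lst) and lst[i][0].interval.start < region.end:
            if lst[i][0].interval.end > region.start:
                members.append(lst[i])
            i += 1
        cursor[region.chrom] = i  # regions are disjoint and sorted
        sample_ids: dict[int, str] = {}
        for p, si in members:
            sample_ids[si] = p.sample_id or str(si)
        support = len(sample_ids)
        if support < min_overlap:
            continue
        chip = sum(p.chip_density for p, _ in members) / len(members)
        inp = sum(p.input_density for p, _ in members) / len(members)
        out.append(
            ConsensusPeak(
                interval=region,
                support=support,
                member_samples=tuple(sample_ids[k] for k in sorted(sample_ids)),
                chip_density=chip,
                input_density=inp,
            )
        )
    return out


def exclusive_sets(
    group_a: Sequence[ConsensusPeak], group_b: Sequence[ConsensusPeak]
) -> ExclusiveSets:
    """Partition A and B elements by cross-group overlap status.

    ``a_only`` are elements of A with zero-bp overlap against all of B,
    symmetrically for ``b_only``; ``shared`` holds every element of A or B
    that overlaps the other group.  The three lists partition A u B.
    """
    b_index: dict[str, list[GenomicInterval]] = {}
    for cp in group_b:
        b_index.setdefault(cp.interval.chrom, []).append(cp.interval)
    a_index: dict[str, list[GenomicInterval]] = {}
    for cp in group_a:
        a_index.setdefault(cp.interval.chrom, []).append(cp.interval)
    for d in (a_index, b_index):
        for lst in d.values():
            lst.sort(key=lambda v: (v.start, v.end))

    def hits(iv: GenomicInterval, index: dict[str, list[GenomicInterval]]) -> bool:
        return any(
            o.start < iv.end and iv.start < o.end for o in index.get(iv.chrom, ())
        )

    a_only = [cp for cp in group_a if not hits(cp.interval, b_index)]
    b_only = [cp for cp in group_b if not hits(cp.interval, a_index)]
    shared = [cp for cp in group_a if hits(cp.interval, b_index)] + [
        cp for cp in group_b if hits(cp.interval, a_index)
    ]
    return ExclusiveSets(a_only, b_only, shared)


# ---------------------------------------------------------------------------
# Annotation


def _classify_midpoint(
    mid: int,
    chrom: str,
    gene: GeneModel,
    tss_window: int,
    downstream_window: int,
) -> str | None:
    """Most specific feature class a single gene assigns to a midpoint."""
    if chrom != gene.chrom:
        return None
    if abs(mid - gene.tss) <= tss_window:
        return "TSS"
    in_exon = any(s <= mid < e for s, e in gene.exons)
    in_body = gene.start <= mid < gene.end
    if in_exon and gene.cds_start is not None:
        if gene.strand == "+":
            if mid < gene.cds_start:
                return "5UTR"
            if mid >= gene.cds_end:
                return "3UTR"
        else:
            if mid >= gene.cds_end:
                return "5UTR"
            if mid < gene.cds_start:
                return "3UTR"
    if in_exon:
        return "Exon"
    if in_body:
        return "Intron"
    if gene.strand == "+":
        if gene.end <= mid < gene.end + downstream_window:
            return "Downstream"
    else:
        if gene.start - downstream_window <= mid < gene.start:
            return "Downstream"
    return None


def annotate(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_window: int = 3000,
    downstream_window: int = 300,
) -> list[AnnotationRecord]:
    """Assign one feature class and the nearest gene to each peak.

    The peak midpoint decides the class with precedence
    TSS > 5'UTR > 3'UTR > Exon > Intron > Downstream > DistalIntergenic
    over all genes; ``nearest_gene`` minimises |midpoint - TSS| with ties
    broken by lexicographic gene id.  Without gene models everything is
    DistalIntergenic with an undefined nearest gene.
    """
    precedence = {c: i for i, c in enumerate(FEATURE_CLASSES)}
    out: list[AnnotationRecord] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for p in peaks:
        mid = p.interval.midpoint
        best_class = "DistalIntergenic"
        nearest: GeneModel | None = None
        nearest_d: int | None = None
        for g in by_chrom.get(p.interval.chrom, ()):
            c = _classify_midpoint(mid, p.interval.chrom, g, tss_window, downstream_window)
            if c is not None and precedence[c] < precedence[best_class]:
                best_class = c
            d = abs(mid - g.tss)
            if (
                nearest_d is None
                or d < nearest_d
                or (d == nearest_d and g.gene_id < nearest.gene_id)
            ):
                nearest, nearest_d = g, d
        out.append(
            AnnotationRecord(
                peak=p,
                feature_class=best_class,
                nearest_gene=nearest.gene_id if nearest else None,
                distance_to_tss=(mid - nearest.tss) if nearest else None,
            )
        )
    return out


def annotation_summary(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Per-class peak percentages (the pie-chart fractions), summing to 100."""
    counts = {c: 0 for c in FEATURE_CLASSES}
    for r in records:
        counts[r.feature_class] += 1
    total = max(1, len(records))
    return pd.DataFrame(
        {
            "feature_class": list(counts),
            "n_peaks": list(counts.values()),
            "percent": [round(100.0 * v / total, 1) for v in counts.values()],
        }
    )
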