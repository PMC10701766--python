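"""Synthetic cohort generator with planted ground truth.

Emulates the data shape of an H3K27ac ChIP-seq tumour cohort downstream of
peak calling: broad peaks with ChIP and input signal densities per sample,
dense super-enhancer clusters planted near driver genes, genes wired to five
or more dispersed classical enhancers (far enough apart never to be stitched
into one element), transcription-factor motifs planted into super-enhancer
sequence, an expression matrix with an ordered effect hierarchy across
element classes, and a clinical table associated with sample clusters.

Everything is a pure function of (configuration, seed): identical seeds give
byte-identical output files, and every ground-truth object is recoverable
from the emitted files alone (see :func:`audit_truth`).

Signal model: per-element net (ChIP minus input) density is log-normal
around a class mean, with independent log-normal per-sample noise — the
heavy-tailed shape typical of ChIP coverage.  Super-enhancer clusters get a
total net signal equal to ``se_signal_ratio`` times the expected classical
element signal, split across their constituent peaks.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from coopenh.intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    read_peaks,
    write_chrom_sizes,
    write_genes_bed12,
    write_peaks,
)
from coopenh.motifscan import PWM, pwm_from_counts, write_jaspar

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Fixed offsets for deriving child random streams from the master seed, so
# adding one generator never perturbs the others.
_STREAM_OFFSETS = {
    "genome": 1,
    "annotation": 2,
    "cohort": 3,
    "pwms": 4,
    "plant": 5,
    "expression": 6,
    "clinical": 7,
    "regulons": 8,
}


def child_seed(seed: int, stream: str) -> int:
    return (seed * 9973 + _STREAM_OFFSETS[stream]) % (2**31)


# ---------------------------------------------------------------------------
# Genome and annotation


def make_genome(
    n_chrom: int,
    chrom_len: int,
    gc: float = 0.41,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """I.i.d. random genome at the stated GC content.

    Returns chromosome name -> uint8 base array (ASCII A/C/G/T).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_len < 200_000:
        raise ValueError("chrom_len must be >= 200 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": _BASES[rng.choice(4, size=chrom_len, p=p)]
        for i in range(n_chrom)
    }


def write_genome(genome: Mapping[str, np.ndarray], fasta_path: str | Path,
                 sizes_path: str | Path | None = None) -> None:
    records = [
        SeqRecord(Seq(arr.tobytes().decode("ascii")), id=name, description="")
        for name, arr in genome.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if sizes_path is not None:
        write_chrom_sizes({c: len(a) for c, a in genome.items()}, sizes_path)


def read_genome(fasta_path: str | Path) -> dict[str, np.ndarray]:
    return {
        rec.id: np.frombuffer(str(rec.seq).upper().encode("ascii"), dtype=np.uint8).copy()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def make_annotation(
    chrom_sizes: Mapping[str, int],
    n_genes: int,
    seed: int = 0,
    min_tss_spacing: int = 85_000,
    edge_margin: int = 60_000,
) -> list[GeneModel]:
    """Place gene models with at least ``min_tss_spacing`` between TSSs.

    Genes get one canonical TSS, a 5-20 kb body, 2-5 exons and an interior
    CDS span; strand is random.  Raises when ``n_genes`` cannot be placed at
    the requested spacing.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    tss_positions: list[tuple[str, int]] = []
    for chrom in chrom_sizes:
        L = chrom_sizes[chrom]
        pos = edge_margin + int(rng.integers(0, min_tss_spacing // 10 + 1))
        while pos < L - edge_margin and len(tss_positions) < n_genes:
            tss_positions.append((chrom, pos))
            pos += min_tss_spacing + int(rng.integers(0, min_tss_spacing // 10 + 1))
    if len(tss_positions) < n_genes:
        raise ValueError(
            f"cannot place {n_genes} genes at >= {min_tss_spacing} bp TSS spacing "
            f"on {sum(chrom_sizes.values())} bp of genome "
            f"(capacity {len(tss_positions)})"
        )
    genes: list[GeneModel] = []
    for i, (chrom, tss) in enumerate(tss_positions):
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(5_000, 20_001))
        if strand == "+":
            start, end = tss, tss + body
        else:
            start, end = tss - body + 1, tss + 1
        n_exons = int(rng.integers(2, 6))
        # Split the body into exons separated by introns.
        cuts = np.sort(rng.choice(np.arange(1, body - 1), size=2 * n_exons - 2,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [body]])
        exons = tuple(
            (start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
            for j in range(n_exons)
        )
        exons = tuple((s, e) for s, e in exons if e > s)
        cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        cds_end = exons[-1][0] + max(1, (exons[-1][1] - exons[-1][0]) // 2)
        if cds_end <= cds_start:
            cds_start, cds_end = exons[0][0], exons[-1][1]
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Cohort configuration and truth


@dataclass(frozen=True)
class CohortConfig:
    """Planted-structure configuration; defaults define the study conditions."""

    n_se: int = 50
    se_fraction_dm: float = 0.4
    se_fraction_shared: float = 0.4  # remainder is PT-specific
    n_coop_genes: int = 50
    coop_enh_fraction_dm: float = 0.3  # remainder shared
    n_classical_genes: int = 50
    classical_fraction_shared: float = 0.6  # rest split evenly PT/DM
    n_background: int = 280  # split across shared/c1/c2/c3 groups
    promoter_fraction: float = 0.4
    se_signal_ratio: float = 25.0
    sigma_element: float = 0.10
    sigma_sample: float = 0.25
    detect_prob: float = 0.8
    input_density: float = 0.2

    def __post_init__(self) -> None:
        for name in ("se_fraction_dm", "se_fraction_shared", "coop_enh_fraction_dm",
                     "classical_fraction_shared", "promoter_fraction", "detect_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.se_fraction_dm + self.se_fraction_shared > 1.0:
            raise ValueError("SE group fractions exceed 1")
        if self.se_signal_ratio <= 1.0:
            raise ValueError("se_signal_ratio must be > 1")
        if min(self.n_se, self.n_coop_genes, self.n_classical_genes,
               self.n_background) < 0:
            raise ValueError("planted counts must be >= 0")
        if not 0.0 < self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in (0, 1]")


@dataclass(frozen=True)
class PlantedElement:
    element_id: str
    kind: str  # se_constituent | coop_enh | classical_enh | background | promoter
    parent: str  # SE id or gene id or ""
    group: str  # shared | pt | dm | c1 | c2 | c3
    interval: GenomicInterval
    net_density: float
    input_density: float


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    seed: int
    planted_se_regions: dict[str, list[GenomicInterval]]  # per analysis group
    se_genes: dict[str, list[str]]
    cooperative_genes: list[str]
    classical_genes: list[str]
    driver_tfs: list[str]
    cluster_labels: dict[str, int]  # sample -> 1 | 2 | 3
    sample_groups: dict[str, str]  # sample -> PT | DM
    elements: list[PlantedElement] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_se_regions": {
                g: [[iv.chrom, iv.start, iv.end] for iv in ivs]
                for g, ivs in self.planted_se_regions.items()
            },
            "se_genes": self.se_genes,
            "cooperative_genes": self.cooperative_genes,
            "classical_genes": self.classical_genes,
            "driver_tfs": self.driver_tfs,
            "cluster_labels": self.cluster_labels,
            "sample_groups": self.sample_groups,
            "elements": [
                {
                    "element_id": e.element_id,
                    "kind": e.kind,
                    "parent": e.parent,
                    "group": e.group,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "net_density": e.net_density,
                    "input_density": e.input_density,
                }
                for e in self.elements
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            planted_se_regions={
                g: [GenomicInterval(c, s, e) for c, s, e in ivs]
                for g, ivs in d["planted_se_regions"].items()
            },
            se_genes=d["se_genes"],
            cooperative_genes=d["cooperative_genes"],
            classical_genes=d["classical_genes"],
            driver_tfs=d["driver_tfs"],
            cluster_labels={k: int(v) for k, v in d["cluster_labels"].items()},
            sample_groups=d["sample_groups"],
            elements=[
                PlantedElement(
                    element_id=e["element_id"],
                    kind=e["kind"],
                    parent=e["parent"],
                    group=e["group"],
                    interval=GenomicInterval(e["chrom"], e["start"], e["end"]),
                    net_density=e["net_density"],
                    input_density=e["input_density"],
                )
                for e in d["elements"]
            ],
        )


# Layout constants (bp).  Chosen so that planted structures keep the
# guarantees the downstream windows rely on: super-enhancer constituents stay
# within 12.5 kb of their neighbours, co-targeting cooperative enhancers stay
# > 12.5 kb apart but within the 50 kb proximal window of their gene, and no
# planted peak is ever fully contained in a TSS +/- 3 kb promoter window.
_SE_CLUSTER_START = 4_000  # offset of cluster start from TSS
_SE_CLUSTER_END = 38_000
_COOP_OFFSETS = (-35_000, -21_000, -7_000, 7_000, 21_000, 35_000)
_CLASSICAL_OFFSET = 15_000
_MIN_ELEMENT_CLEARANCE = 13_000  # keeps background peaks out of stitching reach


def _sample_names(n_pt: int, n_dm: int) -> tuple[list[str], dict[str, int], dict[str, str]]:
    samples = [f"PT{i + 1:02d}" for i in range(n_pt)] + [
        f"DM{i + 1:02d}" for i in range(n_dm)
    ]
    clusters: dict[str, int] = {}
    groups: dict[str, str] = {}
    for i, s in enumerate(samples):
        if s.startswith("PT"):
            clusters[s] = 1 if i < n_pt // 2 else 2
            groups[s] = "PT"
        else:
            clusters[s] = 3
            groups[s] = "DM"
    return samples, clusters, groups


def _eligible(group: str, samples: Sequence[str], clusters: Mapping[str, int]) -> list[str]:
    if group == "shared":
        return list(samples)
    if group == "pt":
        return [s for s in samples if s.startswith("PT")]
    if group == "dm":
        return [s for s in samples if s.startswith("DM")]
    if group in ("c1", "c2", "c3"):
        want = int(group[1])
        return [s for s in samples if clusters[s] == want]
    raise ValueError(f"unknown element group {group!r}")


def make_cohort(
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneModel],
    n_pt: int = 17,
    n_dm: int = 12,
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> tuple[dict[str, list[Peak]], SyntheticTruth]:
    """Per-sample peak lists plus the planted ground truth.

    Group-specific elements are detected in >= 2 samples of their group and
    in none of the other; shared elements in >= 2 samples per group (the
    per-sample Bernoulli detection is topped up where needed so that the
    minimum-support consensus rule is exercised non-trivially).
    """
    if n_pt < 4 or n_dm < 4:
        raise ValueError("need at least 4 samples per group")
    rng = np.random.default_rng(seed)
    samples, clusters, sample_groups = _sample_names(n_pt, n_dm)

    n_assigned = config.n_se + config.n_coop_genes + config.n_classical_genes
    if n_assigned > len(genes):
        raise ValueError(
            f"{n_assigned} class-assigned genes requested but only "
            f"{len(genes)} genes in the annotation"
        )
    gene_order = list(genes)
    rng.shuffle(gene_order)
    se_gene_models = gene_order[: config.n_se]
    coop_gene_models = gene_order[config.n_se : config.n_se + config.n_coop_genes]
    classical_gene_models = gene_order[
        config.n_se + config.n_coop_genes : n_assigned
    ]

    classical_signal = 1200.0  # reference per-element net signal (density x length)

    def element_net_signal() -> float:
        """Per-element net signal, lognormal around the classical reference.

        Signal is drawn per element and divided by the realised peak length,
        so element signal is independent of peak width.
        """
        return classical_signal * float(np.exp(rng.normal(0.0, config.sigma_element)))

    elements: list[PlantedElement] = []
    se_regions: dict[str, GenomicInterval] = {}
    se_groups: dict[str, str] = {}
    se_gene_of: dict[str, str] = {}

    def se_group_for(i: int) -> str:
        f = i / max(1, config.n_se)
        if f < config.se_fraction_dm:
            return "dm"
        if f < config.se_fraction_dm + config.se_fraction_shared:
            return "shared"
        return "pt"

    # --- super-enhancer clusters near driver genes -------------------------
    for i, g in enumerate(se_gene_models):
        se_id = f"se{i:03d}"
        group = se_group_for(i)
        n_pk = int(rng.integers(3, 6))
        pos = g.tss + _SE_CLUSTER_START + int(rng.integers(0, 2001))
        lengths = rng.integers(800, 1601, size=n_pk)
        gaps = rng.integers(2500, 5001, size=n_pk - 1) if n_pk > 1 else []
        total_net = (
            config.se_signal_ratio
            * classical_signal
            * float(np.exp(rng.normal(0.0, config.sigma_element)))
        )
        weights = 1.0 + rng.random(n_pk)
        weights /= weights.sum()
        cluster_start = pos
        for j in range(n_pk):
            iv = GenomicInterval(g.chrom, pos, pos + int(lengths[j]))
            dens = total_net * weights[j] / len(iv)
            elements.append(
                PlantedElement(
                    element_id=f"{se_id}_p{j}",
                    kind="se_constituent",
                    parent=se_id,
                    group=group,
                    interval=iv,
                    net_density=dens,
                    input_density=config.input_density,
                )
            )
            pos = iv.end + (int(gaps[j]) if j < n_pk - 1 else 0)
        se_regions[se_id] = GenomicInterval(g.chrom, cluster_start, pos)
        se_groups[se_id] = group
        se_gene_of[se_id] = g.gene_id
        if pos > g.tss + _SE_CLUSTER_END + 4000:
            raise AssertionError("SE cluster escaped its layout budget")

    # --- cooperative genes: >= 5 dispersed enhancers each ------------------
    for i, g in enumerate(coop_gene_models):
        n_enh = int(rng.integers(5, 7))
        offsets = sorted(rng.choice(len(_COOP_OFFSETS), size=n_enh, replace=False))
        for j, oi in enumerate(offsets):
            center = g.tss + _COOP_OFFSETS[oi] + int(rng.integers(-150, 151))
            length = int(rng.integers(700, 1001))
            group = "dm" if rng.random() < config.coop_enh_fraction_dm else "shared"
            iv = GenomicInterval(g.chrom, center - length // 2, center + (length + 1) // 2)
            elements.append(
                PlantedElement(
                    element_id=f"coop{i:03d}_e{j}",
                    kind="coop_enh",
                    parent=g.gene_id,
                    group=group,
                    interval=iv,
                    net_density=element_net_signal() / len(iv),
                    input_density=config.input_density,
                )
            )

    # --- classical single-enhancer genes -----------------------------------
    for i, g in enumerate(classical_gene_models):
        u = rng.random()
        if u < config.classical_fraction_shared:
            group = "shared"
        elif u < config.classical_fraction_shared + (1 - config.classical_fraction_shared) / 2:
            group = "pt"
        else:
            group = "dm"
        center = g.tss + _CLASSICAL_OFFSET + int(rng.integers(-2000, 2001))
        length = int(rng.integers(800, 1601))
        iv = GenomicInterval(g.chrom, center - length // 2, center + (length + 1) // 2)
        elements.append(
            PlantedElement(
                element_id=f"cls{i:03d}_e0",
                kind="classical_enh",
                parent=g.gene_id,
                group=group,
                interval=iv,
                net_density=element_net_signal() / len(iv),
                input_density=config.input_density,
            )
        )

    # --- promoter peaks (removed by TSS exclusion, visible to annotation) ---
    for i, g in enumerate(genes):
        if rng.random() < config.promoter_fraction:
            half = int(rng.integers(500, 751))
            start = max(0, g.tss - half)
            iv = GenomicInterval(g.chrom, start, g.tss + half)
            elements.append(
                PlantedElement(
                    element_id=f"prom_{g.gene_id}",
                    kind="promoter",
                    parent=g.gene_id,
                    group="shared",
                    interval=iv,
                    net_density=element_net_signal() / len(iv),
                    input_density=config.input_density,
                )
            )

    # --- background peaks, including cluster-specific occupancy ------------
    occupied: dict[str, list[tuple[int, int]]] = {}
    for e in elements:
        occupied.setdefault(e.interval.chrom, []).append(
            (e.interval.start, e.interval.end)
        )
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    bg_groups = ["shared", "c1", "c2", "c3"]
    chrom_names = list(chrom_sizes)
    for i in range(config.n_background):
        group = bg_groups[i % len(bg_groups)]
        length = int(rng.integers(800, 1601))
        placed = None
        for _ in range(2000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(rng.integers(20_000, chrom_sizes[chrom] - 20_000 - length))
            end = start + length
            near_peak = any(
                s - _MIN_ELEMENT_CLEARANCE < end and start < e2 + _MIN_ELEMENT_CLEARANCE
                for s, e2 in occupied.get(chrom, ())
            )
            near_tss = any(
                abs(start + length // 2 - t) < 4_500 for t in tss_by_chrom.get(chrom, ())
            )
            if not near_peak and not near_tss:
                placed = GenomicInterval(chrom, start, end)
                break
        if placed is None:
            raise RuntimeError("could not place background peak; genome too crowded")
        occupied.setdefault(placed.chrom, []).append((placed.start, placed.end))
        elements.append(
            PlantedElement(
                element_id=f"bg{i:04d}",
                kind="background",
                parent="",
                group=group,
                interval=placed,
                net_density=element_net_signal() / len(placed),
                input_density=config.input_density,
            )
        )

    # --- per-sample realisation --------------------------------------------
    # Detection is drawn per *unit*: an SE cluster is detected (or missed) as
    # a whole, so a detecting sample always carries the full >=3-peak chain;
    # every other element is its own unit.
    peaks: dict[str, list[Peak]] = {s: [] for s in samples}
    unit_detected: dict[str, list[str]] = {}

    def detect_unit(group: str) -> list[str]:
        eligible = _eligible(group, samples, clusters)
        if len(eligible) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 eligible samples")
        detected = [s for s in eligible if rng.random() < config.detect_prob]
        # Top up so the consensus support floor holds per eligible sub-group.
        subgroups = ({"PT", "DM"} if group == "shared" else {group})
        for sub in sorted(subgroups):
            if group == "shared":
                pool = [s for s in eligible if sample_groups[s] == sub]
            else:
                pool = eligible
            have = [s for s in detected if s in pool]
            while len(have) < 2:
                candidates = [s for s in pool if s not in detected]
                pick = candidates[int(rng.integers(0, len(candidates)))]
                detected.append(pick)
                have.append(pick)
        return detected

    for e in elements:
        unit = e.parent if e.kind == "se_constituent" else e.element_id
        if unit not in unit_detected:
            unit_detected[unit] = detect_unit(e.group)
        detected = unit_detected[unit]
        for s in samples:
            if s not in detected:
                continue
            jitter_s = int(rng.integers(-50, 51))
            jitter_e = int(rng.integers(-50, 51))
            start = max(0, e.interval.start + jitter_s)
            end = min(chrom_sizes[e.interval.chrom], e.interval.end + jitter_e)
            if end <= start:
                start, end = e.interval.start, e.interval.end
            chip = (e.net_density + e.input_density) * float(
                np.exp(rng.normal(0.0, config.sigma_sample))
            )
            inp = e.input_density * float(np.exp(rng.normal(0.0, 0.2)))
            peaks[s].append(
                Peak(
                    interval=GenomicInterval(e.interval.chrom, start, end),
                    sample_id=s,
                    name=e.element_id,
                    chip_density=chip,
                    input_density=inp,
                )
            )
    for s in samples:
        peaks[s].sort(key=lambda p: (p.interval.chrom, p.interval.start))

    truth = SyntheticTruth(
        seed=seed,
        planted_se_regions={
            "PT": [se_regions[k] for k in sorted(se_regions)
                   if se_groups[k] in ("pt", "shared")],
            "DM": [se_regions[k] for k in sorted(se_regions)
                   if se_groups[k] in ("dm", "shared")],
        },
        se_genes={
            "PT": sorted(se_gene_of[k] for k in se_regions
                         if se_groups[k] in ("pt", "shared")),
            "DM": sorted(se_gene_of[k] for k in se_regions
                         if se_groups[k] in ("dm", "shared")),
        },
        cooperative_genes=sorted(g.gene_id for g in coop_gene_models),
        classical_genes=sorted(g.gene_id for g in classical_gene_models),
        driver_tfs=[],
        cluster_labels=clusters,
        sample_groups=sample_groups,
        elements=elements,
    )
    return peaks, truth


# ---------------------------------------------------------------------------
# Motif planting


def make_pwms(n: int = 4, width: int = 10, seed: int = 0) -> dict[str, np.ndarray]:
    """Synthetic sharp count matrices (name -> (width, 4) counts).

    Most positions are fully informative (12 counts on one base); two
    softened positions per motif carry a 9/3 split, mimicking real motif
    degeneracy while keeping a unique consensus.
    """
    rng = np.random.default_rng(seed)
    pwms: dict[str, np.ndarray] = {}
    for i in range(n):
        counts = np.zeros((width, 4))
        dominant = rng.integers(0, 4, size=width)
        for j in range(width):
            counts[j, dominant[j]] = 12
        soft = rng.choice(width, size=2, replace=False)
        for j in soft:
            alt = (dominant[j] + 1 + rng.integers(0, 3)) % 4
            counts[j, dominant[j]] = 9
            counts[j, alt] = 3
        pwms[f"SYNTF{i + 1}"] = counts
    return pwms


def plant_motifs(
    genome: Mapping[str, np.ndarray],
    se_regions: Sequence[GenomicInterval],
    pwm_set: Mapping[str, PWM],
    rate_in_se: float = 1.0,
    rate_elsewhere: float = 0.01,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Write motif consensus instances into the genome.

    ``rate_in_se`` / ``rate_elsewhere`` are expected instances per kb inside
    planted super-enhancer spans and across the rest of the genome.  Returns
    the mutated genome plus a planting log with one record per insertion
    (chrom, start, tf, strand).  PWMs wider than a target span are skipped
    with a warning.  An empty ``pwm_set`` leaves the genome untouched.
    """
    if not rate_in_se > rate_elsewhere >= 0:
        raise ValueError("require rate_in_se > rate_elsewhere >= 0")
    rng = np.random.default_rng(seed)
    out = {c: arr.copy() for c, arr in genome.items()}
    log: list[dict] = []
    if not pwm_set:
        return out, log

    def insert(chrom: str, lo: int, hi: int, rate_per_kb: float) -> None:
        span = hi - lo
        n_expect = rate_per_kb * span / 1000.0
        n_ins = int(rng.poisson(n_expect)) if n_expect > 0 else 0
        for _ in range(n_ins):
            name = list(pwm_set)[int(rng.integers(0, len(pwm_set)))]
            pwm = pwm_set[name]
            w = pwm.width
            if w > span:
                warnings.warn(
                    f"PWM {name} ({w} bp) wider than target span {chrom}:{lo}-{hi}; skipped"
                )
                log.append({"chrom": chrom, "start": -1, "tf": name,
                            "strand": ".", "skipped": True})
                continue
            pos = lo + int(rng.integers(0, span - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = pwm.consensus
            if strand == "-":
                site = str(Seq(site).reverse_complement())
            out[chrom][pos : pos + w] = np.frombuffer(
                site.encode("ascii"), dtype=np.uint8
            )
            log.append({"chrom": chrom, "start": pos, "tf": pwm.name,
                        "strand": strand, "skipped": False})
    se_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in se_regions:
        se_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, arr in genome.items():
        spans = sorted(se_by_chrom.get(chrom, ()), key=lambda v: v.start)
        cursor = 0
        for iv in spans:
            if iv.start > cursor:
                insert(chrom, cursor, iv.start, rate_elsewhere)
            insert(chrom, iv.start, iv.end, rate_in_se)
            cursor = max(cursor, iv.end)
        if cursor < len(arr):
            insert(chrom, cursor, len(arr), rate_elsewhere)
    log.sort(key=lambda r: (r["chrom"], r["start"]))
    return out, log


# ---------------------------------------------------------------------------
# Expression and clinical tables


def make_expression(
    genes: Sequence[GeneModel],
    se_genes: Sequence[str],
    coop_genes: Sequence[str],
    classical_genes: Sequence[str],
    samples: Sequence[str],
    effect: tuple[float, float, float] = (8.0, 6.0, 4.0),
    sigma: float = 1.0,
    baseline: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalised expression matrix with an ordered class-effect hierarchy.

    Gene-level latent log2 means are N(mu_class, sigma); per-sample values
    add N(0, sigma/2) noise on the log2 scale and are returned as abundances
    (2**x), i.e. log-normal.  With ``sigma=0`` every value is exactly
    2**mu_class.  Unclassified genes sit at ``baseline``.
    """
    mu_se, mu_coop, mu_cls = effect
    if not mu_se > mu_coop > mu_cls:
        raise ValueError("effect means must be strictly ordered SE > coop > classical")
    rng = np.random.default_rng(seed)
    se_set, coop_set, cls_set = set(se_genes), set(coop_genes), set(classical_genes)
    rows = []
    index = []
    for g in genes:
        if g.gene_id in se_set:
            mu = mu_se
        elif g.gene_id in coop_set:
            mu = mu_coop
        elif g.gene_id in cls_set:
            mu = mu_cls
        else:
            mu = baseline
        gene_mean = rng.normal(mu, sigma) if sigma > 0 else mu
        noise = (
            rng.normal(0.0, sigma / 2, size=len(samples))
            if sigma > 0
            else np.zeros(len(samples))
        )
        rows.append(np.power(2.0, gene_mean + noise))
        index.append(g.gene_id)
    return pd.DataFrame(rows, index=index, columns=list(samples))


CLINICAL_FEATURES = {
    "vertical_growth": ("Absent", "Present"),
    "invasion_level": ("Clark IV", "Clark V"),
    "tumor_thickness": ("Breslow <= 4 mm", "Breslow > 4 mm"),
    "mitoses": ("Low", "High"),
}


def make_clinical(
    cluster_labels: Mapping[str, int],
    odds: float = 10.0,
    seed: int = 0,
    mitoses_odds: float = 1.0,
) -> pd.DataFrame:
    """Binary clinical features with cluster-dependent level probabilities.

    For the aggressive level of each feature, P(aggressive | cluster 1) =
    1/(1+odds) and P(aggressive | cluster 2) = odds/(1+odds): ``odds=1``
    makes every feature independent of the cluster, ``odds=math.inf`` gives
    a perfectly separated deterministic table.  Only labels 1 and 2 are
    accepted (the primary-tumour clusters).
    """
    if not odds >= 1:
        raise ValueError("odds must be >= 1")
    for s, c in cluster_labels.items():
        if c not in (1, 2):
            raise ValueError(f"unknown cluster label {c} for sample {s}")
    rng = np.random.default_rng(seed)
    data: dict[str, list[str]] = {f: [] for f in CLINICAL_FEATURES}
    index = list(cluster_labels)
    for s in index:
        c = cluster_labels[s]
        for feature, (benign, aggressive) in CLINICAL_FEATURES.items():
            o = mitoses_odds if feature == "mitoses" else odds
            if math.isinf(o):
                p_aggr = 0.0 if c == 1 else 1.0
            else:
                p_aggr = (1.0 / (1.0 + o)) if c == 1 else (o / (1.0 + o))
            data[feature].append(aggressive if rng.random() < p_aggr else benign)
    return pd.DataFrame(data, index=index)


def make_regulons(
    driver_tf: str,
    decoy_tfs: Sequence[str],
    se_genes: Sequence[str],
    all_genes: Sequence[str],
    seed: int = 0,
) -> dict[str, set[str]]:
    """Regulon library: the driver's regulon tracks the SE target genes.

    The driver regulon holds ~80% of the super-enhancer target genes plus a
    few unrelated genes; decoy TFs get random regulons of comparable size.
    """
    rng = np.random.default_rng(seed)
    pool = [g for g in all_genes if g not in set(se_genes)]
    n_core = max(1, int(0.8 * len(se_genes)))
    core = list(rng.choice(sorted(se_genes), size=n_core, replace=False))
    extra = list(rng.choice(pool, size=min(5, len(pool)), replace=False))
    regulons = {driver_tf: set(core) | set(extra)}
    size = len(regulons[driver_tf])
    for tf in decoy_tfs:
        regulons[tf] = set(rng.choice(list(all_genes), size=size, replace=False))
    return regulons


def write_regulons(regulons: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(regulons):
            for target in sorted(regulons[tf]):
                fh.write(f"{tf}\t{target}\n")


# ---------------------------------------------------------------------------
# One-call simulation and the round-trip audit


@dataclass(frozen=True)
class SimulationParams:
    n_chrom: int = 2
    chrom_len: int = 8_000_000
    gc: float = 0.41
    n_genes: int = 160
    min_tss_spacing: int = 85_000
    n_pt: int = 17
    n_dm: int = 12
    cohort: CohortConfig = CohortConfig()
    n_pwms: int = 4
    pwm_width: int = 10
    rate_in_se: float = 1.0
    rate_elsewhere: float = 0.01
    expression_effect: tuple[float, float, float] = (8.0, 6.0, 4.0)
    expression_sigma: float = 1.0
    clinical_odds: float = 10.0


def simulate(outdir: str | Path, seed: int,
             params: SimulationParams = SimulationParams()) -> SyntheticTruth:
    """Generate a complete synthetic cohort on disk.

    Writes genome (raw and motif-planted), chrom.sizes, gene models, one
    BED6+2 peak file per sample, sample table, expression and clinical TSVs,
    PWMs, regulons, the motif planting log, and the ground truth JSON.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    genome = make_genome(params.n_chrom, params.chrom_len, params.gc,
                         child_seed(seed, "genome"))
    sizes = {c: len(a) for c, a in genome.items()}
    genes = make_annotation(sizes, params.n_genes, child_seed(seed, "annotation"),
                            params.min_tss_spacing)
    peaks, truth = make_cohort(sizes, genes, params.n_pt, params.n_dm,
                               params.cohort, child_seed(seed, "cohort"))

    counts = make_pwms(params.n_pwms, params.pwm_width, child_seed(seed, "pwms"))
    pwms = {name: pwm_from_counts(name, c) for name, c in counts.items()}
    driver = sorted(pwms)[0]
    truth.driver_tfs = [driver]
    all_se_spans = sorted(
        {iv for ivs in truth.planted_se_regions.values() for iv in ivs},
        key=lambda v: (v.chrom, v.start),
    )
    planted, log = plant_motifs(genome, all_se_spans, {driver: pwms[driver]},
                                params.rate_in_se, params.rate_elsewhere,
                                child_seed(seed, "plant"))

    samples = sorted(peaks)
    expr = make_expression(
        genes,
        truth.se_genes["DM"],
        truth.cooperative_genes,
        truth.classical_genes,
        samples,
        params.expression_effect,
        params.expression_sigma,
        seed=child_seed(seed, "expression"),
    )
    pt_clusters = {s: c for s, c in truth.cluster_labels.items() if c in (1, 2)}
    clinical = make_clinical(pt_clusters, params.clinical_odds,
                             child_seed(seed, "clinical"))
    regulons = make_regulons(
        driver,
        [t for t in sorted(pwms) if t != driver],
        truth.se_genes["DM"],
        [g.gene_id for g in genes],
        child_seed(seed, "regulons"),
    )

    write_genome(genome, outdir / "genome.fa", outdir / "chrom.sizes")
    write_genome(planted, outdir / "genome.planted.fa")
    write_genes_bed12(genes, outdir / "genes.bed12")
    for s in samples:
        write_peaks(peaks[s], outdir / "peaks" / f"{s}.bed")
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample\tgroup\tcluster\n")
        for s in samples:
            fh.write(f"{s}\t{truth.sample_groups[s]}\t{truth.cluster_labels[s]}\n")
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index_label="sample")
    write_jaspar(counts, outdir / "pwms.jaspar")
    write_regulons(regulons, outdir / "regulons.tsv")
    with open(outdir / "motif_planting.tsv", "w") as fh:
        fh.write("chrom\tstart\ttf\tstrand\tskipped\n")
        for r in log:
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['tf']}\t{r['strand']}\t"
                     f"{int(r['skipped'])}\n")
    truth.to_json(outdir / "truth.json")
    return truth


def audit_truth(outdir: str | Path, stitch_distance: int = 12500) -> dict:
    """Verify that the planted ground truth is recoverable from files alone.

    Checks, from the emitted peak files and truth JSON only: every planted
    super-enhancer region contains >= 3 constituent peak footprints within
    stitching reach of each other in >= 2 samples of its group, and every
    cooperative gene has >= 5 planted enhancers whose pairwise gaps all
    exceed the stitching distance.  Returns summary counts; raises on
    violation.
    """
    outdir = Path(outdir)
    truth = SyntheticTruth.from_json(outdir / "truth.json")
    sample_peaks = {
        s: read_peaks(outdir / "peaks" / f"{s}.bed", sample_id=s)
        for s in truth.sample_groups
    }
    for group, regions in truth.planted_se_regions.items():
        group_samples = [s for s, g in truth.sample_groups.items() if g == group]
        for region in regions:
            n_supporting = 0
            for s in group_samples:
                inside = [
                    p.interval
                    for p in sample_peaks[s]
                    if p.interval.chrom == region.chrom
                    and p.interval.start >= region.start - 100
                    and p.interval.end <= region.end + 100
                ]
                inside.sort(key=lambda iv: iv.start)
                chained = len(inside) >= 3 and all(
                    b.start - a.end <= stitch_distance
                    for a, b in zip(inside, inside[1:])
                )
                if chained:
                    n_supporting += 1
            if n_supporting < 2:
                raise AssertionError(
                    f"planted SE {region} lacks a >=3-peak chain in >=2 {group} samples"
                )
    coop_elems: dict[str, list[GenomicInterval]] = {}
    for e in truth.elements:
        if e.kind == "coop_enh":
            coop_elems.setdefault(e.parent, []).append(e.interval)
    for gene in truth.cooperative_genes:
        ivs = sorted(coop_elems.get(gene, []), key=lambda v: v.start)
        if len(ivs) < 5:
            raise AssertionError(f"cooperative gene {gene} has {len(ivs)} enhancers")
        for a, b in zip(ivs, ivs[1:]):
            if b.start - a.end <= stitch_distance:
                raise AssertionError(
                    f"cooperative gene {gene}: enhancers within stitching reach"
                )
    return {
        "n_se_regions": sum(len(v) for v in truth.planted_se_regions.values()),
        "n_cooperative_genes": len(truth.cooperative_genes),
    }
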