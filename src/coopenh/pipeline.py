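"""End-to-end orchestration of the regulatory-element hierarchy analysis.

``run_all`` consumes a cohort directory (per-sample peak BEDs, gene models,
genome FASTA, expression and clinical TSVs, PWMs, regulons — the layout
written by :func:`coopenh.synthdata.simulate`) and executes every stage:
per-group consensus, annotation, super-enhancer calling, cooperative-gene
classification, group-specific element sets, sample clustering, clinical
association, expression hierarchy and the two-step upstream-TF inference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coopenh import coopnet, intervals, motifscan, secall, stats
from coopenh.intervals import ConsensusPeak, GenomicInterval, Peak

_CONFIG_RANGES = {
    "stitch_distance": (0, 10_000_000),
    "tss_exclusion": (0, 1_000_000),
    "proximal_window": (0, 10_000_000),
    "min_overlap": (1, 10_000),
    "cooperative_k": (1, 10_000),
    "motif_q": (0.0, 1.0),
    "enrich_q": (0.0, 1.0),
    "min_expr": (0.0, float("inf")),
    "k_clusters": (2, 10_000),
    "seed": (0, 2**31 - 1),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric threshold of the analysis, with auditable defaults."""

    stitch_distance: int = 12500
    tss_exclusion: int = 3000
    proximal_window: int = 50000
    min_overlap: int = 2
    cooperative_k: int = 5
    motif_q: float = 0.1
    enrich_q: float = 0.1
    min_expr: float = 0.0
    k_clusters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    config: PipelineConfig
    consensus: dict[str, list[ConsensusPeak]]  # per group + "ALL"
    annotation_summary: dict[str, pd.DataFrame]
    elements: dict[str, list[secall.StitchedElement]]
    associations: dict[str, list[secall.GeneAssociation]]
    gene_counts: dict[str, list[coopnet.GeneRECount]]
    cooperative_genes: dict[str, set[str]]
    class_histogram: dict[str, pd.DataFrame]
    specificity: pd.DataFrame
    cluster_labels: pd.Series
    dendrogram_order: list[str]
    clinical: pd.DataFrame | None
    hierarchy: stats.HierarchyResult | None
    regulon_enrichment: pd.DataFrame | None
    tf_enrichment: pd.DataFrame | None


def _read_samples(datadir: Path) -> pd.DataFrame:
    path = datadir / "samples.tsv"
    if not path.exists():
        raise FileNotFoundError(str(path))
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(str(path))
    return path


def consensus_signal_matrix(
    regions: Sequence[ConsensusPeak], peaks_by_sample: Mapping[str, Sequence[Peak]]
) -> pd.DataFrame:
    """Elements x samples matrix of per-sample input-normalised signal.

    A sample's value on a region is the sum, over its peaks overlapping the
    region, of max(0, chip - input) * peak_length; absent peaks give 0.
    """
    samples = sorted(peaks_by_sample)
    index = [
        f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}" for r in regions
    ]
    mat = np.zeros((len(regions), len(samples)))
    region_index: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        region_index.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end, i)
        )
    for lst in region_index.values():
        lst.sort()
    for j, s in enumerate(samples):
        for p in peaks_by_sample[s]:
            for rs, re_, i in region_index.get(p.interval.chrom, ()):
                if rs >= p.interval.end:
                    break
                if re_ > p.interval.start:
                    mat[i, j] += max(0.0, p.chip_density - p.input_density) * len(
                        p.interval
                    )
    return pd.DataFrame(mat, index=index, columns=samples)


def _region_sequences(
    genome: Mapping[str, np.ndarray], regions: Sequence[GenomicInterval]
) -> dict[str, str]:
    out = {}
    for iv in regions:
        out[f"{iv.chrom}:{iv.start}-{iv.end}"] = (
            genome[iv.chrom][iv.start : iv.end].tobytes().decode("ascii")
        )
    return out


def tf_inference(
    genome: Mapping[str, np.ndarray],
    chrom_sizes: Mapping[str, int],
    re_regions: Sequence[GenomicInterval],
    target_genes: set[str],
    regulons: Mapping[str, set[str]],
    universe: set[str],
    pwms: Mapping[str, motifscan.PWM],
    excluded: Sequence[GenomicInterval],
    seed: int,
    motif_q: float = 0.1,
    enrich_q: float = 0.1,
    scan_all_pwms: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step upstream-TF inference on a regulatory-element set.

    Step 1 ranks TFs by regulon over-representation in the target gene list;
    step 2 validates the selected TFs (or all supplied PWMs when
    ``scan_all_pwms``) by motif scanning of the element sequence against a
    shuffled background, with chi-squared binding-difference ranking.
    Returns (regulon table, enrichment table).
    """
    overrep = motifscan.regulon_overrepresentation(
        target_genes, dict(regulons), universe, q_threshold=enrich_q
    )
    if scan_all_pwms:
        candidates = sorted(pwms)
    else:
        candidates = [
            tf for tf in overrep.loc[overrep["selected"], "tf"] if tf in pwms
        ]
        if not candidates:
            candidates = sorted(pwms)
    bg_regions = motifscan.shuffle_background(
        list(re_regions), chrom_sizes, seed=seed, excluded=list(excluded)
    )
    re_seqs = _region_sequences(genome, re_regions)
    bg_seqs = _region_sequences(genome, bg_regions)
    background = motifscan.genome_background({**re_seqs, **bg_seqs})
    re_bound: dict[str, list[bool]] = {}
    bg_bound: dict[str, list[bool]] = {}
    for tf in candidates:
        pwm = motifscan.with_background(pwms[tf], background)
        dist = motifscan.score_distribution(pwm)
        hits_re = motifscan.scan(re_seqs, pwm, q_threshold=motif_q, dist=dist)
        hits_bg = motifscan.scan(bg_seqs, pwm, q_threshold=motif_q, dist=dist)
        bound_re = {h.interval.chrom for h in hits_re}
        bound_bg = {h.interval.chrom for h in hits_bg}
        re_bound[tf] = [name in bound_re for name in re_seqs]
        bg_bound[tf] = [name in bound_bg for name in bg_seqs]
    records = motifscan.tf_enrichment(re_bound, bg_bound, q_threshold=enrich_q)
    return overrep, motifscan.enrichment_table(records)


def run_all(
    datadir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    scan_all_pwms: bool = False,
) -> RunResult:
    """Execute the full analysis on a cohort directory.

    ``scan_all_pwms`` bypasses the regulon pre-selection in the TF-inference
    step and validates every supplied PWM against the shuffled background.
    """
    datadir = Path(datadir)
    sizes = intervals.read_chrom_sizes(_require(datadir / "chrom.sizes"))
    genes = intervals.read_genes_bed12(_require(datadir / "genes.bed12"))
    samples = _read_samples(datadir)
    peaks_by_sample = {
        row["sample"]: intervals.read_peaks(
            _require(datadir / "peaks" / f"{row['sample']}.bed"),
            sample_id=row["sample"],
            chrom_sizes=sizes,
        )
        for _, row in samples.iterrows()
    }
    groups = {g: list(df["sample"]) for g, df in samples.groupby("group")}

    # Consensus occupancy per group and overall.
    cons: dict[str, list[ConsensusPeak]] = {}
    for g, ss in groups.items():
        cons[g] = intervals.consensus(
            [peaks_by_sample[s] for s in ss], min_overlap=config.min_overlap
        )
    cons["ALL"] = intervals.consensus(
        [peaks_by_sample[s] for s in samples["sample"]],
        min_overlap=config.min_overlap,
    )

    ann_summary = {
        g: intervals.annotation_summary(
            intervals.annotate(
                [cp.as_peak() for cp in cons[g]],
                genes,
                tss_window=config.tss_exclusion,
            )
        )
        for g in groups
    }

    # Super-enhancer calling and target mapping per group.
    se_config = secall.SECallConfig(
        stitch_distance=config.stitch_distance,
        tss_exclusion=config.tss_exclusion,
        proximal_window=config.proximal_window,
    )
    elements: dict[str, list[secall.StitchedElement]] = {}
    associations: dict[str, list[secall.GeneAssociation]] = {}
    gene_counts: dict[str, list[coopnet.GeneRECount]] = {}
    coop_genes: dict[str, set[str]] = {}
    histograms: dict[str, pd.DataFrame] = {}
    for g in groups:
        elems = secall.call_elements(
            [cp.as_peak() for cp in cons[g]], genes, se_config
        )
        elements[g] = elems
        assoc = secall.map_targets(elems, genes, config.proximal_window)
        associations[g] = assoc
        labels = {e.element_id: ("SE" if e.is_super else "ENH") for e in elems}
        counts = coopnet.count_res_per_gene(assoc, labels, k=config.cooperative_k)
        gene_counts[g] = counts
        coop_genes[g], histograms[g] = coopnet.classify_cooperative(
            counts, k=config.cooperative_k
        )
    group_names = sorted(groups)
    if len(group_names) == 2:
        specificity = coopnet.specificity_summary(
            elements[group_names[0]],
            elements[group_names[1]],
            label_a=group_names[0],
            label_b=group_names[1],
        )
    else:
        specificity = pd.DataFrame()

    # Sample clustering on the overall consensus signal matrix.
    matrix = consensus_signal_matrix(cons["ALL"], peaks_by_sample)
    cluster_labels, dendro = stats.cluster_samples(matrix, k=config.k_clusters)

    # Clinical association on the primary-tumour clusters.
    clinical_table = None
    clin_path = datadir / "clinical.tsv"
    if clin_path.exists() and "PT" in groups:
        clinical = pd.read_csv(clin_path, sep="\t", index_col=0)
        pt_labels = cluster_labels[cluster_labels.index.isin(groups["PT"])]
        top2 = pt_labels.value_counts().index[:2]
        usable = pt_labels[pt_labels.isin(top2)]
        if usable.nunique() == 2 and len(usable) >= 4:
            clinical_table = stats.clinical_association(
                clinical.loc[clinical.index.isin(usable.index)],
                usable.to_dict(),
            )

    # Expression hierarchy on the metastatic group (falls back to the last
    # group name alphabetically when no DM group is present).
    hier = None
    expr_path = datadir / "expression.tsv"
    focus = "DM" if "DM" in groups else group_names[-1]
    overrep = enrichment = None
    if expr_path.exists():
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        expressed = stats.expressed_filter(
            expr, groups[focus], min_mean=config.min_expr
        )
        focus_elems = elements[focus]
        se_ids = {e.element_id for e in focus_elems if e.is_super}
        se_targets = {
            a.gene_id for a in associations[focus] if a.element_id in se_ids
        }
        counts_by_gene = {c.gene_id: c for c in gene_counts[focus]}
        coop_set = coop_genes[focus]
        classical_set = {
            g
            for g, c in counts_by_gene.items()
            if 1 <= c.n_enhancers < config.cooperative_k
        }
        try:
            hier = stats.expression_hierarchy(
                expr,
                se_targets & expressed,
                coop_set & expressed,
                (classical_set - se_targets - coop_set) & expressed,
                group_samples=groups[focus],
            )
        except ValueError:
            hier = None

        # Two-step TF inference on the focus group's super-enhancers.
        pwm_path = datadir / "pwms.jaspar"
        reg_path = datadir / "regulons.tsv"
        genome_path = (
            datadir / "genome.planted.fa"
            if (datadir / "genome.planted.fa").exists()
            else datadir / "genome.fa"
        )
        if pwm_path.exists() and reg_path.exists() and genome_path.exists():
            from coopenh.synthdata import read_genome

            genome = read_genome(genome_path)
            pwms = {p.name: p for p in motifscan.read_jaspar(pwm_path)}
            regulons = motifscan.read_regulons(reg_path)
            se_regions = [e.interval for e in focus_elems if e.is_super]
            if se_regions:
                overrep, enrichment = tf_inference(
                    genome,
                    sizes,
                    se_regions,
                    se_targets & expressed,
                    regulons,
                    set(expr.index),
                    pwms,
                    excluded=[cp.interval for cp in cons["ALL"]],
                    seed=config.seed,
                    motif_q=config.motif_q,
                    enrich_q=config.enrich_q,
                    scan_all_pwms=scan_all_pwms,
                )

    return RunResult(
        config=config,
        consensus=cons,
        annotation_summary=ann_summary,
        elements=elements,
        associations=associations,
        gene_counts=gene_counts,
        cooperative_genes=coop_genes,
        class_histogram=histograms,
        specificity=specificity,
        cluster_labels=cluster_labels,
        dendrogram_order=dendro,
        clinical=clinical_table,
        hierarchy=hier,
        regulon_enrichment=overrep,
        tf_enrichment=enrichment,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: RunResult, datadir: str | Path, outdir: str | Path) -> list[str]:
    """Write stage outputs and a run manifest; returns written paths."""
    from coopenh import __version__

    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save_df(df: pd.DataFrame | None, name: str) -> None:
        if df is not None and len(df):
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            written.append(str(path))

    for g, cps in result.consensus.items():
        path = outdir / f"consensus_{g}.bed"
        with open(path, "w") as fh:
            for cp in cps:
                iv = cp.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"support={cp.support}\t{cp.support}\t.\n"
                )
        written.append(str(path))
    for g, df in result.annotation_summary.items():
        save_df(df, f"annotation_summary_{g}.tsv")
    for g, elems in result.elements.items():
        save_df(secall.elements_table(elems), f"elements_{g}.tsv")
        se_path, enh_path = secall.write_element_beds(elems, str(outdir / g))
        written.extend([se_path, enh_path])
        save_df(
            pd.DataFrame(
                [
                    {"element_id": a.element_id, "gene_id": a.gene_id,
                     "relation": a.relation}
                    for a in result.associations[g]
                ]
            ),
            f"associations_{g}.tsv",
        )
        save_df(
            pd.DataFrame(
                [
                    {"gene_id": c.gene_id, "n_enhancers": c.n_enhancers,
                     "n_superenhancers": c.n_superenhancers, "re_class": c.re_class}
                    for c in result.gene_counts[g]
                ]
            ),
            f"gene_re_counts_{g}.tsv",
        )
        save_df(result.class_histogram[g], f"class_histogram_{g}.tsv")
        save_df(
            coopnet.enhancers_per_gene_table(result.gene_counts[g]),
            f"enhancers_per_gene_{g}.tsv",
        )
    save_df(result.specificity, "specificity_summary.tsv")
    result.cluster_labels.to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
    written.append(str(outdir / "cluster_labels.tsv"))
    (outdir / "dendrogram_order.txt").write_text(
        "\n".join(result.dendrogram_order) + "\n"
    )
    written.append(str(outdir / "dendrogram_order.txt"))
    save_df(result.clinical, "clinical_association.tsv")
    if result.hierarchy is not None:
        h = result.hierarchy
        rows = [
            {
                "comparison": f"{a}_vs_{b}",
                "p_value": h.pairwise_p[(a, b)],
                "q_value": h.pairwise_q[(a, b)],
            }
            for (a, b) in h.pairwise_p
        ]
        df = pd.DataFrame(rows)
        for cls, m in h.class_means.items():
            df[f"mean_{cls}"] = m
        df["ordered"] = h.ordered
        save_df(df, "expression_hierarchy.tsv")
    save_df(result.regulon_enrichment, "regulon_enrichment.tsv")
    save_df(result.tf_enrichment, "tf_enrichment.tsv")

    manifest = {
        "package_version": __version__,
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "inputs": {
            str(p.relative_to(datadir)): _sha256(p)
            for p in sorted(datadir.rglob("*"))
            if p.is_file()
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    written.append(str(outdir / "run_manifest.json"))
    return written
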