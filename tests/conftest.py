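"""Shared fixtures: tiny hand-built inputs and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from coopenh import pipeline, synthdata
from coopenh.intervals import GeneModel, GenomicInterval, Peak


def iv(chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval:
    return GenomicInterval(chrom, start, end, strand)


def pk(chrom, start, end, sample="s1", chip=1.0, inp=0.1, name="."):
    return Peak(iv(chrom, start, end), sample_id=sample, name=name,
                chip_density=chip, input_density=inp)


@pytest.fixture(scope="session")
def simple_genes() -> list[GeneModel]:
    """Two genes on chr1 (one per strand) and one on chr2."""
    return [
        GeneModel("geneA", "chr1", 100_000, 110_000, "+",
                  exons=((100_000, 102_000), (105_000, 110_000)),
                  cds_start=101_000, cds_end=108_000),
        GeneModel("geneB", "chr1", 200_000, 215_000, "-",
                  exons=((200_000, 204_000), (210_000, 215_000)),
                  cds_start=202_000, cds_end=212_000),
        GeneModel("geneC", "chr2", 50_000, 60_000, "+",
                  exons=((50_000, 60_000),), cds_start=52_000, cds_end=58_000),
    ]


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> str:
    """One full synthetic cohort at default study conditions."""
    d = tmp_path_factory.mktemp("cohort")
    synthdata.simulate(d, seed=11)
    return str(d)


def _overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _f1(n_tp: int, n_fp: int, n_fn: int) -> float:
    return 2 * n_tp / (2 * n_tp + n_fp + n_fn) if n_tp else 0.0


def cohort_recovery_metrics(workdir, seed: int) -> dict:
    """Simulate one cohort, run the full pipeline, score recovery vs truth."""
    d = workdir / f"seed{seed}"
    truth = synthdata.simulate(d, seed=seed)
    res = pipeline.run_all(d, pipeline.PipelineConfig(seed=seed),
                           scan_all_pwms=True)

    planted = truth.planted_se_regions["DM"]
    called = [e for e in res.elements["DM"] if e.is_super]
    se_tp = sum(1 for p in planted if any(_overlaps(p, c.interval) for c in called))
    se_fp = sum(1 for c in called if not any(_overlaps(p, c.interval) for p in planted))
    recovered = res.cooperative_genes["DM"]
    true_coop = set(truth.cooperative_genes)
    coop_tp = len(recovered & true_coop)

    ari = adjusted_rand_score(
        [truth.cluster_labels[s] for s in res.cluster_labels.index],
        res.cluster_labels.to_numpy(),
    )
    top = res.tf_enrichment.iloc[0]
    hierarchy = res.hierarchy
    return {
        "se_f1": _f1(se_tp, se_fp, len(planted) - se_tp),
        "coop_f1": _f1(coop_tp, len(recovered - true_coop), len(true_coop - recovered)),
        "ari": ari,
        "top_tf": top["tf"],
        "top_selected": bool(top["selected"]),
        "driver_tf": truth.driver_tfs[0],
        "hierarchy_ordered": hierarchy.ordered,
        "hierarchy_max_q": max(hierarchy.pairwise_q.values()),
    }


@pytest.fixture(scope="session")
def recovery_batch(tmp_path_factory) -> list[dict]:
    """Recovery metrics over 20 seeded synthetic cohorts at default conditions."""
    work = tmp_path_factory.mktemp("batch")
    return [cohort_recovery_metrics(work, seed) for seed in range(101, 121)]
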