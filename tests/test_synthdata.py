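"""The synthetic cohort generator: contracts, determinism, planted recovery."""

import filecmp
import math

import numpy as np
import pytest
from scipy import stats as sps

from coopenh import synthdata
from coopenh.intervals import GenomicInterval
from coopenh.motifscan import pwm_from_counts
from coopenh.synthdata import (
    CohortConfig,
    SimulationParams,
    make_annotation,
    make_clinical,
    make_cohort,
    make_expression,
    make_genome,
    make_pwms,
    plant_motifs,
)


# ---------------------------------------------------------------------------
# genome


def test_genome_length_contract():
    genome = make_genome(1, 1_000_000, gc=0.5, seed=7)
    assert list(genome) == ["chr1"]
    assert len(genome["chr1"]) == 1_000_000


def test_genome_determinism_byte_identical(tmp_path):
    for d in ("a", "b"):
        (tmp_path / d).mkdir()
        g = make_genome(2, 500_000, gc=0.41, seed=1)
        synthdata.write_genome(g, tmp_path / d / "g.fa", tmp_path / d / "g.sizes")
    assert filecmp.cmp(tmp_path / "a" / "g.fa", tmp_path / "b" / "g.fa", shallow=False)
    assert filecmp.cmp(tmp_path / "a" / "g.sizes", tmp_path / "b" / "g.sizes",
                       shallow=False)


def test_genome_gc_within_binomial_bound():
    n, gc = 1_000_000, 0.6
    genome = make_genome(1, n, gc=gc, seed=3)
    observed = np.isin(genome["chr1"], np.frombuffer(b"GC", dtype=np.uint8)).sum()
    sd = math.sqrt(n * gc * (1 - gc))
    assert abs(observed - n * gc) < 3 * sd


def test_genome_rejects_bad_parameters():
    with pytest.raises(ValueError):
        make_genome(0, 1_000_000)
    with pytest.raises(ValueError):
        make_genome(1, 100)  # below the 200 kb minimum


# ---------------------------------------------------------------------------
# annotation


def test_annotation_empty_is_valid(tmp_path):
    genes = make_annotation({"chr1": 1_000_000}, 0, seed=1)
    assert genes == []
    from coopenh.intervals import read_genes_bed12, write_genes_bed12

    write_genes_bed12(genes, tmp_path / "empty.bed12")
    assert read_genes_bed12(tmp_path / "empty.bed12") == []


def test_annotation_bounds_and_spacing():
    sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
    genes = make_annotation(sizes, 18, seed=2, min_tss_spacing=50_000)
    assert len(genes) == 18
    by_chrom = {}
    for g in genes:
        assert 0 <= g.start < g.end <= sizes[g.chrom]
        assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    for tsss in by_chrom.values():
        assert min(np.diff(sorted(tsss)), default=50_000) >= 50_000


def test_annotation_infeasible_spacing_rejected():
    with pytest.raises(ValueError, match="cannot place"):
        make_annotation({"chr1": 300_000}, 100, seed=0, min_tss_spacing=5_000,
                        edge_margin=10_000)


# ---------------------------------------------------------------------------
# cohort


SMALL = CohortConfig(n_se=10, n_coop_genes=8, n_classical_genes=8,
                     n_background=40)


def _small_layout(seed=11):
    sizes = {"chr1": 4_000_000, "chr2": 4_000_000}
    genes = make_annotation(sizes, 40, seed=seed)
    return sizes, genes


def test_cohort_construction_contract():
    sizes, genes = _small_layout()
    peaks, truth = make_cohort(sizes, genes, n_pt=6, n_dm=6, config=SMALL, seed=11)
    assert len(peaks) == 12
    dm_samples = [s for s, g in truth.sample_groups.items() if g == "DM"]
    for region in truth.planted_se_regions["DM"]:
        n_support = 0
        for s in dm_samples:
            inside = [
                p for p in peaks[s]
                if p.interval.chrom == region.chrom
                and p.interval.start >= region.start - 100
                and p.interval.end <= region.end + 100
            ]
            if len(inside) >= 3:
                n_support += 1
        assert n_support >= 2
    # group-specific elements never appear in the other group
    pt_samples = [s for s, g in truth.sample_groups.items() if g == "PT"]
    dm_only_ids = {e.element_id for e in truth.elements if e.group in ("dm", "c3")}
    for s in pt_samples:
        assert not {p.name for p in peaks[s]} & dm_only_ids


def test_cohort_determinism():
    sizes, genes = _small_layout()
    p1, t1 = make_cohort(sizes, genes, 6, 6, SMALL, seed=4)
    p2, t2 = make_cohort(sizes, genes, 6, 6, SMALL, seed=4)
    assert p1 == p2
    assert t1.cooperative_genes == t2.cooperative_genes
    assert t1.planted_se_regions == t2.planted_se_regions


def test_cohort_signal_ratio_recovered_from_peaks():
    sizes, genes = _small_layout(seed=5)
    config = CohortConfig(n_se=10, n_coop_genes=8, n_classical_genes=10,
                          n_background=40, se_signal_ratio=10.0)
    peaks, truth = make_cohort(sizes, genes, 8, 8, config, seed=5)

    def mean_element_signal(regions):
        vals = []
        for region in regions:
            per_sample = []
            for sample_peaks in peaks.values():
                sig = sum(
                    max(0.0, p.chip_density - p.input_density) * len(p.interval)
                    for p in sample_peaks
                    if p.interval.chrom == region.chrom
                    and p.interval.start >= region.start - 100
                    and p.interval.end <= region.end + 100
                )
                if sig > 0:
                    per_sample.append(sig)
            vals.append(np.mean(per_sample))
        return float(np.mean(vals))

    se_regions = sorted(
        {iv for ivs in truth.planted_se_regions.values() for iv in ivs},
        key=lambda v: (v.chrom, v.start),
    )
    cls_regions = [
        e.interval for e in truth.elements if e.kind == "classical_enh"
    ]
    ratio = mean_element_signal(se_regions) / mean_element_signal(cls_regions)
    assert 7.0 <= ratio <= 13.0


def test_cohort_contradictory_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(se_fraction_dm=0.8, se_fraction_shared=0.5)
    with pytest.raises(ValueError):
        CohortConfig(detect_prob=1.5)


# ---------------------------------------------------------------------------
# motif planting


def _pwm_set():
    counts = make_pwms(2, width=8, seed=9)
    return {name: pwm_from_counts(name, c) for name, c in counts.items()}


def test_plant_rate_zero_elsewhere_stays_in_se():
    genome = make_genome(1, 300_000, seed=1)
    spans = [GenomicInterval("chr1", 50_000, 80_000)]
    pwms = _pwm_set()
    driver = sorted(pwms)[0]
    mutated, log = plant_motifs(genome, spans, {driver: pwms[driver]},
                                rate_in_se=2.0, rate_elsewhere=0.0, seed=2)
    placed = [r for r in log if not r["skipped"]]
    assert placed, "expected at least one planted instance"
    for r in placed:
        assert 50_000 <= r["start"] <= 80_000 - 8


def test_plant_count_within_poisson_band():
    genome = make_genome(1, 300_000, seed=1)
    spans = [GenomicInterval("chr1", 100_000, 110_000)]  # 10 kb at 2/kb -> 20
    pwms = _pwm_set()
    driver = sorted(pwms)[0]
    _, log = plant_motifs(genome, spans, {driver: pwms[driver]},
                          rate_in_se=2.0, rate_elsewhere=0.0, seed=6)
    n = sum(1 for r in log if not r["skipped"])
    lo, hi = sps.poisson.ppf([0.005, 0.995], 20)
    assert lo <= n <= hi


def test_plant_empty_pwm_set_is_identity():
    genome = make_genome(1, 250_000, seed=4)
    mutated, log = plant_motifs(genome, [GenomicInterval("chr1", 0, 1000)], {},
                                rate_in_se=1.0, rate_elsewhere=0.0, seed=0)
    assert log == []
    assert (mutated["chr1"] == genome["chr1"]).all()


def test_plant_rejects_inverted_rates():
    genome = make_genome(1, 250_000, seed=4)
    with pytest.raises(ValueError):
        plant_motifs(genome, [], _pwm_set(), rate_in_se=0.1, rate_elsewhere=0.5,
                     seed=0)


def test_plant_skips_pwm_wider_than_span():
    genome = make_genome(1, 250_000, seed=4)
    pwms = _pwm_set()
    driver = sorted(pwms)[0]
    with pytest.warns(UserWarning, match="wider than"):
        _, log = plant_motifs(genome, [GenomicInterval("chr1", 100, 104)],
                              {driver: pwms[driver]}, rate_in_se=500.0,
                              rate_elsewhere=0.0, seed=1)
    assert all(r["skipped"] for r in log)


# ---------------------------------------------------------------------------
# expression


def _genes(n):
    return make_annotation({"chr1": 6_000_000}, n, seed=3, min_tss_spacing=50_000)


def test_expression_class_means_ordered():
    genes = _genes(60)
    ids = [g.gene_id for g in genes]
    se, coop, cls = ids[:20], ids[20:40], ids[40:60]
    expr = make_expression(genes, se, coop, cls, [f"s{i}" for i in range(6)],
                           effect=(8, 6, 4), sigma=1.0, seed=2)
    log_means = np.log2(expr).mean(axis=1)
    assert log_means[se].mean() > log_means[coop].mean() > log_means[cls].mean()


def test_expression_sigma_zero_exact():
    genes = _genes(12)
    ids = [g.gene_id for g in genes]
    expr = make_expression(genes, ids[:4], ids[4:8], ids[8:], ["s1", "s2"],
                           effect=(8, 6, 4), sigma=0.0, seed=0)
    assert (expr.loc[ids[:4]] == 2.0 ** 8).all().all()
    assert (expr.loc[ids[4:8]] == 2.0 ** 6).all().all()
    assert (expr.loc[ids[8:]] == 2.0 ** 4).all().all()


def test_expression_deterministic():
    genes = _genes(12)
    ids = [g.gene_id for g in genes]
    args = (genes, ids[:4], ids[4:8], ids[8:], ["s1", "s2"])
    a = make_expression(*args, seed=9)
    b = make_expression(*args, seed=9)
    assert a.equals(b)


def test_expression_unordered_means_rejected():
    genes = _genes(12)
    ids = [g.gene_id for g in genes]
    with pytest.raises(ValueError):
        make_expression(genes, ids[:4], ids[4:8], ids[8:], ["s1"],
                        effect=(4, 6, 8))


# ---------------------------------------------------------------------------
# clinical


def test_clinical_deterministic_mode_perfectly_separated():
    labels = {f"p{i}": (1 if i < 5 else 2) for i in range(10)}
    clin = make_clinical(labels, odds=math.inf, seed=1)
    for feature in ("vertical_growth", "invasion_level", "tumor_thickness"):
        levels_c1 = set(clin.loc[[f"p{i}" for i in range(5)], feature])
        levels_c2 = set(clin.loc[[f"p{i}" for i in range(5, 10)], feature])
        assert len(levels_c1) == 1 and len(levels_c2) == 1
        assert levels_c1 != levels_c2


def test_clinical_fixed_seed_identical():
    labels = {f"p{i}": 1 + i % 2 for i in range(12)}
    assert make_clinical(labels, seed=3).equals(make_clinical(labels, seed=3))


def test_clinical_unknown_cluster_rejected():
    with pytest.raises(ValueError):
        make_clinical({"p1": 3}, odds=2.0)
    with pytest.raises(ValueError):
        make_clinical({"p1": 1}, odds=0.5)


# ---------------------------------------------------------------------------
# simulation round trip


def test_simulate_deterministic_and_auditable(tmp_path):
    params = SimulationParams(
        n_chrom=2, chrom_len=4_000_000, n_genes=40, n_pt=6, n_dm=6,
        cohort=SMALL,
    )
    d1, d2 = tmp_path / "one", tmp_path / "two"
    synthdata.simulate(d1, seed=21, params=params)
    synthdata.simulate(d2, seed=21, params=params)
    files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
    # planted ground truth is recoverable from the emitted files alone
    summary = synthdata.audit_truth(d1)
    assert summary["n_cooperative_genes"] == SMALL.n_coop_genes
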