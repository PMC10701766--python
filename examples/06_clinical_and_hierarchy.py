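"""Sample clustering, clinical association, and the expression hierarchy.

Clusters samples on their consensus H3K27ac signal profiles, tests the
primary-tumour clusters against binary clinical features with Fisher's
exact test, and compares expression of genes under super-enhancers,
cooperative enhancers and classical enhancers.
"""

from pathlib import Path

from coopenh import pipeline

datadir = Path("scratch/example_cohort")
res = pipeline.run_all(datadir, pipeline.PipelineConfig(seed=11))

print("sample clusters (1/2 = primary-tumour clusters, 3 = metastases):")
print(res.cluster_labels.to_string())

print("\nclinical association (feature level x PT cluster, Fisher p):")
print(res.clinical[["feature", "a", "b", "c", "d", "p_value"]]
      .to_string(index=False))

h = res.hierarchy
print("\nexpression hierarchy (mean abundance per element class):")
for cls, m in h.class_means.items():
    print(f"  {cls:12s} {m:10.1f}")
for pair, q in h.pairwise_q.items():
    print(f"  {pair[0]} vs {pair[1]}: BH q = {q:.2g}")
print(f"  ordered SE > cooperative > classical: {h.ordered}")
print()
print("Chromatin profiles separate disease stages; aggressive clinical")
print("features concentrate in one PT cluster, and genes under SEs are")
print("expressed above cooperative-enhancer targets, which sit above")
print("classical-enhancer targets - a regulatory hierarchy.")
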