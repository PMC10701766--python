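"""Classify genes by the number of classical enhancers converging on them.

A gene regulated by five or more distinct dispersed enhancers is called
cooperative: its elements are too far apart to be stitched into one
super-enhancer but jointly converge on the same promoter.
"""

from pathlib import Path

import pandas as pd

from coopenh import coopnet, intervals, secall

datadir = Path("scratch/example_cohort")
samples = pd.read_csv(datadir / "samples.tsv", sep="\t")
dm = samples.loc[samples["group"] == "DM", "sample"]
consensus = intervals.consensus(
    [intervals.read_peaks(datadir / "peaks" / f"{s}.bed", sample_id=s) for s in dm],
    min_overlap=2,
)
genes = intervals.read_genes_bed12(datadir / "genes.bed12")
elements = secall.call_elements([cp.as_peak() for cp in consensus], genes)
assoc = secall.map_targets(elements, genes)

labels = {e.element_id: ("SE" if e.is_super else "ENH") for e in elements}
counts = coopnet.count_res_per_gene(assoc, labels, k=5)
coop, hist = coopnet.classify_cooperative(counts, k=5)

print(hist.to_string(index=False))
print(f"\ncooperative genes (>=5 enhancers): {len(coop)}")
multi = hist.loc[hist["re_class"] != "single", "n_genes"].sum()
total = hist["n_genes"].sum()
print(f"genes with more than one enhancer: "
      f"{coopnet.share_percent(int(multi), int(total))}% of {total}")
regions = coopnet.cooperative_regions(coop, assoc, elements)
print(f"cooperative regulatory regions (deduplicated): {len(regions)}")
print()
print("The histogram is the enhancer-convergence ranking; the cooperative")
print("regions are the sequence searched for upstream TF motifs next.")
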