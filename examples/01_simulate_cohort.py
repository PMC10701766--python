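"""Generate a synthetic melanoma-style ChIP-seq cohort with planted truth.

Writes a genome, gene models, per-sample H3K27ac peak files, an expression
matrix, a clinical table, PWMs and regulons into ./scratch/example_cohort,
then prints what was planted.  Every downstream example reads this directory.
"""

from pathlib import Path

from coopenh import synthdata

outdir = Path("scratch/example_cohort")
truth = synthdata.simulate(outdir, seed=11)

print(f"cohort written to {outdir}/")
print(f"samples: {sum(g == 'PT' for g in truth.sample_groups.values())} primary "
      f"tumours, {sum(g == 'DM' for g in truth.sample_groups.values())} metastases")
print(f"planted SE regions visible to the DM group: "
      f"{len(truth.planted_se_regions['DM'])}")
print(f"cooperative genes (>=5 dispersed enhancers each): "
      f"{len(truth.cooperative_genes)}")
print(f"driver TF planted into SE sequence: {truth.driver_tfs[0]}")
print()
print("Each number is a piece of ground truth the analysis stages should")
print("recover: SE calling should find the planted regions, the cooperative")
print("classifier the wired genes, and TF inference the planted motif.")
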