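"""Two-step upstream-TF inference on the called super-enhancers.

Step 1 asks which TF regulons are over-represented among SE target genes;
step 2 validates candidates by scanning their binding motifs over SE
sequence versus shuffled background regions, ranking TFs by binding
difference (percent of SEs bound minus percent of background bound).
"""

from pathlib import Path

from coopenh import pipeline

datadir = Path("scratch/example_cohort")
res = pipeline.run_all(datadir, pipeline.PipelineConfig(seed=11),
                       scan_all_pwms=True)

print("step 1 - regulon over-representation among SE target genes:")
print(res.regulon_enrichment[["tf", "overlap", "regulon_size", "p_value",
                              "q_value", "selected"]].to_string(index=False))
print("\nstep 2 - motif validation against shuffled background:")
print(res.tf_enrichment.to_string(index=False))
print()
print("A TF is selected when its motif occurs in significantly more SE")
print("regions than matched background regions (chi-squared q < 0.1) with a")
print("positive binding difference; the top row is the predicted master")
print("regulator of the SE program.")
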