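"""Dataset-level Q3 averaging on the packaged T100 benchmark table.

The package ships the per-protein Q3 accuracies of the PSRSM and
DeepCNF web servers on the T100 benchmark (100 PDB chains released in
early 2018).  Average Q3 is the unweighted mean of per-protein values
over the chains with valid predictions: four chains are too short for
the DeepCNF server, so its mean runs over 96 chains.
"""

from psrsm import average_q3, load_t100_table

df = load_t100_table()
print(f"benchmark chains        : {len(df)} (lengths "
      f"{df.length.min()}-{df.length.max()})")

psrsm_all = df["psrsm_q3"].tolist()
print(f"PSRSM average Q3        : {average_q3(psrsm_all):.2f} % over "
      f"{len(psrsm_all)} chains")

subset = df.loc[df["length"] < 1460, "psrsm_q3"]
print(f"  excluding the 1460-aa chain: {average_q3(subset.tolist()):.2f} % "
      f"over {len(subset)} chains (the published summary figure)")

deepcnf = df["deepcnf_q3"].dropna()
print(f"DeepCNF average Q3      : {average_q3(deepcnf.tolist()):.2f} % over "
      f"{len(deepcnf)} valid chains")
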