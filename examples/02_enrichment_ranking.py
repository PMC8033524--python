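"""Rank genes enriched for insertions in metastatic versus tumour samples.

Plants a single gene with 5-fold elevated insertion diversity in the
metastatic group and shows that the percentage-of-unique-insertions
ranking recovers it at the top, with its two-tailed Mann-Whitney p-value.
"""

import pbscreen as pb

config = pb.SimConfig(
    seed=3, n_chroms=1, chrom_length=500_000, n_genes=10,
    n_insertions_per_sample=80,
    groups=[("tumour", 4), ("metastatic", 4)],
    enriched_genes=[("gene0004", "metastatic", 5.0)],
)

result = pb.run_screen(config)

print("gene groups ranked by delta = mean % (metastatic) - mean % (tumour):\n")
print(f"{'gene':<22}{'% met':>8}{'% tum':>8}{'delta':>8}{'U':>6}{'p':>9}")
for r in result.ranking[:6]:
    print(f"{r.gene_id:<22}{r.mean_pct_met:>8.2f}{r.mean_pct_tum:>8.2f}"
          f"{r.delta:>8.2f}{r.U:>6.0f}{r.p_two_sided:>9.3f}")

top = result.ranking[0]
print(f"\nthe planted gene was gene0004; rank 1 is {top.gene_id}.")
print("each column of the underlying matrix sums to 100: a gene's value is "
      "its summed shear-end diversity as a share of the sample total.")
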