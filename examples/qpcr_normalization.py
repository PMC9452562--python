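"""qPCR: pick stable reference genes with geNorm, normalize, compare groups.

Generates a Ct matrix whose reference candidates include one unstable gene,
ranks candidates by the geNorm M value, normalizes targets by the geometric
mean of the selected references, and tests vehicle vs treated with BH FDR.
"""

from pdxscreen import qpcr, synthetic

config = synthetic.SyntheticConfig(seed=1)
ct, groups, truth = synthetic.gen_qpcr(config)
candidates = list(config.qpcr.stable_genes) + list(config.qpcr.unstable_genes)

m = qpcr.genorm_stability(ct, candidates)
print("geNorm stability (lower M = more stable):")
print(m.round(3).to_string())

kept, excluded = qpcr.genorm_select(ct, candidates, n_keep=2)
print(f"\nselected references: {kept} (excluded first: {excluded})")

norm = qpcr.normalize_ct(ct, kept)
print(f"\nrelative expression (2^-dCt vs reference geomean), first samples:")
print(norm.expression.iloc[:, :4].round(3).to_string())

result = qpcr.compare_groups(norm.expression, groups)
print("\nvehicle vs treated (rank-sum, BH FDR):")
print(result.round(4).to_string())
print("\nGenes with q < 0.05 differ between groups after multiplicity "
      "control; the generator plants the effect on "
      f"{list(config.qpcr.affected_genes)}.")
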