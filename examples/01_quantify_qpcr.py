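"""Relative quantification: from raw Cq values to a rescaled table.

Synthesizes a small single-bud experiment's raw qPCR output (technical
replicates + dilution series), fits per-gene standard curves, inverts Cq
to quantities, normalizes to the reference gene and rescales each gene
to its highest stage median.
"""

import singlebud as sb

design = sb.study_design(seed=42, stage_sizes={"S1": 4, "S2": 4,
                                               "S3": 12, "S4": 4})
records, dilutions, _, truth = sb.generate_cq(design, cq_noise_sd=0.05)
print(f"{len(records)} Cq measurements "
      f"({len(design.genes) + 1} amplicons incl. reference, 2-3 replicates)")

# fit one standard curve per amplicon from its ten-fold dilution series
curves = {}
for gene, grp in dilutions.groupby("gene"):
    curves[gene] = sb.fit_standard_curve(
        list(zip(grp["log10_quantity"], grp["cq"])), gene)
ex = curves["DAM1-like"]
print(f"DAM1-like curve: slope {ex.slope:.3f} Cq/decade, "
      f"efficiency {100 * ex.efficiency:.1f}% (100% = perfect doubling), "
      f"R^2 {ex.r_squared:.4f}")

table, qc = sb.quantify_cq_table(records, curves, reference_gene="SAND-like")
print(f"high-spread replicate groups flagged: {int(qc['high_spread'].sum())} "
      f"of {len(qc)} (replicate range > 0.5 cycles)")

table, dropped = sb.filter_undetected_genes(table, min_detected_fraction=0.5)
print(f"amplicons dropped as undetected: {dropped}")

rescaled = sb.rescale_to_max_stage_median(table)
med = rescaled.stage_medians("DAM1-like")
print("DAM1-like stage medians after rescaling:",
      {s: round(v, 3) for s, v in med.items()})
print("(the dormant stage sits at 1 by construction; the released stage "
      "shows the fold drop of this dormancy marker)")
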