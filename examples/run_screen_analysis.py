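"""Screen analysis on a small plate with planted drug effects.

Builds a 15-compound plate (12 inactive compounds, one anti-CSC, one
anti-CAF, one pan-cytotoxic plant), computes percent change vs the control
wells, Blom-normalizes, clusters with centroid linkage, and applies the
selection rules.  The printed classifications show the planted effects
recovered and the nonselective compound excluded by the >80% rule.
"""

import nichescreen as ns

effects = {f"cmpd_{i:02d}": ns.EffectModel() for i in range(12)}
effects["anti_csc_plant"] = ns.EffectModel(csc_fraction=0.2)   # CSC fraction x0.2
effects["anti_caf_plant"] = ns.EffectModel(caf_survival=0.3)   # CAF survival x0.3
effects["pan_tox_plant"] = ns.EffectModel(
    csc_fraction=0.1, colony_count=0.1, cancer_survival=0.1, caf_survival=0.1
)

base = ns.FieldSpec(width_px=300, height_px=300, n_caf=200, n_cancer=60,
                    n_colonies=1, colony_radius_um=140.0,
                    noise_sd=(0.0, 0.0, 0.0), seed=7)
plate = ns.generate_plate(effects, base, n_control_wells=3)

pct = ns.summarize_screen(plate.phenotypes, plate.annotation)
tree = ns.cluster_compounds(ns.normalize_matrix(pct))
hits = ns.select_hits(tree, pct)

print(f"{len(plate.annotation)} wells, {len(pct)} compounds, "
      f"{len(hits)} flat clusters\n")
for h in hits:
    members = ", ".join(h.compounds[:4]) + (" ..." if len(h.compounds) > 4 else "")
    print(f"cluster {h.cluster} -> {h.classification:<9} "
          f"(CSC {h.mean_change['total_cscs']:+.0%}, "
          f"CAF {h.mean_change['total_cafs']:+.0%}): {members}")

# percent changes are (drug - control)/control on cluster means: the
# anti-CSC plant loses ~80% of CSCs while sparing CAFs (<15%), the
# anti-CAF plant loses ~70% of CAFs, and the pan-cytotoxic plant is
# excluded because CSCs, colonies and colony cells all drop by >80%.
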