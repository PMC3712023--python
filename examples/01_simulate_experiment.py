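"""Simulate a two-color MeDIP-chip promoter tiling experiment.

Builds a 100-promoter design (each promoter tiled 3,880 bp upstream to
970 bp downstream of its TSS with 50-75 nt probes every 100 bp), plants
differential methylation in 10% of promoters, and generates three paired
treatment-vs-control hybridizations with dye bias and noise.
"""

import medipchip as mc

cfg = mc.SimConfig(n_promoters=100, dmr_fraction=0.1, effect_size=1.0, seed=42)
design = mc.generate_design(cfg)
arrays, manifest = mc.generate_medip_experiment(design, cfg)

print(f"design: {len(design)} probes over {design.probes['promoter_id'].nunique()} "
      f"promoters on {len(design.chromosomes())} chromosomes")
print(f"comparative hybridizations: {[a.comparison_id for a in arrays]}")
print(f"planted DMRs: {len(manifest.planted_dmrs)} "
      f"(each a >=600 bp region shifted by {cfg.effect_size} M units)")
print(manifest.planted_dmrs.head(3).to_string(index=False))
# Each row is one planted ground-truth region: its promoter, coordinates and
# the methylation effect (log2-ratio shift) that downstream calling must find.
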