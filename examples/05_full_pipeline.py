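"""One-call pipeline run on a scaled-down synthetic study.

Runs every stage (contaminants -> filter -> diversity -> SparCC networks ->
topology -> keystones -> robustness battery -> differential abundance) and
lists the artifacts.  The robustness battery is scaled down here (k = 50
additions, 10 bootstrap attacks) so the example finishes in seconds; the
defaults used by `micronet run` match the full study protocol.
"""

from micronet import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(seed=7, outdir="example_out/pipeline")
cfg.sim = SimConfig(n_taxa=20, seed=7)
cfg.k_values = (50,)
cfg.n_boot = 10
cfg.sparcc_resamples = 10
cfg.n_mc_instances = 16
cfg.n_perm = 199

out = run_pipeline(cfg)
print(f"artifacts in {out}:")
for f in sorted(out.iterdir()):
    print(f"  {f.name}")
print("topology.tsv holds one row per (group x timepoint) network; "
      "attack_fractions.tsv is the removal-robustness summary.")
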