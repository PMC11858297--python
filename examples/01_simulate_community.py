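"""Generate a synthetic rhizosphere community with known structure.

Draws a 60-taxon, 30-sample count table whose taxa fall into 3 planted
correlation modules with planted hub taxa, plus a soil/plant covariate
table from a known path model, and prints what the ground truth contains.
"""

from rhizonet import synthetic

config = synthetic.demo_scenario(seed=7)
table, taxonomy, truth = synthetic.generate_modular_abundances(config)
metadata, path_truth = synthetic.generate_soil_plant_table(config, config.n_samples)

print(f"count table: {table.shape[0]} taxa x {table.shape[1]} samples")
print(f"column sums all equal sequencing depth: "
      f"{(table.sum(axis=0) == config.sequencing_depth).all()}")
sizes = {}
for module in truth.module_assignment.values():
    sizes[module] = sizes.get(module, 0) + 1
print(f"planted modules (taxa per module): {sizes}")
print(f"planted hub taxa: {truth.planted_roles}")
print(f"covariate table: {metadata.shape[1]} variables, "
      f"{len(path_truth.true_paths)} true causal paths")
# Every downstream stage (network, modules, Zi/Pi, SEM) can be scored
# against this truth: the generator is the benchmark, not just a demo.
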