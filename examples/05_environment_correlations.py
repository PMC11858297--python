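"""Spearman screen between soil, plant and microbiome summary variables.

Produces the long-format table behind a correlation heatmap: rho, raw p,
BH-adjusted q and significance stars for every variable pair.
"""

from rhizonet import envcorr, synthetic

config = synthetic.demo_scenario(seed=7)
features, truth = synthetic.generate_soil_plant_table(config, 120)

corr = envcorr.spearman_matrix(features)
long = corr.to_long()
strong = long[long["stars"] != ""].sort_values("p").head(10)
print(strong.round(4).to_string(index=False))
print(f"\n{len(long)} pairs screened, "
      f"{(long['stars'] != '').sum()} significant at raw p < 0.05, "
      f"{(long['q'] < 0.05).sum()} at BH q < 0.05")
print("the strongest associations are exactly the generator's true paths "
      f"(e.g. NN->RW = {truth.true_paths[('NN', 'RW')]})")
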