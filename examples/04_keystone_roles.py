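"""Module detection and Zi/Pi keystone-role classification.

Zi (within-module connectivity) and Pi (among-module connectivity)
classify each taxon as peripheral, connector, module hub or network hub;
non-peripheral taxa are the keystone taxa.  Thresholds: Zi > 2.5 for
hubs, Pi > 0.62 for connectors.
"""

from rhizonet import keystone, network, synthetic

config = synthetic.demo_scenario(seed=11)
table, taxonomy, truth = synthetic.generate_modular_abundances(config)
net = network.correlation_network(network.filter_taxa(table, 0.2))

partition, q = keystone.detect_modules(net)
sizes = {}
for module in partition.values():
    sizes[module] = sizes.get(module, 0) + 1
n_major = sum(1 for s in sizes.values() if s > 1)
print(f"detected {n_major} multi-taxon modules "
      f"(+ {len(sizes) - n_major} isolated singletons), "
      f"modularity Q = {q:.3f}")

roles = keystone.node_roles(net, partition, taxonomy=taxonomy)
print(roles["role"].value_counts().to_dict())
keystones = roles[roles["keystone"]]
print(f"\nkeystone taxa ({len(keystones)}):")
print(keystones[["phylum", "degree", "Zi", "Pi", "role"]].round(3))

planted = set(truth.planted_roles)
print(f"\nplanted hubs rank in the top Zi: "
      f"{roles.loc[sorted(planted & set(roles.index)), 'Zi'].round(2).to_dict()}")
print(keystone.aggregate_by_taxon(roles, taxonomy))
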