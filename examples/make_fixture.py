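"""Regenerate the shipped demo fixture (examples/fixture) from scratch.

The fixture is a synthetic community under the default study conditions
(60 taxa in 3 modules, 30 samples at depth 50,000, planted hubs) plus a
soil/plant covariate table drawn from the demo path model.  Running this
script with the same seed reproduces the shipped files byte for byte.
"""

from pathlib import Path

from rhizonet import synthetic

SEED = 42
HERE = Path(__file__).resolve().parent


def main() -> None:
    config = synthetic.demo_scenario(seed=SEED)
    table, taxonomy, truth_a = synthetic.generate_modular_abundances(config)
    metadata, truth_b = synthetic.generate_soil_plant_table(
        config, config.n_samples
    )
    out = HERE / "fixture"
    synthetic.write_fixture_bundle(
        out, table, taxonomy, metadata, truth_a.merged_with(truth_b),
        overwrite=True,
    )
    print(f"fixture written to {out}")


if __name__ == "__main__":
    main()
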