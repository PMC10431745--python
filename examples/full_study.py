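"""Run a reduced end-to-end study and print the result summary.

Simulates a smaller cohort (12 subjects, 250 permutations) through the
complete pipeline — preprocessing, cross-decoding, masked TFCE
inference, paired facilitation contrasts and the sensor searchlight —
and writes the report bundle (CSV/JSON + figures) to ./study-output.
The default 28-subject study is the same call with the default config.
"""

import json

import megscenes as m

config = m.validate_config(
    {
        "master_seed": 1,
        "simulation": {"n_subjects": 12},
        "inference": {"n_permutations": 250},
    }
)
bundle = m.run_full_analysis(config, output_dir="study-output")
summary = bundle.summary()

print(json.dumps(summary["contrasts"], indent=2, sort_keys=True))
print("searchlight significant channels per 50-ms cluster:",
      summary["searchlight"]["n_significant_channels_per_cluster"])
# Both facilitation contrasts should be significant only around the
# planted 325-ms boost; the searchlight should light up in the 300-350 ms
# cluster, concentrated on left-posterior sensors.
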