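"""Generate one synthetic subject and inspect the study design.

Builds the intact-scene localizer and the degraded-stimulus main
experiment for a single subject, then prints the trial bookkeeping that
defines the design: trials per run, one-back targets, and the number of
unique exemplar-averaged patterns each experiment yields.
"""

import megscenes as m

config = m.SimulationConfig(seed=1)
layout = m.make_sensor_layout(config.n_channels)
data = m.simulate_subject(config, layout, subject_index=0)

for name, (epochs, table) in data.items():
    print(f"\n{name} experiment")
    print(f"  epochs: {epochs.data.shape} (trials x channels x 10-ms bins)")
    per_run = table.groupby("run").size().unique()
    onebacks = table.groupby("run").is_oneback.sum().unique()
    print(f"  trials/run: {per_run[0]} of which {onebacks[0]} one-back targets")
    clean, clean_table = m.drop_onebacks(epochs, table)
    avg, avg_table = m.average_exemplars(m.detrend_demean(clean), clean_table)
    counts = avg_table.groupby("condition").size()
    print(f"  exemplar-averaged patterns: {len(avg_table)}")
    print("  per condition:", dict(counts))

print(f"\nleft-posterior decoding set: {len(layout.left_posterior_ids)} magnetometers")
# The numbers mirror the study design: 198 trials/run (18 one-backs) in the
# main experiment -> 90 averaged patterns (15 per condition x category);
# 132 trials/run (12 one-backs) in the localizer -> 120 patterns.
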