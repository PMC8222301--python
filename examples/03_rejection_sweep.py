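"""Rejection-rate sweep across window lengths for a clustered stream.

Generates a diel stream with self-exciting clustering (each release
stimulates ~0.6 further releases with ~10-s delays, the mutual-
stimulation hypothesis) and tabulates the percentage of analyzed windows
the S-CON test flags as non-random, per window length and connectivity
interval.
"""

from scon import ClusterParams, DielIntensityParams, SconConfig, gen_clustered, sweep

days = 6
events = gen_clustered(
    DielIntensityParams(),
    ClusterParams(branching_ratio=0.6, kernel_decay_s=10.0),
    seed=11, days=days,
)
print(f"{events.size} events over {days} days")

table = sweep(events, [60, 300, 1800, 3600, 21600], [25, 30, 35],
              (0, days * 86_400), SconConfig(), master_seed=5)
print(table.to_string(index=False,
                      formatters={"pct_rejected": "{:.1f}".format}))
# pct_rejected climbs with window length: 1-min windows are too short for
# the statistic to separate clustering from chance, while multi-hour
# windows almost always reject; shifting the connectivity interval
# between 25 and 35 s moves the numbers by only a few points.
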