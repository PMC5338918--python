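"""Pulsatile apicomedial myosin: detect pulses, pool intervals.

Generates asynchronous per-cell intensity traces with normally
distributed inter-pulse intervals (mean 131.7 s, SD 42.8 s) sampled every
5 s, detects peaks, and recovers the interval statistics.
"""

from placodekit import (PulsationConfig, detect_peaks, generate_pulse_traces,
                        interval_statistics)

pcfg = PulsationConfig()  # 131.7 +/- 42.8 s, 5 s frames, 30 min traces
traces = generate_pulse_traces(pcfg, n_cells=14, seed=8)
for tr in traces:
    detect_peaks(tr)

st = interval_statistics(traces)
print(f"{st['n_cells']} cells, {st['n_intervals']} pooled intervals")
print(f"inter-pulse interval: {st['mean']:.1f} ± {st['sd']:.1f} s "
      f"(mean ± s.d.)")
print(f"per-cell means range: {st['per_cell_means'].min():.0f}"
      f"-{st['per_cell_means'].max():.0f} s")
# The pooled mean matches the generating 131.7 s rhythm to within a
# frame interval; pulses are asynchronous across cells.
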