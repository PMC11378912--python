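"""Slow-wave detection and slow-wave -> spindle temporal coupling.

Generates a recording in which high-radius bursts are preferentially
triggered 100 ms after slow-wave peaks, detects both event types, and
quantifies coupling in the 125-ms forward window; shifting the slow-wave
timestamps by 700 ms shows the chance level.
"""

from spindleq import (SimulationConfig, couple, detect_slow_waves,
                      detect_spindles, gen_recording, shift_control,
                      sw_filter)

cfg = SimulationConfig(duration=400.0, seed=21,
                       sw_coupling_prob=(0.1, 0.3, 0.6, 0.9))
rec, hyp, gt = gen_recording(cfg)

filtered = sw_filter(rec.channel("LFP4"), rec.fs)
sws = detect_slow_waves(filtered, rec.fs, selection="above_median")
spindles = detect_spindles(rec.channel("LFP4"), rec.fs, hypnogram=hyp,
                           channel="LFP4")

res = couple(sws, spindles, window=0.125, oq_split=True)
ctl = shift_control(sws, spindles, offset=0.7, window=0.125)

print(f"slow waves (above-median): {len(sws)}; spindle events: {len(spindles)}")
print(f"slow waves followed by a spindle within 125 ms: "
      f"{res.pct_sw_followed_by_spindle:.1f}%")
print(f"spindles preceded by a slow wave: "
      f"{res.pct_spindles_preceded_by_sw:.1f}%")
print(f"per-oQ spindle coupling: "
      f"{ {q: round(v, 1) for q, v in res.per_oq.items()} }")
print(f"after shifting slow waves by 700 ms: "
      f"{ctl.pct_sw_followed_by_spindle:.1f}% (chance)")
print()
print("Coupling above the shifted control (rising with oQ, as scheduled by")
print("the generator) indicates genuine temporal nesting of spindles in the")
print("slow-oscillation cycle; detection latency relative to the true burst")
print("onset dilutes the absolute percentages in the strict 125-ms window.")
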