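"""Follow caspase-3 activation in single cells with a FRET biosensor.

Simulates a paired CFP/YFP time-lapse movie of cells whose YFP/CFP
ratio drops when caspase 3 cleaves the biosensor, then runs the full
imaging pipeline: Otsu segmentation, nearest-centroid tracking,
per-cell ratio traces, activation calling (sustained 30% ratio drop)
and the cumulative activation curve.
"""

from resistkit import fret
from resistkit.simulate import FretSimConfig, simulate_fret_movie

cfg = FretSimConfig(
    n_cells=12, n_timepoints=25, frame_interval=2.0,  # a 48 h observation
    ratio_drop=0.5, intensity_noise_sd=2.0, seed=11,
)
pair, trace_table, truth = simulate_fret_movie(cfg)
print(f"movie: {cfg.n_cells} cells, {cfg.n_timepoints} frames, "
      f"{cfg.frame_interval} h apart, stacks {pair.yfp_stack.shape}")

labels = fret.segment_cells(pair.yfp_stack[0])
print(f"segmentation finds {labels.max()} cells in frame 0 "
      f"({cfg.n_cells} planted)")

traces = fret.extract_traces(pair)
for tr in traces:
    fret.classify_apoptosis(tr, drop_fraction=0.3)

n_act = sum(tr.activated for tr in traces)
true_n = sum(t is not None for t in truth.true_activation.values())
print(f"\nactivation calls: {n_act} activated ({true_n} planted)")
est = sorted(tr.activation_time for tr in traces if tr.activated)
tru = sorted(t for t in truth.true_activation.values() if t is not None)
for e, t in zip(est, tru):
    print(f"  called at {e:5.1f} h (planted {t:5.1f} h)")

curve = fret.activation_curve(traces)
print("\ncumulative fraction of cells with active caspase 3:")
print(curve.iloc[::4].to_string(index=False))
print("\nThe curve is the population's apoptosis time course; calls land at "
      "the first frame at or after each planted switch.")
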