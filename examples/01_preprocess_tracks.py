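"""Preprocess a raw 3-D motion track into a model-ready acceleration profile.

Builds a synthetic 110 Hz transport movement (lift over an obstacle, carry,
set down), derives the acceleration profile from finite differences of the
speed, maps it to percentual time with a 5%-of-peak threshold rule, and
rescales a small dataset to unit value span.
"""

import numpy as np

import movewarp as mw

# a 1.4 s movement sampled at 110 Hz: quiet - transport with lift - quiet
t = np.arange(0, 1.4, 1 / 110.0)
progress = np.clip((t - 0.2) / 1.0, 0, 1)  # movement between 0.2 s and 1.2 s
s = 3 * progress**2 - 2 * progress**3  # smooth start and stop
track = mw.RawTrack(
    sample_rate_hz=110.0,
    positions=np.column_stack([40 * s, 2 * np.sin(np.pi * s), 12 * np.sin(np.pi * s)]),
    timestamps=t,
)

acc = mw.compute_acceleration(track)
print(f"acceleration profile: {len(acc.values)} points "
      f"(raw track had {len(t)}; central differencing drops the endpoints)")
print(f"peak |acceleration|: {np.abs(acc.values).max():.1f} cm/s^2")

pct = mw.to_percentual_time(acc, mw.OnsetRule(kind="fraction_of_peak", fraction=0.05))
print(f"percentual time: kept {len(pct.values)} points, "
      f"time span now [{pct.times.min():.2f}, {pct.times.max():.2f}]"
      " (0 = movement onset, 1 = offset)")

scaled, record = mw.rescale_dataset([pct])
span = np.ptp(scaled[0].values[~scaled[0].missing_mask])
print(f"after rescaling: global value span = {span:.3f} (unit span shared by "
      f"all conditions); scale record stores offset {record.value_min:.1f} and "
      f"span {record.value_span:.1f} for exact inversion")
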