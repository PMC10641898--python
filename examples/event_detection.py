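"""Detect calcium events in simulated dF/F traces and compare against the
generator's ground truth."""

import numpy as np

from caimnet import (
    SimConfig,
    annotate_metrics,
    detect_events,
    event_rate,
    segment_bouts,
    simulate_speed,
    simulate_traces,
)
from caimnet.behavior import BoutSegmentation

cfg = SimConfig(n_cells=5, seed=3)
speed, bouts = simulate_speed(cfg)
seg = segment_bouts(speed)
traces, truth = simulate_traces(cfg, bouts)

for tr, onsets in zip(traces, truth.true_event_onsets):
    events = annotate_metrics(detect_events(tr.values), tr.values)
    det = np.array([e.t_on for e in events])
    matched = sum(1 for o in onsets if det.size and np.abs(det - o).min() <= 2)
    rates = (event_rate(events, seg, "rest"), event_rate(events, seg, "run"))
    fwhm = [e.fwhm_s for e in events if e.fwhm_s is not None]
    print(f"cell {tr.cell_id}: {len(onsets)} planted / {len(events)} detected "
          f"({matched} within 100 ms), rest {rates[0]:.2f} / run {rates[1]:.2f} "
          f"events/min, median FWHM {np.median(fwhm):.2f} s")
# rates near the configured 1.71 (rest) and, for modulated cells, 2.79 (run)
# events/min show the detector recovering the planted activity structure
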