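"""Classify correlated vs random neuron pairs per behavioral state and
show that shared-source pairs stand out from chance."""

import numpy as np

from caimnet import (
    SimConfig,
    binarize,
    classify_session,
    detect_events,
    segment_bouts,
    simulate_speed,
    simulate_traces,
)

cfg = SimConfig(n_cells=16, shared_fraction=0.7, correlated_pair_fraction=0.5,
                source_rate=3.0, seed=9)
speed, bouts = simulate_speed(cfg)
seg = segment_bouts(speed)
traces, truth = simulate_traces(cfg, bouts)

trains = [binarize(speed.n_samples, detect_events(tr.values), cell_id=tr.cell_id)
          for tr in traces]
cents = np.array([tr.centroid for tr in traces])
planted = {(i, j) for i, j, _ in truth.true_correlated_pairs}

for scope in ("rest", "run", "session"):
    pairs, frac = classify_session(trains, cents, seg, scope=scope,
                                   rng=np.random.default_rng(21))
    hits = sum(1 for p in pairs if (p.i, p.j) in planted and p.klass == "correlated")
    print(f"{scope:8s}: correlated fraction {100 * frac:.1f}% "
          f"({hits}/{len(planted)} planted pairs recovered)")
# pairs are correlated when their binarized-train Pearson r beats the 95th
# percentile of 2,000 circular shifts; ~5% of independent pairs pass by chance
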