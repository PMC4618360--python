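"""End-to-end channel recovery on the synthetic motor-imagery benchmark.

Generates the 20-channel benchmark (4 planted mu-band ERD channels: 6 and 8
desynchronize for class 0, 16 and 18 for class 1), runs the full pipeline —
surface Laplacian, 13-band envelope features, min-max normalization, a
full-set Relieff pass with deterministic targets — and sums feature weights
per channel. The top 4 channels by weight should be exactly the planted
ones, and the cross-validated accuracy-vs-channels curve should already be
at its peak once all planted channels are included.
"""

import numpy as np

from micsel import (
    ReliefConfig,
    SVMConfig,
    accuracy_vs_channels,
    channel_weight_map,
    design_constant_q_bank,
    extract_features,
    grid_montage,
    laplacian_filter,
    minmax_normalize,
    relieff_weights,
)
from micsel.synthetic import default_benchmark

ts, gt = default_benchmark(seed=1)
print(f"benchmark: {ts.n_trials} trials x {ts.n_channels} channels "
      f"@ {ts.rate:g} Hz; planted channels {gt.all_channels.tolist()}")

ts = laplacian_filter(ts, grid_montage(4, 5))
fm = extract_features(ts, design_constant_q_bank())
fmn = minmax_normalize(fm)
w = relieff_weights(fmn, ReliefConfig(k=10), targets=np.arange(fm.n_trials))
cw = channel_weight_map(w, fm.map)

top4 = np.sort(np.argsort(cw)[-4:])
print(f"top 4 channels by weight: {top4.tolist()} "
      f"(recovered={np.array_equal(top4, gt.all_channels)})")

curve = accuracy_vs_channels(fm, cw, SVMConfig(), n_folds=10, seed=0)
print("\nchannels used -> mean CV accuracy:")
for c, acc in zip(curve.n_channels_used[:8], curve.mean_accuracy[:8]):
    print(f"  {c:2d}: {acc:.3f}")
n_peak, acc_peak = curve.peak()
print(f"peak: {acc_peak:.3f} reached with {n_peak} channel(s); "
      "accuracy saturates once the informative channels are in")
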