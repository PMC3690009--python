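"""Simulate a single-resident smart home and inspect the dataset shape.

Generates two weeks of binary sensor data at 60-second slices from the
packaged default home (8 activities including idle, 12 sensors), then
prints the slice count and the per-activity time budget.  The marginals
show the characteristic class imbalance of real deployments: sleeping and
leisure dominate, while toileting or showering occupy well under 1% of
slices each.
"""

import numpy as np

from hybridhmm import sample_home, small_home

sim = sample_home(small_home(n_days=14, dt=60), seed=7)
obs, labels = sim.truth

print(f"{obs.n_slices} time slices x {obs.n_sensors} sensors "
      f"({sim.config.n_days} days at dt={obs.dt:.0f}s)")
print(f"{len(sim.events)} sensor events, "
      f"{len(sim.activities)} annotated activity intervals\n")

print(f"{'activity':<12s} {'slices':>7s} {'share':>7s}")
counts = np.bincount(labels.indices, minlength=labels.n_classes)
for name, count in zip(labels.class_names, counts):
    print(f"{name:<12s} {count:>7d} {count / len(labels):>6.1%}")
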