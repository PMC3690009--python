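"""Leave-one-day-out comparison of five recognizers with significance tests.

On a simulated home, compares the generative Bernoulli HMM, the two hybrid
recognizers (HMM with MLP / SVM emitters) and the two static classifiers
under the leave-one-day-out protocol, then tests the hybrid-vs-static fold
scores with a paired t-test and a Wilcoxon signed-ranks test.  A p-value
below 0.05 means the fold-wise F-measure differences are unlikely under
the no-difference hypothesis.
"""

import warnings

import numpy as np

from hybridhmm import (
    leave_one_day_out,
    paired_tests,
    raw,
    sample_home,
    small_home,
    split_days,
    summarize_folds,
)
from hybridhmm.experiments import default_model_suite

warnings.simplefilter("ignore")

sim = sample_home(small_home(n_days=6, dt=120), seed=5)
days = [(raw(o), l) for o, l in split_days(*sim.truth)]

folds = {}
for name, trainer in default_model_suite(seed=0).items():
    folds[name] = leave_one_day_out(days, trainer)
    s = summarize_folds(folds[name])
    print(f"{name:<12s} F = {s['fmeasure_mean']:.3f} "
          f"± {s['fmeasure_sd']:.3f}  ({int(s['n_folds'])} folds)")

print()
for hybrid, static in (("hybrid_mlp", "static_mlp"),
                       ("hybrid_svm", "static_svm")):
    a = [r.fmeasure for r in folds[hybrid]]
    b = [r.fmeasure for r in folds[static]]
    res = paired_tests(a, b)
    print(f"{hybrid} vs {static}: mean gain {np.mean(a) - np.mean(b):+.3f}, "
          f"t p={res.t_pvalue:.3g}, Wilcoxon p={res.wilcoxon_pvalue:.3g}")
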