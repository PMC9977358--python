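"""Control analyses: contamination, nuisance decoding, counterbalancing.

Three safeguards against spurious decoding: (1) spiking half of the absent
trials with the estimated rate of mislabeled conscious trials must stay at
chance; (2) a nuisance factor carrying no signal must not decode; (3) a
contrast whose accuracy is driven by a skewed nuisance distribution must
fall to chance once the factor is counterbalanced.

Run:  python examples/06_control_analyses.py
"""

import numpy as np

from cfswm import mvpa

rng = np.random.default_rng(0)

# 1. clean vs contaminated absent bins at the 6.3% erroneous-rating estimate
absent = rng.normal(size=(42, 50))
conscious = rng.normal(loc=1.0, size=(60, 50))
res = mvpa.contamination_control(
    absent, np.arange(42) * 80.0, conscious, np.arange(60) * 80.0 + 40.0,
    contamination_rate=0.063, n_folds=4, n_iter=50, seed=0,
)
print(f"clean vs contaminated (6.3%): {100 * res.accuracy:.1f}% (chance = 50%)")

# 2. decoding the response finger (a factor with no planted signal)
n = 80
X = rng.normal(size=(n, 50))
finger = np.array(["index", "long"] * (n // 2))
folds = mvpa.build_folds(np.arange(n) * 40.0, n_folds=5, seed=0, labels=finger)
res = mvpa.relabel_control(X, finger, finger, folds, n_iter=10, seed=0,
                           mode="decode_factor")
print(f"response-finger decode:      {100 * res.accuracy:.1f}% (chance = 50%)")

# 3. probe-status decode confounded by probe side, then counterbalanced
n = 160
status = np.array(["target-match"] * 80 + ["distractor-match"] * 80)
side = np.concatenate([
    np.array(["left"] * 60 + ["right"] * 20),
    np.array(["left"] * 20 + ["right"] * 60),
])
X = rng.normal(size=(n, 50))
X[side == "left", :15] += 1.0  # signal follows the probe's side only
perm = rng.permutation(n)
X, status, side = X[perm], status[perm], side[perm]
folds = mvpa.build_folds(np.arange(n) * 40.0, n_folds=4, seed=0)
naive = mvpa.decode_roi_balanced(X, status, folds, n_iter=10, seed=0)
balanced = mvpa.relabel_control(X, status, side, folds, n_iter=50, seed=0)
print(f"probe status, naive:         {100 * naive.accuracy:.1f}%")
print(f"probe status, side-balanced: {100 * balanced.accuracy:.1f}%")
# The naive decode succeeds only through the side confound; after exact
# counterbalancing of the label x side cross-tab it returns to chance.
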