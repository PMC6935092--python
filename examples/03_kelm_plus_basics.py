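"""KELM and KELM+ on toy data: closed-form training and the LUPI contract.

KELM+ uses a privileged feature set during training only; at test time the
model owns nothing but the main-feature training samples and its output
weights.

Run:  python examples/03_kelm_plus_basics.py
"""

import numpy as np

from kelmplus import (KernelSpec, encode_labels, predict_kelm, predict_kelm_plus,
                      train_kelm, train_kelm_plus)
from kelmplus.synthetic import generate_separable

# Two well-separated Gaussian classes; half for training, half held out
X, y = generate_separable(n_per_class=30, dim=6, separation=6.0, seed=0)
half = len(y) // 2
X_tr, y_tr, X_te, y_te = X[:half], y[:half], X[half:], y[half:]
T = encode_labels(y_tr, [0, 1])
spec = KernelSpec("rbf", 0.2)

kelm = train_kelm(X_tr, T, C=10.0, spec=spec, classes=[0, 1])
_, pred = predict_kelm(kelm, X_te)
print(f"KELM held-out accuracy:  {np.mean(pred == y_te):.2%}")

# Privileged information: a noisy copy of the class label, seen only in training
rng = np.random.default_rng(1)
P_tr = (2.0 * y_tr[:, None] - 1.0) + 0.3 * rng.standard_normal((half, 1))
plus = train_kelm_plus(X_tr, P_tr, T, C=10.0, eps=1.0, spec_main=spec,
                       spec_priv=KernelSpec("rbf", 1.0), classes=[0, 1],
                       include_main_gram=True)
_, pred_plus = predict_kelm_plus(plus, X_te)  # no privileged input here
print(f"KELM+ held-out accuracy: {np.mean(pred_plus == y_te):.2%}")

del P_tr  # the model keeps no reference to the privileged samples
_, again = predict_kelm_plus(plus, X_te)
print(f"predictions unchanged after deleting the privileged data: "
      f"{bool(np.all(again == pred_plus))}")
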