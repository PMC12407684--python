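"""Output-legality interpreter for decoded quaddle labels.

The classifier heads emit one probability vector per feature dimension.
Taking the per-dimension argmax can yield an object that cannot occur in
the task: legal quaddles have between 1 and 3 non-neutral dimensions
(the neutral value is index 0).  The interpreter repairs illegal
predictions using the *neutral confidence* of each dimension — the
neutral probability minus the best non-neutral probability:

* all dimensions neutral: the dimension with the lowest neutral
  confidence is flipped to its best non-neutral value;
* too many non-neutral dimensions: the non-neutral dimension with the
  highest neutral confidence is flipped to neutral;

repeating until the label is legal.  Each flip moves the non-neutral
count toward the legal band, so the procedure terminates.
"""

from __future__ import annotations

import numpy as np

MAX_NON_NEUTRAL = 3
_SIMPLEX_ATOL = 1e-6


def is_legal(label, max_non_neutral: int = MAX_NON_NEUTRAL) -> bool:
    """A label is legal iff its non-neutral count is in {1, ..., 3}."""
    k = int(np.count_nonzero(np.asarray(label)))
    return 1 <= k <= max_non_neutral


def _check_simplex(probs: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for p in probs:
        p = np.asarray(p, dtype=float)
        if p.ndim != 1 or p.size < 2 or np.any(p < -_SIMPLEX_ATOL) or abs(p.sum() - 1.0) > 1e-4:
            raise ValueError("each dimension needs a probability vector summing to 1")
        out.append(p)
    return out


def neutral_confidence(probs: list[np.ndarray]) -> np.ndarray:
    """Per dimension: neutral probability minus the best non-neutral one."""
    return np.array([p[0] - p[1:].max() for p in _check_simplex(probs)])


def argmax_decode(probs: list[np.ndarray]) -> np.ndarray:
    """Per-dimension argmax (possibly illegal); ties break toward the lower
    index, so neutral wins a neutral/non-neutral tie."""
    return np.array([int(np.argmax(p)) for p in _check_simplex(probs)])


def repair(label: np.ndarray, probs: list[np.ndarray]) -> np.ndarray:
    """Minimal legality repair of an argmax-decoded label."""
    label = np.asarray(label).copy()
    probs = _check_simplex(probs)
    conf = neutral_confidence(probs)
    while int(np.count_nonzero(label)) < 1:
        d = int(np.argmin(np.where(label == 0, conf, np.inf)))
        label[d] = 1 + int(np.argmax(probs[d][1:]))
    while int(np.count_nonzero(label)) > MAX_NON_NEUTRAL:
        d = int(np.argmax(np.where(label != 0, conf, -np.inf)))
        label[d] = 0
    return label


def decode(probs: list[np.ndarray]) -> np.ndarray:
    """Argmax decode followed by legality repair."""
    return repair(argmax_decode(probs), probs)


def decode_batch(probs: list[np.ndarray]) -> np.ndarray:
    """Vectorized decode-and-repair over trials and windows.

    ``probs[j]`` has shape (..., N_j); returns labels of shape (..., M).
    The leading axes of all dimensions must agree.
    """
    lead = probs[0].shape[:-1]
    m = len(probs)
    flat = [p.reshape(-1, p.shape[-1]) for p in probs]
    n = flat[0].shape[0]
    labels = np.stack([f.argmax(axis=1) for f in flat], axis=1)
    counts = np.count_nonzero(labels, axis=1)
    for i in np.flatnonzero((counts < 1) | (counts > MAX_NON_NEUTRAL)):
        labels[i] = repair(labels[i], [f[i] for f in flat])
    return labels.reshape(*lead, m)
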