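"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's code paths: the NCDF is evaluated with
scipy's high-precision ``ndtr``, rounding is applied literally, and patterns
are counted with an explicit census into a Counter.
"""

from collections import Counter

import numpy as np
from scipy.special import ndtr


def census_labels(x, c):
    x = np.asarray(x, dtype=float)
    theta = ndtr((x - x.mean()) / x.std())
    # round half away from zero of c*theta + 0.5, clamped to [1, c]
    z = np.floor(c * theta + 0.5 + 0.5).astype(int)
    return np.clip(z, 1, c)


def census_entropy(x, c=3, m=2, tau=1):
    """Shannon entropy of the explicit dispersion-pattern census (nats)."""
    z = census_labels(x, c)
    n = len(z) - (m - 1) * tau
    patterns = [tuple(z[i + k * tau] for k in range(m)) for i in range(n)]
    counts = Counter(patterns)
    return -sum((v / n) * np.log(v / n) for v in counts.values())


def equiprobable_signal(c=3, m=2, repeats=4):
    """A raw signal whose label sequence visits every (c, m) pattern equally
    often: a cyclic de Bruijn label sequence realised through equally spaced
    values (c=3, m=2 only)."""
    assert c == 3 and m == 2
    debruijn = np.array([1, 1, 2, 1, 3, 2, 2, 3, 3])
    labels = np.concatenate([np.tile(debruijn, repeats), debruijn[:1]])
    return np.array([-1.0, 0.0, 1.0])[labels - 1]
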