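"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they validate: the enclosed-area
oracle is a Monte-Carlo point-in-region estimator, and the paired-t oracle
is the textbook closed form evaluated directly.
"""

from __future__ import annotations

import math

import numpy as np


def mc_enclosed_area(
    width_cm: float,
    area_AG: float,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo area of {(u, v): u^2+v^2 <= r^2, |v| <= W/2} with
    r = sqrt(A_G/pi); returns (estimate, standard_error)."""
    r = math.sqrt(area_AG / math.pi)
    u = rng.uniform(-r, r, n_samples)
    v = rng.uniform(-r, r, n_samples)
    hit = (u * u + v * v <= r * r) & (np.abs(v) <= width_cm / 2.0)
    p = hit.mean()
    box = (2.0 * r) ** 2
    se = math.sqrt(p * (1.0 - p) / n_samples) * box
    return p * box, se


def paired_t_closed_form(a, b) -> tuple[float, float]:
    """Paired t statistic and df from the definition: t = dbar / (s_d / sqrt(n))."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    s = d.std(ddof=1)
    return float(d.mean() / (s / math.sqrt(n))), n - 1
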