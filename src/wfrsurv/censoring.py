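"""Progressive type-II censoring: removal schemes and sample generation.

In a progressive type-II life test, ``n`` units start on test and at the
``i``-th observed failure ``R_i`` of the surviving units are withdrawn at
random; the test stops at the ``m``-th failure, where the remaining
``R_m = n - m - sum(R_1..R_{m-1})`` survivors are removed.  The scheme
``R = (R_1, ..., R_m)`` together with the ordered failure times
``y_1 < ... < y_m`` fully describes the experiment.

Simulated samples are produced with the Balakrishnan-Sandhu uniform
transformation, which maps m independent uniforms directly to the joint law
of the progressively censored order statistics without simulating the full
cohort; ``apply_progressive_censoring`` implements the physical withdrawal
mechanism itself and serves both for censoring real data and as an
independent cross-check on the transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .distribution import WFrParams, quantile

__all__ = [
    "ProgressiveScheme",
    "CensoredSample",
    "make_scheme",
    "binomial_removal_scheme",
    "generate_progressive_uniforms",
    "generate_progressive_sample",
    "apply_progressive_censoring",
]


@dataclass(frozen=True)
class ProgressiveScheme:
    """Removal plan (n, m, R_1..R_m) of a progressive type-II design."""

    n: int
    m: int
    removals: tuple

    def __post_init__(self) -> None:
        n, m = int(self.n), int(self.m)
        rem = tuple(int(r) for r in self.removals)
        if not (1 <= m <= n):
            raise ValueError(f"need 1 <= m <= n, got n={n}, m={m}")
        if len(rem) != m:
            raise ValueError(f"removals must have length m={m}, got {len(rem)}")
        if any(r < 0 for r in rem):
            raise ValueError("removals must be nonnegative")
        if sum(rem) != n - m:
            raise ValueError(
                f"removals sum to {sum(rem)}, expected n - m = {n - m}"
            )
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "removals", rem)

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "m": self.m, "removals": list(self.removals)})

    @classmethod
    def from_json(cls, text: str) -> "ProgressiveScheme":
        d = json.loads(text)
        return cls(d["n"], d["m"], tuple(d["removals"]))


@dataclass(frozen=True)
class CensoredSample:
    """Ordered observed failure times bound to their removal scheme."""

    times: tuple
    scheme: ProgressiveScheme

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.times)
        if len(t) != self.scheme.m:
            raise ValueError(
                f"expected {self.scheme.m} observed times, got {len(t)}"
            )
        arr = np.asarray(t)
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValueError("observed times must be positive and finite")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("observed times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def removals(self) -> np.ndarray:
        return np.asarray(self.scheme.removals, dtype=float)


def make_scheme(kind: str, n: int, m: int) -> ProgressiveScheme:
    """Conventional one-point removal schemes CS-I / CS-II / CS-III.

    CS-I places all n - m removals at the first failure, CS-III at the last,
    and CS-II at the middle failure: position (m+1)/2 for odd m, m/2 for
    even m (1-based).
    """
    key = kind.strip().upper().replace("_", "-").replace(" ", "-")
    aliases = {
        "CS-I": 1, "CS1": 1, "CSI": 1, "I": 1,
        "CS-II": 2, "CS2": 2, "CSII": 2, "II": 2,
        "CS-III": 3, "CS3": 3, "CSIII": 3, "III": 3,
    }
    if key not in aliases:
        raise ValueError(f"unknown censoring scheme kind {kind!r}")
    which = aliases[key]
    removals = [0] * m
    if which == 1:
        pos = 1
    elif which == 3:
        pos = m
    else:
        pos = (m + 1) // 2 if m % 2 == 1 else m // 2
    removals[pos - 1] = n - m
    return ProgressiveScheme(n, m, tuple(removals))


def binomial_removal_scheme(
    n: int, m: int, p: float, rng: np.random.Generator
) -> ProgressiveScheme:
    """Random removal scheme with sequential binomial withdrawals.

    R_1 ~ Binomial(n - m, p) and thereafter R_i ~ Binomial(n - m -
    sum(R_1..R_{i-1}), p); the final entry R_m absorbs whatever removal
    budget is left, so the scheme always accounts for all n units.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("removal probability p must lie in [0, 1]")
    if not (1 <= m <= n):
        raise ValueError(f"need 1 <= m <= n, got n={n}, m={m}")
    left = n - m
    removals = []
    for _ in range(m - 1):
        r = int(rng.binomial(left, p)) if left > 0 else 0
        removals.append(r)
        left -= r
    removals.append(left)
    return ProgressiveScheme(n, m, tuple(removals))


def generate_progressive_uniforms(
    scheme: ProgressiveScheme, rng: np.random.Generator
) -> np.ndarray:
    """Balakrishnan-Sandhu uniforms U_{1:m:n} < ... < U_{m:m:n}.

    Draw W_i ~ U(0,1); set V_i = W_i ** (1 / (i + R_m + ... + R_{m-i+1}))
    and U_i = 1 - V_m V_{m-1} ... V_{m-i+1}.  The U_i are distributed as a
    progressively censored sample from the standard uniform law.
    """
    m = scheme.m
    rem = np.asarray(scheme.removals, dtype=float)
    w = rng.random(m)
    w = np.clip(w, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    # exponent of V_i: i plus the removals at the i highest failure ranks
    gamma = np.arange(1, m + 1) + np.cumsum(rem[::-1])
    v = w ** (1.0 / gamma)
    # U_i = 1 - V_m V_{m-1} ... V_{m-i+1}: product over the last i entries
    u = 1.0 - np.cumprod(v[::-1])
    return u


def generate_progressive_sample(
    params: WFrParams, scheme: ProgressiveScheme, rng: np.random.Generator
) -> CensoredSample:
    """Simulate a progressive type-II censored WFr sample.

    Applies the WFr quantile function to Balakrishnan-Sandhu uniforms; the
    output times are strictly increasing with probability one.
    """
    u = generate_progressive_uniforms(scheme, rng)
    u = np.clip(u, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    y = np.asarray(quantile(u, params), dtype=float)
    return CensoredSample(tuple(y), scheme)


def apply_progressive_censoring(
    full_data, scheme: ProgressiveScheme, rng: np.random.Generator
) -> CensoredSample:
    """Apply the physical withdrawal mechanism to a complete data vector.

    Repeatedly observes the smallest remaining value, then removes R_i of
    the survivors uniformly at random without replacement.  Ties are broken
    by stable input order, so replicated values behave deterministically.
    """
    data = np.asarray(full_data, dtype=float)
    if data.ndim != 1 or data.size != scheme.n:
        raise ValueError(
            f"full_data must be a vector of length n={scheme.n}, got {data.size}"
        )
    if np.any(data <= 0) or not np.all(np.isfinite(data)):
        raise ValueError("full_data must contain positive finite values")
    order = np.argsort(data, kind="stable")
    alive = list(order)  # indices sorted by value, stable in input position
    observed = []
    for r in scheme.removals:
        observed.append(data[alive.pop(0)])
        if r > 0:
            drop = rng.choice(len(alive), size=int(r), replace=False)
            for j in sorted(drop, reverse=True):
                alive.pop(int(j))
    times = np.sort(np.asarray(observed))
    if np.any(np.diff(times) <= 0):
        # real data may contain exact ties; perturb is wrong, so reject
        raise ValueError("censored subsample contains tied values")
    return CensoredSample(tuple(times), scheme)
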