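"""Closed-form model of aggregated AP-MS testing under biased bait usage.

The model: an unknown ground-truth interactome G is an ER graph on ``n``
proteins with edge probability ``p``.  Each protein ``u`` is selected ``b(u)``
times as bait, and each time it is selected, every pair {u, v} is tested once
with per-test false-positive rate FPR and false-negative rate FNR.  An edge
enters the observed network as soon as it tests positive at least once, so an
unordered pair {u, v}, tested ``b(u) + b(v)`` times in total, is observed with
probability

    p_uv = p * (1 - FNR^(b(u)+b(v))) + (1 - p) * (1 - (1-FPR)^(b(u)+b(v))).

For small FPR and p (both of order 1/n) the expected observed degree of ``v``
is sandwiched between ``(1-p)*FPR*(n-1)*b(v)`` and the same plus the additive
constant ``A = p*n + (1-p)*FPR*B`` (B the total bait usage) — i.e. expected
degrees track the bait-usage distribution up to a uniform offset.  If bait
usage is power-law distributed, observed degrees are too, even over an empty
ground truth.

The default bait-usage surrogate mirrors the empirical one from large PPI
databases: zero with probability 0.24 (never-baited proteins), otherwise a
discrete power law with exponent 3.13 and cutoff 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.special import zeta as _hurwitz_zeta

from .powerlaw import _DiscretePLSampler

__all__ = [
    "ModelParams",
    "BaitUsage",
    "edge_prob",
    "directed_edge_prob",
    "expected_degree_bounds",
    "powerlaw_bait_usage",
    "expected_bait_usage",
    "sample_observed_degrees",
    "expected_mean_degree",
]

#: empirical fraction of proteins never used as bait
DEFAULT_ZERO_FRAC = 0.24
#: fitted power-law exponent of the bait-usage distribution
DEFAULT_BIAS_ALPHA = 3.13


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the aggregated testing model."""

    n: int
    p: float
    fnr: float
    fpr: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be at least 2")
        for name in ("p", "fnr", "fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class BaitUsage:
    """Times each protein was selected as bait."""

    counts: Mapping[Hashable, int]
    total: int = field(init=False)

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("bait-usage counts must be non-negative")
        self.total = int(sum(self.counts.values()))

    def __getitem__(self, u) -> int:
        return int(self.counts.get(u, 0))

    def as_array(self, nodes: Sequence[Hashable]) -> np.ndarray:
        return np.array([self.counts.get(u, 0) for u in nodes], dtype=np.int64)

    @classmethod
    def from_array(cls, b: np.ndarray) -> "BaitUsage":
        return cls({int(i): int(v) for i, v in enumerate(b)})


def edge_prob(params: ModelParams, bu: int, bv: int) -> float:
    """Probability that the unordered pair {u, v} appears in the observed network.

    Uses the convention 0**0 = 1, so a never-tested pair (bu = bv = 0) is
    observed with probability 0.
    """
    e = np.asarray(bu, dtype=np.float64) + np.asarray(bv, dtype=np.float64)
    out = params.p * (1.0 - params.fnr**e) + (1.0 - params.p) * (
        1.0 - (1.0 - params.fpr) ** e
    )
    return out if out.ndim else float(out)


def directed_edge_prob(params: ModelParams, bv: int) -> float:
    """Probability that {u, v} is observed through tests where ``v`` is the bait."""
    e = np.asarray(bv, dtype=np.float64)
    out = params.p * (1.0 - params.fnr**e) + (1.0 - params.p) * (
        1.0 - (1.0 - params.fpr) ** e
    )
    return out if out.ndim else float(out)


def expected_degree_bounds(
    params: ModelParams, usage: BaitUsage, v: Hashable
) -> tuple[float, float]:
    """First-order bounds on E[deg(v)]: [L, L + A] with
    L = (1-p)*FPR*(n-1)*b(v) and A = p*n + (1-p)*FPR*B.

    Meaningful when FPR * (b(u)+b(v)) is small (first-order binomial
    approximation); this is documented, not enforced.
    """
    lower = (1.0 - params.p) * params.fpr * (params.n - 1) * usage[v]
    a_const = params.p * params.n + (1.0 - params.p) * params.fpr * usage.total
    return float(lower), float(lower + a_const)


def additive_constant(params: ModelParams, total_bait_usage: float) -> float:
    """The uniform offset A = p*n + (1-p)*FPR*B in the expected-degree bounds."""
    return float(params.p * params.n + (1.0 - params.p) * params.fpr * total_bait_usage)


def expected_bait_usage(
    zero_frac: float = DEFAULT_ZERO_FRAC, alpha: float = DEFAULT_BIAS_ALPHA
) -> float:
    """Mean of the surrogate bait-usage distribution:
    (1 - zero_frac) * zeta(alpha - 1) / zeta(alpha); ~0.99 at the defaults.
    """
    if alpha <= 2.0:
        raise ValueError("mean diverges for alpha <= 2")
    return float((1.0 - zero_frac) * _hurwitz_zeta(alpha - 1.0, 1) / _hurwitz_zeta(alpha, 1))


def powerlaw_bait_usage(
    n: int,
    seed,
    zero_frac: float = DEFAULT_ZERO_FRAC,
    alpha: float = DEFAULT_BIAS_ALPHA,
) -> BaitUsage:
    """i.i.d. bait usage: 0 with probability ``zero_frac``, else a draw from the
    discrete power law with exponent ``alpha`` and cutoff 1."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = np.zeros(n, dtype=np.int64)
    nonzero = rng.random(n) >= zero_frac
    k = int(nonzero.sum())
    if k:
        b[nonzero] = _DiscretePLSampler(alpha, 1).sample(k, rng)
    return BaitUsage.from_array(b)


def _sample_distinct(rng: np.random.Generator, n_total: int, m: int) -> np.ndarray:
    """m distinct uniform indices from range(n_total), for m << n_total."""
    if m > n_total:
        raise ValueError("cannot draw more distinct indices than available")
    if m * 3 >= n_total:  # dense case: a partial permutation is cheap enough
        return rng.permutation(n_total)[:m]
    out = np.unique(rng.integers(0, n_total, size=int(m * 1.1) + 8))
    while out.size < m:
        extra = rng.integers(0, n_total, size=m)
        out = np.unique(np.concatenate([out, extra]))
    return rng.permutation(out)[:m]


def _decode_triangular(idx: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices into the strict upper triangle of a c x c grid to (row, col)."""
    idx = idx.astype(np.float64)
    b = 2 * c - 1
    r = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    # guard against float rounding at block boundaries
    first = r * (b - r) // 2  # index of pair (r, r+1)
    too_big = first > idx.astype(np.int64)
    r[too_big] -= 1
    first = r * (b - r) // 2
    col = idx.astype(np.int64) - first + r + 1
    return r, col


def sample_observed_degrees(
    n: int,
    fpr: float,
    usage: BaitUsage,
    p: float = 0.0,
    fnr: float = 0.0,
    seed=None,
) -> np.ndarray:
    """One-shot sample of the observed network's degree sequence.

    Each unordered pair {u, v} is included independently with probability
    ``edge_prob``; only the degree sequence is returned.  Proteins are grouped
    by bait-usage value, so for each pair of usage classes the edge probability
    is constant and the number of edges between the classes is a single
    binomial draw, assigned to uniformly chosen member pairs.  Expected cost is
    near-linear in n plus the expected edge count, which keeps n ~ 17,000
    within seconds.
    """
    params = ModelParams(n=n, p=p, fnr=fnr, fpr=fpr)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = usage.as_array(range(n))
    if b.size != n:
        raise ValueError("usage must cover nodes 0..n-1")

    uvals, inv = np.unique(b, return_inverse=True)
    members = [np.nonzero(inv == i)[0] for i in range(uvals.size)]
    deg = np.zeros(n, dtype=np.int64)

    for i in range(uvals.size):
        ci = members[i]
        for j in range(i, uvals.size):
            cj = members[j]
            prob = edge_prob(params, int(uvals[i]), int(uvals[j]))
            if prob <= 0.0:
                continue
            if i == j:
                c = ci.size
                n_pairs = c * (c - 1) // 2
                if n_pairs == 0:
                    continue
                m = int(rng.binomial(n_pairs, prob))
                if m == 0:
                    continue
                idx = _sample_distinct(rng, n_pairs, m)
                r, s = _decode_triangular(idx, c)
                np.add.at(deg, ci[r], 1)
                np.add.at(deg, ci[s], 1)
            else:
                n_pairs = ci.size * cj.size
                m = int(rng.binomial(n_pairs, prob))
                if m == 0:
                    continue
                idx = _sample_distinct(rng, n_pairs, m)
                np.add.at(deg, ci[idx // cj.size], 1)
                np.add.at(deg, cj[idx % cj.size], 1)
    return deg


def expected_mean_degree(params: ModelParams, usage: BaitUsage) -> float:
    """Exact (1/n) * sum_v sum_{u != v} p_uv, via usage-class grouping."""
    b = usage.as_array(range(params.n))
    uvals, counts = np.unique(b, return_counts=True)
    total = 0.0
    for i in range(uvals.size):
        for j in range(i, uvals.size):
            prob = edge_prob(params, int(uvals[i]), int(uvals[j]))
            if i == j:
                n_pairs = counts[i] * (counts[i] - 1) // 2
            else:
                n_pairs = counts[i] * counts[j]
            total += n_pairs * prob
    return float(2.0 * total / params.n)
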