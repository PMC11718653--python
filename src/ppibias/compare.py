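"""Distribution-level comparison of degree distributions.

A reference degree distribution (e.g. of an observed aggregated PPI network)
is compared against two ensembles of simulated networks — one grown from
power-law (BA) ground truths, one from binomial (ER) ground truths — via the
earth mover's distance (first Wasserstein distance on the integer line).
Summary statistics:

* ΔSOD, the signed relative difference of summed distances; negative means
  the reference is closer to the power-law-origin ensemble;
* K-NN origin probabilities, the fraction of BA members among the K ensemble
  networks nearest to the reference;
* the tipping point, the first FPR-grid bracket where ΔSOD changes sign from
  negative to non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import wasserstein_distance

__all__ = [
    "degree_distribution",
    "emd",
    "delta_sod",
    "knn_origin",
    "tipping_point",
    "ComparisonResult",
    "compare_to_ensembles",
]

_NORM_TOL = 1e-8


def degree_distribution(degrees: Sequence[int]) -> dict:
    """Normalized PMF of a degree sequence: {degree: relative frequency}."""
    arr = np.asarray(degrees, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty degree sequence")
    if np.any(arr < 0):
        raise ValueError("degrees must be non-negative")
    vals, counts = np.unique(arr, return_counts=True)
    return {int(v): float(c) / arr.size for v, c in zip(vals, counts)}


def _check_pmf(p: Mapping[int, float], name: str) -> None:
    total = sum(p.values())
    if abs(total - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} is not normalized (sums to {total!r})")


def emd(p: Mapping[int, float], q: Mapping[int, float]) -> float:
    """Earth mover's (1-Wasserstein) distance between two degree PMFs."""
    _check_pmf(p, "p")
    _check_pmf(q, "q")
    return float(
        wasserstein_distance(
            list(p.keys()), list(q.keys()), list(p.values()), list(q.values())
        )
    )


def delta_sod(
    ref: Mapping[int, float],
    ens_ba: Sequence[Mapping[int, float]],
    ens_er: Sequence[Mapping[int, float]],
    normalized: bool = False,
) -> float:
    """Signed relative difference of summed EMDs.

    Default ("printed") form: (sum d_BA - sum d_ER) / sum d_ER.  With
    ``normalized=True``, divides by max(sum d_BA, sum d_ER) instead, which
    guarantees a value in [-1, 1].  Both forms share their sign.
    """
    if not ens_ba or not ens_er:
        raise ValueError("both ensembles must be non-empty")
    s_ba = sum(emd(ref, q) for q in ens_ba)
    s_er = sum(emd(ref, q) for q in ens_er)
    if normalized:
        denom = max(s_ba, s_er)
        if denom == 0.0:
            return 0.0
        return (s_ba - s_er) / denom
    if s_er == 0.0:
        raise ZeroDivisionError(
            "sum of ER distances is zero; use normalized=True for the "
            "range-normalized variant"
        )
    return (s_ba - s_er) / s_er


def _sorted_labels(ref, ens_ba, ens_er):
    entries = [(emd(ref, q), 0, i) for i, q in enumerate(ens_ba)]
    entries += [(emd(ref, q), 1, i) for i, q in enumerate(ens_er)]
    entries.sort()  # distance, then BA before ER, then insertion index
    return [lab for _, lab, _ in entries]


def knn_origin(
    ref: Mapping[int, float],
    ens_ba: Sequence[Mapping[int, float]],
    ens_er: Sequence[Mapping[int, float]],
    k: int,
) -> tuple[float, float]:
    """K-NN origin probabilities (prob_powerlaw, prob_binomial) for the reference."""
    total = len(ens_ba) + len(ens_er)
    if not 1 <= k <= total:
        raise ValueError(f"K must be in [1, {total}]")
    labels = _sorted_labels(ref, ens_ba, ens_er)
    n_ba = labels[:k].count(0)
    return n_ba / k, 1.0 - n_ba / k


def tipping_point(delta_sods: Mapping[float, float]):
    """Bracket the first sign change of ΔSOD from negative to non-negative.

    ``delta_sods`` maps FPR grid values to ΔSOD.  Returns the bracketing
    (fpr_below, fpr_above) pair, or ``None`` when no such sign change occurs
    in the grid range.
    """
    if len(delta_sods) < 2:
        raise ValueError("need at least 2 FPR grid points")
    fprs = sorted(delta_sods)
    for lo, hi in zip(fprs, fprs[1:]):
        if delta_sods[lo] < 0.0 <= delta_sods[hi]:
            return (lo, hi)
    return None


@dataclass
class ComparisonResult:
    """Full comparison of a reference distribution to two simulated ensembles."""

    d_ba: list
    d_er: list
    delta_sod: float
    delta_sod_normalized: float
    knn_prob_pl: dict
    knn_prob_binom: dict


def compare_to_ensembles(
    ref: Mapping[int, float],
    ens_ba: Sequence[Mapping[int, float]],
    ens_er: Sequence[Mapping[int, float]],
) -> ComparisonResult:
    """EMDs, ΔSOD (both variants) and K-NN probabilities for all K."""
    if not ens_ba or not ens_er:
        raise ValueError("both ensembles must be non-empty")
    d_ba = [emd(ref, q) for q in ens_ba]
    d_er = [emd(ref, q) for q in ens_er]
    s_ba, s_er = sum(d_ba), sum(d_er)
    ds = (s_ba - s_er) / s_er if s_er > 0 else float("nan")
    denom = max(s_ba, s_er)
    dsn = (s_ba - s_er) / denom if denom > 0 else 0.0
    labels = _sorted_labels(ref, ens_ba, ens_er)
    cum_ba = np.cumsum([1 - lab for lab in labels])
    ks = np.arange(1, len(labels) + 1)
    prob_pl = {int(k): float(c) / int(k) for k, c in zip(ks, cum_ba)}
    prob_binom = {k: 1.0 - v for k, v in prob_pl.items()}
    return ComparisonResult(
        d_ba=d_ba,
        d_er=d_er,
        delta_sod=ds,
        delta_sod_normalized=dsn,
        knn_prob_pl=prob_pl,
        knn_prob_binom=prob_binom,
    )
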