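"""Naive mutual information between binary choice series and its
surrogate-based significance test.

MI color / MI side quantify, in bits, how much one agent's color / side
choice sequence tells about the other's.  Probabilities in the MI
formula are replaced by relative frequencies (the naive estimator, which
is adequate for binary series).  Significance is assessed against
Whittle surrogates: random sequences that preserve a series' first-order
(Markov) transition counts and initial symbol, so the null keeps each
agent's choice autocorrelation but destroys any cross-agent dependence.

For binary first-order sequences the admissible surrogate set has a
clean combinatorial structure: fixing the start symbol and the
transition counts fixes the number of runs of each symbol, and a
sequence is exactly a pair of compositions (the run lengths of the
zeros and of the ones).  Sampling a uniform surrogate therefore reduces
to sampling two uniform compositions, which is done exactly and without
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MIResult",
    "naive_mi",
    "whittle_surrogates",
    "mi_significance",
]


def _as_binary(x) -> np.ndarray:
    """Map an arbitrary two-symbol sequence to a 0/1 int array."""
    arr = np.asarray(x)
    if arr.size == 0:
        raise ValueError("empty series")
    symbols = np.unique(arr)
    if len(symbols) > 2:
        raise ValueError(f"series must be binary, found symbols {symbols!r}")
    return (arr == symbols[-1]).astype(np.int8)


def naive_mi(x, y) -> float:
    """Naive mutual information (bits) between two binary series.

    Joint and marginal probabilities are relative frequencies; 0*log(0)
    terms contribute zero.  Symmetric in its arguments, invariant under
    relabeling either alphabet, and bounded by min(H(x), H(y)) <= 1 bit.
    """
    bx = _as_binary(x)
    by = _as_binary(y)
    if len(bx) != len(by):
        raise ValueError(f"length mismatch: {len(bx)} vs {len(by)}")
    n = len(bx)
    joint = np.zeros((2, 2))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(px, py)
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))
    return max(mi, 0.0)


def _transition_counts(b: np.ndarray) -> np.ndarray:
    """2x2 first-order transition count matrix of a 0/1 array."""
    c = np.zeros((2, 2), dtype=int)
    if len(b) > 1:
        np.add.at(c, (b[:-1], b[1:]), 1)
    return c


def _random_composition(rng: np.random.Generator, total: int, parts: int) -> np.ndarray:
    """Uniform composition of ``total`` into ``parts`` positive parts."""
    if parts == 0:
        return np.zeros(0, dtype=int)
    if parts == 1:
        return np.array([total], dtype=int)
    cuts = rng.choice(total - 1, size=parts - 1, replace=False) + 1
    cuts.sort()
    bounds = np.concatenate(([0], cuts, [total]))
    return np.diff(bounds)


def _one_surrogate(rng: np.random.Generator, b: np.ndarray) -> np.ndarray:
    n = len(b)
    start = int(b[0])
    trans = _transition_counts(b)
    n0 = int(np.sum(b == 0))
    n1 = n - n0
    # run counts follow from the start symbol and the cross transitions:
    # every 1->0 transition opens a new 0-run (plus the initial run if the
    # series starts with 0), and symmetrically for 1-runs.
    r0 = trans[1, 0] + (1 if start == 0 else 0)
    r1 = trans[0, 1] + (1 if start == 1 else 0)
    runs0 = _random_composition(rng, n0, r0)
    runs1 = _random_composition(rng, n1, r1)
    out = np.empty(n, dtype=np.int8)
    pos = 0
    i0 = i1 = 0
    sym = start
    while pos < n:
        if sym == 0:
            ln = runs0[i0]
            i0 += 1
        else:
            ln = runs1[i1]
            i1 += 1
        out[pos : pos + ln] = sym
        pos += ln
        sym = 1 - sym
    return out


def whittle_surrogates(x, n_surrogates: int, seed: int) -> np.ndarray:
    """Surrogate series preserving first-order transition counts.

    Returns an (n_surrogates, len(x)) array over x's own alphabet; every
    row shares x's initial symbol, symbol counts and 2x2 transition-
    count matrix, drawn uniformly from the set of such sequences.  A
    constant series has a singleton admissible set, so all surrogates
    equal the input.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    arr = np.asarray(x)
    symbols = np.unique(arr)
    b = _as_binary(x)
    if len(b) < 3:
        raise ValueError("series too short for surrogate construction")
    rng = np.random.default_rng(seed)
    rows = np.stack([_one_surrogate(rng, b) for _ in range(n_surrogates)])
    if len(symbols) == 1:
        return np.broadcast_to(arr, rows.shape).copy()
    return symbols[rows]


@dataclass
class MIResult:
    """Observed MI with its surrogate significance threshold."""

    mi_bits: float
    surrogate_threshold_bits: float
    n_surrogates: int
    alpha: float
    significant: bool


def mi_significance(
    x,
    y,
    alpha: float = 0.01,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> MIResult:
    """One-sided surrogate test of MI against the independent-series null.

    x- and y-surrogates are drawn independently of each other, which
    preserves each series' own Markov structure while destroying any
    cross-series dependence.  The threshold is the k-th largest
    surrogate MI with k = floor(alpha * (n_surrogates + 1)); the
    observed MI is significant when it strictly exceeds the threshold.
    """
    mi = naive_mi(x, y)
    # MI is alphabet-invariant: work on the 0/1 encoding throughout
    sx = whittle_surrogates(_as_binary(x), n_surrogates, seed)
    sy = whittle_surrogates(_as_binary(y), n_surrogates, seed + 1)
    n = sx.shape[1]
    # vectorized MI over surrogate pairs via the four joint counts
    n11 = np.einsum("ij,ij->i", sx, sy).astype(float)
    nx1 = sx.sum(axis=1).astype(float)
    ny1 = sy.sum(axis=1).astype(float)
    n10 = nx1 - n11
    n01 = ny1 - n11
    n00 = n - nx1 - n01
    joint = np.stack([n00, n01, n10, n11], axis=1) / n
    px1 = nx1 / n
    py1 = ny1 / n
    outer = np.stack(
        [(1 - px1) * (1 - py1), (1 - px1) * py1, px1 * (1 - py1), px1 * py1], axis=1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / outer)
    terms[joint == 0] = 0.0
    surrogate_mi = np.maximum(terms.sum(axis=1), 0.0)
    k = max(1, int(np.floor(alpha * (n_surrogates + 1))))
    threshold = float(np.sort(surrogate_mi)[-k])
    # tolerance so that exact count ties (computed in a different
    # summation order) do not count as exceedance
    exceeds = mi > threshold + 1e-9 * max(1.0, abs(threshold))
    return MIResult(
        mi_bits=mi,
        surrogate_threshold_bits=threshold,
        n_surrogates=n_surrogates,
        alpha=alpha,
        significant=bool(exceeds),
    )
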