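"""Seed-anchored LD windows.

Every core SNP seeds a window.  Walking outward from the seed in each
direction, a candidate joins the window when |Pearson r(seed, candidate)| is
at least the threshold; a single failing SNP that is followed by a passing SNP
is rescued and included (one-SNP gap allowance for brief LD loss or mapping
error); two consecutive failures end the walk in that direction and neither
failing SNP is included.  The walk may enter the segment's flank regions but
never leaves the segment, and flank (buffer) SNPs never act as seeds.

Absolute correlation is used so that windows do not depend on the arbitrary
choice of counted allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LDWindow", "seed_correlations", "define_window", "enumerate_windows"]


@dataclass(eq=False)
class LDWindow:
    seed_index: int
    member_indices: np.ndarray   # contiguous, sorted, includes the seed
    segment: object = None

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        lo, hi = int(self.member_indices[0]), int(self.member_indices[-1])
        if not np.array_equal(self.member_indices, np.arange(lo, hi + 1)):
            raise ValueError("window members must form a contiguous index run")
        if not lo <= self.seed_index <= hi:
            raise ValueError("seed must be a window member")

    @property
    def n_snps(self) -> int:
        return len(self.member_indices)

    def key(self) -> tuple:
        return (int(self.member_indices[0]), int(self.member_indices[-1]))


def seed_correlations(X: np.ndarray, seed: int, candidate: int) -> float:
    """Pearson correlation between two (imputed, centered) dosage columns.

    A zero-variance column yields 0: a monomorphic SNP can never pass any
    threshold.
    """
    xs = X[:, seed] - X[:, seed].mean()
    xc = X[:, candidate] - X[:, candidate].mean()
    ss = float(xs @ xs)
    sc = float(xc @ xc)
    if ss <= 0.0 or sc <= 0.0:
        return 0.0
    return float(xs @ xc) / np.sqrt(ss * sc)


def _walk(corr, seed, step, stop, threshold):
    """Walk from seed by ``step`` until ``stop`` (exclusive); return the last
    included index, honouring the single-gap rescue and two-failure stop."""
    last_included = seed
    pending_fail = None
    j = seed + step
    while j != stop:
        if abs(corr(j)) >= threshold:
            last_included = j          # includes any pending failed SNP between
            pending_fail = None
        else:
            if pending_fail is not None:
                break                  # two consecutive failures: both excluded
            pending_fail = j
        j += step
    return last_included


def define_window(X: np.ndarray, segment, seed: int, threshold: float = 0.1) -> LDWindow:
    """Build the LD window anchored at core SNP ``seed`` within ``segment``.

    ``X`` is the panel-wide imputed centered dosage matrix (individuals x
    SNPs); indices are panel coordinates.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not (segment.core[0] <= seed < segment.core[1]):
        raise ValueError(
            f"seed {seed} lies outside the segment core {segment.core}; "
            "buffer SNPs never seed windows"
        )
    xs = X[:, seed] - X[:, seed].mean()
    ss = float(xs @ xs)

    def corr(j):
        if ss <= 0.0:
            return 0.0
        xc = X[:, j] - X[:, j].mean()
        sc = float(xc @ xc)
        if sc <= 0.0:
            return 0.0
        return float(xs @ xc) / np.sqrt(ss * sc)

    left = _walk(corr, seed, -1, segment.start - 1, threshold)
    right = _walk(corr, seed, +1, segment.stop, threshold)
    return LDWindow(
        seed_index=seed,
        member_indices=np.arange(left, right + 1),
        segment=segment,
    )


def enumerate_windows(X: np.ndarray, segments, threshold: float = 0.1):
    """One window per core SNP across all segments, then exact-duplicate
    member sets removed (keeping the first seed in map order).

    Returns ``(windows, n_raw)`` so callers can log both counts.
    """
    windows = []
    seen = set()
    n_raw = 0
    for seg in segments:
        for seed in seg.core_indices:
            n_raw += 1
            w = define_window(X, seg, seed, threshold)
            k = w.key()
            if k not in seen:
                seen.add(k)
                windows.append(w)
    return windows, n_raw
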