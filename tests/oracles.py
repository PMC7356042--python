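"""Independent reference implementations used only to check package output.

Each oracle recomputes a quantity from first principles by a different route
than the package takes: substring enumeration instead of boundary joining
for digestion, the textbook pooled-variance t statistic instead of
scipy.stats.ttest_ind, exact label permutation instead of a parametric null.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def cleavable_after(sequence: str, pos: int, lysc: bool = False) -> bool:
    """True if trypsin (or trypsin/LysC) cuts after 1-based position pos."""
    if pos >= len(sequence):
        return False
    aa = sequence[pos - 1]
    if aa not in "KR":
        return False
    if sequence[pos] == "P" and not (lysc and aa == "K"):
        return False
    return True


def brute_force_digest(sequence: str, max_missed: int,
                       lysc: bool = False) -> set[tuple[int, int]]:
    """Every substring satisfying the fully-tryptic predicate, by enumeration.

    Tests all O(n^2) (start, end) spans: both termini must conform to the
    cleavage rule (or be protein termini) and the number of unused internal
    cleavage sites must not exceed ``max_missed``.  Returns 1-based
    inclusive spans.
    """
    n = len(sequence)
    cut = np.array([cleavable_after(sequence, i, lysc) for i in range(1, n)],
                   dtype=bool)  # cut[i-1]: bond after position i
    cum = np.concatenate([[0], np.cumsum(cut)])  # cum[i] = cuts in bonds 1..i
    start_ok = np.array([s == 1 or cut[s - 2] for s in range(1, n + 1)])
    end_ok = np.array([e == n or cut[e - 1] for e in range(1, n + 1)])
    spans = set()
    for s in range(1, n + 1):
        if not start_ok[s - 1]:
            continue
        for e in range(s, n + 1):
            if not end_ok[e - 1]:
                continue
            missed = cum[e - 1] - cum[s - 1]
            if missed <= max_missed:
                spans.add((s, e))
    return spans


def tryptic_status_oracle(sequence: str, start: int, end: int,
                          lysc: bool = False) -> str:
    n = len(sequence)
    n_ok = start == 1 or cleavable_after(sequence, start - 1, lysc)
    c_ok = end == n or cleavable_after(sequence, end, lysc)
    if n_ok and c_ok:
        return "fully_tryptic"
    if n_ok or c_ok:
        return "semi_tryptic"
    return "non_tryptic"


def student_t_pvalue(a, b) -> float:
    """Two-sided pooled-variance two-sample t-test from the textbook formula."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return 2.0 * t_dist.sf(abs(t_stat), df)


def exact_permutation_pvalue(a, b) -> float:
    """Two-sided exact permutation p-value on the difference of means."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    na = len(a)
    observed = abs(np.mean(pooled[:na]) - np.mean(pooled[na:]))
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


def overlap_by_sets(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    return len(set(range(start_a, end_a + 1)) & set(range(start_b, end_b + 1)))
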