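"""Brute-force reference implementations used as independent oracles."""

from __future__ import annotations

import itertools

import numpy as np

from exocrac.records import revcomp


def oracle_longest_run(seq: str) -> int:
    """Enumerate every substring start and extend; N breaks runs."""
    best = 0
    for i in range(len(seq)):
        if seq[i] == "N":
            continue
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        best = max(best, j - i)
    return best


def oracle_align(seq: str, references: dict, max_mismatch: int = 2,
                 allow_deletion: bool = True, min_aligned: int = 15,
                 deletion_penalty: float = 0.5):
    """All-positions scan over both strands of every reference.

    Returns the set of (reference, start, strand) placements tied at
    the minimum score, with the same scoring rule as the package
    aligner (mismatches + 0.5 per deletion), softclip disallowed.
    """
    placements: dict = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        L = len(s)
        for name, ref in references.items():
            R = len(ref)
            if L >= min_aligned:
                for start in range(R - L + 1):
                    mm = sum(a != b for a, b in zip(s, ref[start:start + L]))
                    if mm <= max_mismatch:
                        key = (name, start, strand)
                        sc = float(mm)
                        if sc < placements.get(key, np.inf):
                            placements[key] = sc
            if allow_deletion and L >= max(2, min_aligned - 1):
                for start in range(R - L):
                    window = ref[start:start + L + 1]
                    best = min(
                        sum(a != b for a, b in zip(s[:d], window[:d]))
                        + sum(a != b for a, b in zip(s[d:], window[d + 1:]))
                        for d in range(1, L))
                    if best <= max_mismatch:
                        key = (name, start, strand)
                        sc = best + deletion_penalty
                        if sc < placements.get(key, np.inf):
                            placements[key] = sc
    if not placements:
        return set()
    top = min(placements.values())
    return {k for k, v in placements.items() if abs(v - top) < 1e-9}


def oracle_tail_call(ref: str, start: int, blen: int, tail: int,
                     min_tail: int = 2):
    """Expected (raw_run, genomic_A, nonencoded, tailed) for a read
    constructed as ``ref[start:start+blen] + "A"*tail``.

    The 3' A-run of the insert spans the appended tail plus any
    trailing genomic A's of the body; absorption counts reference A's
    from the stripped body's 3' end onward.
    """
    body = ref[start:start + blen]
    trailing = 0
    for c in reversed(body):
        if c != "A":
            break
        trailing += 1
    raw = tail + trailing if (tail > 0 or trailing > 0) else 0
    genomic = 0
    pos = start + blen - trailing
    while pos < len(ref) and genomic < raw and ref[pos] == "A":
        genomic += 1
        pos += 1
    non = raw - genomic
    return raw, genomic, non, non >= min_tail


def oracle_kmedians_optimum(X: np.ndarray, k: int = 2) -> float:
    """Exhaustive enumeration of all k-partitions of the rows.

    For each partition the center is the component-wise median and the
    objective the summed Euclidean distances; returns the global
    minimum (the same center rule as the package's k-medians).
    """
    n = len(X)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        labels = np.array(assignment)
        obj = 0.0
        for j in range(k):
            members = X[labels == j]
            med = np.median(members, axis=0)
            obj += np.linalg.norm(members - med, axis=1).sum()
        if obj < best:
            best = obj
    return float(best)
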