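"""Shared test helpers: compact builders and independent oracles."""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import permutations

import numpy as np

from stemlinc.genemodels import Gene, Transcript
from stemlinc.intervals import GenomicInterval


def tx(tid, exons, chrom="chr1", strand="+", **kw) -> Transcript:
    return Transcript(
        tid, [GenomicInterval(chrom, s, e, strand) for s, e in exons], **kw
    )


def gene(gid, transcripts) -> Gene:
    return Gene(gid, list(transcripts))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_components(transcripts) -> list[frozenset]:
    """O(n^2) connected components of the same-strand exonic-overlap graph."""
    n = len(transcripts)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = transcripts[i], transcripts[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if any(
                ea.start < eb.end and eb.start < ea.end
                for ea in a.exons
                for eb in b.exons
            ):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(transcripts[k].transcript_id for k in comp))
    return comps


def fisher_oracle(a, b, c, d, sidedness="greater") -> float:
    """Exact Fisher p by full margin-conditioned enumeration (Fractions)."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    weights = {
        k: Fraction(math.comb(c1, k) * math.comb(N - c1, r1 - k))
        for k in range(lo, hi + 1)
    }
    total = sum(weights.values())
    probs = {k: w / total for k, w in weights.items()}
    if sidedness == "greater":
        p = sum(p_ for k, p_ in probs.items() if k >= a)
    elif sidedness == "less":
        p = sum(p_ for k, p_ in probs.items() if k <= a)
    else:
        p_obs = probs[a]
        p = sum(p_ for p_ in probs.values() if p_ <= p_obs)
    return float(p)


def gcc_oracle_directional(x, y) -> float:
    """GCC(x|y) by averaging the sorted-order formula over tied-y orderings.

    Independent of the rank-weight implementation: explicitly enumerates
    every admissible ascending ordering of y (permuting within tied
    blocks) and averages the weighted sum of x in that order.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    w = np.array([2 * (i + 1) - n - 1 for i in range(n)], float)
    denom = float(w @ np.sort(x))
    if denom == 0:
        raise ZeroDivisionError("constant x")
    order = np.argsort(y, kind="stable")
    blocks, i = [], 0
    while i < n:
        j = i
        while j < n and y[order[j]] == y[order[i]]:
            j += 1
        blocks.append(list(order[i:j]))
        i = j
    nums = []
    def rec(prefix, rest):
        if not rest:
            nums.append(float(w @ x[np.array(prefix)]))
            return
        for perm in permutations(rest[0]):
            rec(prefix + list(perm), rest[1:])
    rec([], blocks)
    return float(np.mean(nums)) / denom


def gcc_oracle(x, y) -> float:
    gxy = gcc_oracle_directional(x, y)
    gyx = gcc_oracle_directional(y, x)
    return gxy if abs(gxy) >= abs(gyx) else gyx


# nested clades of the default 7-taxon tree, written out by hand
NESTED_CLADES = [
    {"human"},
    {"human", "chimp"},
    {"human", "chimp", "gorilla"},
    {"human", "chimp", "gorilla", "orangutan"},
    {"human", "chimp", "gorilla", "orangutan", "rhesus"},
    {"human", "chimp", "gorilla", "orangutan", "rhesus", "marmoset"},
    {"human", "chimp", "gorilla", "orangutan", "rhesus", "marmoset", "mouse"},
]


def dating_oracle(present_with_focal: set) -> int | None:
    """Index of the unique nested clade equal to the present set, else None."""
    for rank, clade in enumerate(NESTED_CLADES):
        if clade == present_with_focal:
            return rank
    return None
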