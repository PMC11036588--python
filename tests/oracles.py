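"""Brute-force reference implementations used to validate the scanners and
statistics by exhaustive computation on small inputs.

These deliberately share no code with the package: runs are found by direct
per-period scanning, dispersed pairs by enumerating every diagonal of every
orientation, and the rank test by enumerating every labelling.
"""

from itertools import combinations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_minimal_period(s: str) -> int:
    for q in range(1, len(s) + 1):
        if all(s[i] == s[i - q] for i in range(q, len(s))):
            return q
    return len(s)


def _match(x: str, y: str) -> bool:
    return x == y and x != "N"


def brute_runs(seq: str, p: int):
    """Maximal [a,b) with seq[j] == seq[j-p] for all j in [a+p, b)."""
    n = len(seq)
    j = p
    while j < n:
        if _match(seq[j], seq[j - p]):
            a = j - p
            while j < n and _match(seq[j], seq[j - p]):
                j += 1
            yield a, j
        else:
            j += 1


def brute_ssrs(seq: str, thresholds: dict[int, int]):
    """(motif, copies, start, end) for every qualifying microsatellite."""
    out = []
    for u, min_copies in sorted(thresholds.items()):
        for a, b in brute_runs(seq, u):
            copies = (b - a) // u
            if copies < min_copies:
                continue
            if brute_minimal_period(seq[a:b]) != u:
                continue
            out.append((seq[a : a + u], copies, a, a + u * copies))
    return sorted(out)


def brute_tandem(seq: str, min_period: int, max_period: int, min_total: int):
    """(period, start, end) of every maximal exact tandem array."""
    out = []
    for p in range(min_period, min(max_period, len(seq) // 2) + 1):
        for a, b in brute_runs(seq, p):
            if b - a < max(2 * p, min_total):
                continue
            if brute_minimal_period(seq[a:b]) != p:
                continue
            out.append((p, a, b))
    return sorted(out)


def brute_dispersed(seq: str, min_len: int, max_mismatch: int):
    """Canonical (class, start1, start2, length, mismatches) of every maximal
    pair, by full diagonal enumeration in all four orientations.

    Only the per-diagonal character comparison is vectorized; every diagonal
    of every orientation is still checked directly.
    """
    n = len(seq)
    k = max_mismatch
    targets = {
        "forward": seq,
        "palindromic": revcomp(seq),
        "reverse": seq[::-1],
        "complement": seq.translate(_COMP),
    }
    s_arr = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int16)
    s_arr[s_arr == ord("N")] = -1
    found = {}
    for klass, tgt in targets.items():
        t_arr = np.frombuffer(tgt.encode(), dtype=np.uint8).astype(np.int16)
        t_arr[t_arr == ord("N")] = -2
        for d in range(-(n - 1), n):
            t0 = max(0, -d)
            t1 = min(n, n - d)
            span = t1 - t0
            if span < min_len:
                continue
            mism = np.flatnonzero(
                s_arr[t0:t1] != t_arr[t0 + d : t1 + d]
            ).tolist()
            if len(mism) <= k:
                windows = [(0, span - 1)]
            else:
                windows = []
                for j in range(len(mism) - k + 1):
                    left = mism[j - 1] + 1 if j > 0 else 0
                    right = mism[j + k] - 1 if j + k < len(mism) else span - 1
                    windows.append((left, right))
            for left, right in windows:
                length = right - left + 1
                if length < min_len:
                    continue
                i1 = t0 + left
                u1 = t0 + d + left
                if klass in ("forward", "complement"):
                    j1 = u1
                else:
                    j1 = n - u1 - length
                if i1 == j1:
                    continue
                a, b = sorted((i1, j1))
                mm = int((s_arr[i1 : i1 + length] != t_arr[u1 : u1 + length]).sum())
                found[(klass, a, b, length)] = mm
    return sorted((k_ + (v,)) for k_, v in found.items())


def brute_mannwhitney_p(a, b):
    """Exact two-sided p by full enumeration of labellings (midranks)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    n = len(pooled)
    srt = sorted(pooled)
    ranks = []
    for v in pooled:
        lo = srt.index(v)
        hi = n - 1 - srt[::-1].index(v)
        ranks.append((lo + hi) / 2 + 1)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        lo += u <= u_obs + 1e-9
        hi += u >= u_obs - 1e-9
    return min(1.0, 2 * min(lo, hi) / total), u_obs
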