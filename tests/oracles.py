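"""Independent brute-force reference implementations used only by tests.

Each function re-derives a result from its textbook definition with
primitives different from the library path it checks.
"""

from __future__ import annotations

from math import comb

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def bh_textbook(p):
    """Step-up BH by the rank formula, applied literally."""
    n = len(p)
    order = sorted(range(n), key=lambda i: (p[i], i))
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * n / rank))
        q[i] = running
    return q


def holm_textbook(p):
    """Step-down Holm by the rank formula, applied literally."""
    n = len(p)
    order = sorted(range(n), key=lambda i: (p[i], i))
    out = [0.0] * n
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (n - rank) * p[i]))
        out[i] = running
    return out


def hypergeom_tail_enumerated(k, K, n, N):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)) / total


def sw_score_dp(a, b, match=1, mismatch=-1, gap=-2):
    """Smith-Waterman best score by the plain quadratic recurrence."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def naive_seed_sites(mirna, target):
    """Position-by-position Watson-Crick pairing scan.

    Returns {core_start: site_class} keyed by the start of the seed-2-7
    core match, classifying each binding register at its highest class.
    """
    mirna = mirna.upper().replace("U", "T")
    seed = mirna[1:8]  # positions 2-8

    def pairs(t_base, m_base):
        return (t_base, m_base) in _PAIR

    def window_matches(start, n_seed):
        # antiparallel: target[start + j] pairs seed base n_seed-1-j
        for j in range(n_seed):
            if start + j >= len(target):
                return False
            if not pairs(target[start + j], seed[n_seed - 1 - j]):
                return False
        return True

    out = {}
    for start in range(len(target)):
        if window_matches(start, 7):  # seed 2-8 matched; core 2-7 begins at start+1
            core = start + 1
            has_a = core + 6 < len(target) and target[core + 6] == "A"
            cls = "8mer" if has_a else "7mer-m8"
            out[core] = _higher(out.get(core), cls)
    for start in range(len(target)):
        if window_matches(start, 6):
            has_a = start + 6 < len(target) and target[start + 6] == "A"
            cls = "7mer-A1" if has_a else "6mer"
            out[start] = _higher(out.get(start), cls)
    return out


_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}


def _higher(existing, candidate):
    if existing is None or _RANK[candidate] > _RANK[existing]:
        return candidate
    return existing


def pwm_score_naive(seq, probs, offset, background=0.25):
    """Per-position log-odds summation, one base at a time."""
    from math import log2

    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for j in range(probs.shape[1]):
        base = seq[offset + j]
        if base in idx:
            total += log2(probs[idx[base], j] / background)
    return total
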