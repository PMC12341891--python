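"""Independent brute-force oracles for partition measures.

Deliberately naive: plain dict counting, per-element loops, pair
enumeration.  Shares no code path with the package implementation.
"""

import math
from collections import Counter
from itertools import combinations


def _joint_counts(p_labels, q_labels):
    return Counter(zip(p_labels, q_labels))


def _entropy_of(counter, n):
    h = 0.0
    for c in counter.values():
        h -= (c / n) * math.log(c / n)
    return h


def oracle_vi(p_labels, q_labels):
    n = len(p_labels)
    hp = _entropy_of(Counter(p_labels), n)
    hq = _entropy_of(Counter(q_labels), n)
    hj = _entropy_of(_joint_counts(p_labels, q_labels), n)
    return 2.0 * hj - hp - hq


def oracle_nmi(p_labels, q_labels):
    n = len(p_labels)
    pc, qc, jc = Counter(p_labels), Counter(q_labels), _joint_counts(p_labels, q_labels)
    hp, hq = _entropy_of(pc, n), _entropy_of(qc, n)
    if hp == 0.0 and hq == 0.0:
        return 1.0
    if hp == 0.0 or hq == 0.0:
        return 0.0
    mi = 0.0
    for (a, b), c in jc.items():
        mi += (c / n) * math.log(c * n / (pc[a] * qc[b]))
    return mi / math.sqrt(hp * hq)


def oracle_ari(p_labels, q_labels):
    """ARI by explicit enumeration of all element pairs."""
    n = len(p_labels)
    ss = sd = ds = dd = 0  # same/same, same/diff, diff/same, diff/diff
    for i, j in combinations(range(n), 2):
        same_p = p_labels[i] == p_labels[j]
        same_q = q_labels[i] == q_labels[j]
        if same_p and same_q:
            ss += 1
        elif same_p:
            sd += 1
        elif same_q:
            ds += 1
        else:
            dd += 1
    pairs = n * (n - 1) // 2
    expected = (ss + sd) * (ss + ds) / pairs
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


def oracle_split_join(p_labels, q_labels):
    """Direct overlap maximization in both directions."""
    n = len(p_labels)
    blocks_p = {}
    blocks_q = {}
    for i in range(n):
        blocks_p.setdefault(p_labels[i], set()).add(i)
        blocks_q.setdefault(q_labels[i], set()).add(i)

    def one_way(src, dst):
        total = 0
        for block in src.values():
            total += max(len(block & other) for other in dst.values())
        return n - total

    return one_way(blocks_p, blocks_q) + one_way(blocks_q, blocks_p)
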