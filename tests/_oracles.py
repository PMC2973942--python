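"""Brute-force reference implementations used by the acceptance tests.

These deliberately use different mechanics from the library: contiguity is
decided by rotating the raw label list and comparing prefixes, adjacencies
are enumerated as explicit 4-tuples, and repeats are extended by whole
substring comparison.
"""

import itertools


def contiguous(order, subset, circular=True):
    labels = [label for label, _ in order.tokens]
    k = len(subset)
    if circular:
        doubled = labels + labels
        return any(set(doubled[i:i + k]) == subset for i in range(len(labels)))
    return any(set(labels[i:i + k]) == subset for i in range(len(labels) - k + 1))


def common_interval_count(a, b, sizes, circular=True):
    labels = sorted(a.labels())
    count = 0
    for k in sizes:
        for combo in itertools.combinations(labels, k):
            s = set(combo)
            if contiguous(a, s, circular) and contiguous(b, s, circular):
                count += 1
    return count


def breakpoint_count(a, b, circular=True):
    def adjacencies_with_reverse(order):
        toks = list(order.tokens) + ([order.tokens[0]] if circular else [])
        out = set()
        for (l1, s1), (l2, s2) in zip(toks, toks[1:]):
            out.add((l1, s1, l2, s2))
            out.add((l2, -s2, l1, -s1))
        return out

    adj_b = adjacencies_with_reverse(b)
    toks = list(a.tokens) + ([a.tokens[0]] if circular else [])
    return sum(1 for (l1, s1), (l2, s2) in zip(toks, toks[1:])
               if (l1, s1, l2, s2) not in adj_b)


def maximal_repeats(seq, min_unit, min_copies=2):
    n = len(seq)
    occurrences = {}
    for i in range(n - min_unit + 1):
        occurrences.setdefault(seq[i:i + min_unit], []).append(i)
    out = set()
    for pos in occurrences.values():
        if len(pos) < min_copies:
            continue
        left = 0
        while (min(pos) - left - 1 >= 0
               and len({seq[p - left - 1: p + min_unit] for p in pos}) == 1):
            left += 1
        right = 0
        while (max(pos) + min_unit + right < n
               and len({seq[p - left: p + min_unit + right + 1] for p in pos}) == 1):
            right += 1
        starts = tuple(p - left for p in pos)
        out.add((seq[starts[0]: starts[0] + min_unit + left + right], starts))
    return out
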