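"""Independent brute-force motif scorer used as a test oracle.

Deliberately written with plain Python loops and its own arithmetic (no
shared code with the package's vectorized scanner) so the two paths can
cross-validate each other.
"""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def naive_revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def naive_frequencies(counts, pseudocount):
    freqs = []
    for row in counts:
        total = sum(row) + 4 * pseudocount
        freqs.append([(c + pseudocount) / total for c in row])
    return freqs


def naive_info_weights(freqs):
    weights = []
    for row in freqs:
        h = sum(p * math.log2(p) for p in row if p > 0)
        weights.append(2.0 + h)
    return weights


def naive_mat_sim(counts, pseudocount, subseq):
    freqs = naive_frequencies(counts, pseudocount)
    weights = naive_info_weights(freqs)
    denom = sum(w * max(row) for w, row in zip(weights, freqs))
    if denom == 0:
        return 0.0
    num = 0.0
    for w, row, base in zip(weights, freqs, subseq):
        p = row[_IDX[base]] if base in _IDX else 0.0
        num += w * p
    return num / denom


def naive_scan(counts, pseudocount, sequence, threshold):
    """(forward_offsets, reverse_offsets) of hits scoring >= threshold."""
    L = len(counts)
    fwd, rev = [], []
    for strand, seq, out in (
        ("+", sequence, fwd),
        ("-", naive_revcomp(sequence), rev),
    ):
        for offset in range(len(seq) - L + 1):
            if naive_mat_sim(counts, pseudocount, seq[offset : offset + L]) >= threshold:
                out.append(offset)
    return fwd, rev
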