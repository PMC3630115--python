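"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately written in plain Python (dicts, math.log, direct iteration),
sharing no code path with the package's numpy/scipy implementation.
"""

import math


def abundance_dict(bg):
    """Background frequencies as a plain residue->float dict."""
    return dict(bg.frequencies)


def oracle_subpocket_entropy(records, pos_index, freqs, base=math.e):
    """Tally residues at one window position and evaluate the score directly."""
    tally = {}
    for rec in records:
        ch = rec.window[pos_index]
        if ch in freqs:
            tally[ch] = tally.get(ch, 0) + 1
    if not tally:
        return None
    weighted = {a: c / freqs[a] for a, c in tally.items()}
    total = sum(weighted.values())

    def log(x):
        return math.log(x, base)

    return -sum((v / total) * log(v / total) for v in weighted.values()) / log(20)


def oracle_total_entropy(records, freqs):
    values = []
    for i in range(8):
        s = oracle_subpocket_entropy(records, i, freqs)
        if s is None:
            return None
        values.append(s)
    return sum(values)


def oracle_pairwise_entropy(records, i, j, freqs, base=math.e):
    """Direct enumeration of residue pairs at positions (i, j)."""
    tally = {}
    for rec in records:
        a, b = rec.window[i], rec.window[j]
        if a in freqs and b in freqs:
            tally[(a, b)] = tally.get((a, b), 0) + 1
    if not tally:
        return None
    weighted = {k: c / (freqs[k[0]] * freqs[k[1]]) for k, c in tally.items()}
    total = sum(weighted.values())

    def log(x):
        return math.log(x, base)

    return -sum((v / total) * log(v / total) for v in weighted.values()) / log(400)


def mixture_motif_entropy(q):
    """Closed-form S_i for a motif position: fraction q fixed to one residue,
    remainder uniform over all 20, under a uniform background."""
    p_motif = q + (1 - q) / 20.0
    p_other = (1 - q) / 20.0
    terms = []
    if p_motif > 0:
        terms.append(p_motif * math.log(p_motif))
    if p_other > 0:
        terms.extend([p_other * math.log(p_other)] * 19)
    return -sum(terms) / math.log(20)
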