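"""Independent brute-force reference implementations used only by tests.

Everything here is written as explicit pair/column enumeration with plain
Python loops, deliberately sharing no code path with the package.
"""

import itertools


def gene_diversity_pairs(counts):
    """h as the small-sample-corrected fraction of unordered pairs that differ.

    Equivalent to Nei's unbiased estimator: n/(n-1)*(1 - sum p_i^2) equals
    (# differing unordered pairs) / C(n, 2).
    """
    labels = []
    for k, c in enumerate(counts):
        labels.extend([k] * c)
    n = len(labels)
    pairs = diff = 0
    for a, b in itertools.combinations(range(n), 2):
        pairs += 1
        diff += labels[a] != labels[b]
    return diff / pairs


def nucleotide_diversity_loops(seqs):
    """pi by double loop over pairs and columns with pairwise deletion."""
    n = len(seqs)
    total = pairs = 0.0
    for i, j in itertools.combinations(range(n), 2):
        comp = diff = 0
        for a, b in zip(seqs[i], seqs[j]):
            if a in "ACGT" and b in "ACGT":
                comp += 1
                diff += a != b
        total += diff / comp
        pairs += 1
    return total / pairs


def hamming_pairwise_deletion(s1, s2):
    comp = diff = 0
    for a, b in zip(s1, s2):
        if a in "ACGT" and b in "ACGT":
            comp += 1
            diff += a != b
    return diff, comp


def sharing_count_pairs(haplotypes):
    """# individuals appearing in >= 1 identical-haplotype pair (per id list)."""
    sharing = set()
    for i, j in itertools.combinations(range(len(haplotypes)), 2):
        if haplotypes[i] == haplotypes[j]:
            sharing.add(i)
            sharing.add(j)
    return len(sharing)


def amova_ss_pairs(d, labels):
    """(SS_among, SS_within) of a one-level AMOVA by explicit pair enumeration."""
    n = len(labels)
    ss_total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        ss_total += d[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        s = 0.0
        for a, b in itertools.combinations(idx, 2):
            s += d[a][b] ** 2
        ss_within += s / len(idx)
    return ss_total - ss_within, ss_within


def phipt_components(d, labels):
    """PhiPT from the pair-enumerated SS partition (truncated at zero)."""
    groups = sorted(set(labels), key=str)
    n = len(labels)
    k = len(groups)
    sizes = [labels.count(g) for g in groups]
    ss_among, ss_within = amova_ss_pairs(d, labels)
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (n - k)
    n0 = (n - sum(s * s for s in sizes) / n) / (k - 1)
    var_a = (ms_among - ms_within) / n0
    var_w = ms_within
    var_a_trunc = max(0.0, var_a)
    total = var_a_trunc + var_w
    return var_a_trunc / total if total > 0 else 0.0
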