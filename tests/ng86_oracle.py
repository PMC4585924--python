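"""Independent brute-force oracle for Nei–Gojobori site/difference counting.

Kept deliberately separate from the package: the genetic code is a hardcoded
literal (table 11 shares all codon assignments with the standard code) and
the counting is done by plain enumeration with no caching or tables, so it
can serve as a second, independent implementation to check the estimator
against on all sense-codon pairs.
"""

from itertools import permutations, product

_BASES_TCAG = "TCAG"
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODE = {
    b1 + b2 + b3: _AA_STRING[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES_TCAG)
    for j, b2 in enumerate(_BASES_TCAG)
    for k, b3 in enumerate(_BASES_TCAG)
}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


def oracle_sites(codon):
    """(synonymous, non-synonymous) fractional site counts of one codon."""
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if CODE[nb] == "*":
                continue
            outcomes.append(CODE[nb] == CODE[codon])
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def oracle_differences(c1, c2):
    """Pathway-averaged (synonymous, non-synonymous) differences between two
    sense codons; pathways through stops excluded, with an all-pathways
    fallback when every pathway is blocked."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(positions):
        cur, sd, nd, hits_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODE[nxt] == "*" and nxt != c2:
                hits_stop = True
            if CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hits_stop else clean).append((sd, nd))
    use = clean or blocked
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def oracle_kska(codons_a, codons_b):
    """Whole-alignment NG86 computed from the primitives above, with the
    Jukes–Cantor correction applied by formula (None when saturated)."""
    import math

    s_a = sum(oracle_sites(c)[0] for c in codons_a)
    s_b = sum(oracle_sites(c)[0] for c in codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(codons_a) - S
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d = oracle_differences(ca, cb)
        sd += d[0]
        nd += d[1]

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(sd / S) if S > 0 else None
    ka = jc(nd / N) if N > 0 else None
    return {"S": S, "N": N, "Sd": sd, "Nd": nd, "ks": ks, "ka": ka}


def all_sense_pairs():
    return product(SENSE, repeat=2)
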