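"""Independent brute-force oracles for the feature encoders and metrics.

Everything here is written with plain Python loops and dicts, deliberately
avoiding the package's vectorized code paths, so agreement between the two is
a meaningful check and not a tautology.
"""

from itertools import product
from math import sqrt

BASES = "ACGT"
DINUCS = ["".join(p) for p in product(BASES, repeat=2)]
TRINUCS = ["".join(p) for p in product(BASES, repeat=3)]


def oracle_mono(seq):
    return [seq.count(b) / len(seq) for b in BASES]


def oracle_kmer(seq, k):
    counts = {"".join(p): 0 for p in product(BASES, repeat=k)}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return [counts[w] for w in sorted(counts)]


def oracle_skews(seq):
    g, c = seq.count("G"), seq.count("C")
    a, t = seq.count("A"), seq.count("T")
    gc = (g - c) / (g + c) if g + c else 0.0
    at = (a - t) / (a + t) if a + t else 0.0
    return gc, at


def oracle_eiip(seq, eiip):
    n = len(seq) - 2
    out = []
    for w in TRINUCS:
        cnt = sum(1 for i in range(n) if seq[i : i + 3] == w)
        out.append((cnt / n) * (eiip[w[0]] + eiip[w[1]] + eiip[w[2]]))
    return out


def oracle_pstnp(pos_seqs, neg_seqs):
    """Per-position trinucleotide frequency difference, counted naively."""
    L = len(pos_seqs[0])
    z = []
    for i in range(L - 2):
        row = []
        for w in TRINUCS:
            fp = sum(1 for s in pos_seqs if s[i : i + 3] == w) / len(pos_seqs)
            fn = sum(1 for s in neg_seqs if s[i : i + 3] == w) / len(neg_seqs)
            row.append(fp - fn)
        z.append(row)
    return z


def oracle_pstnp_encode(seq, z):
    return [z[i][TRINUCS.index(seq[i : i + 3])] for i in range(len(seq) - 2)]


def _series(seq, prop):
    return [prop[seq[i : i + 2]] for i in range(len(seq) - 1)]


def oracle_dac(seq, props, lag_max):
    """props: list of dicts dinucleotide -> standardized value."""
    out = []
    for prop in props:
        P = _series(seq, prop)
        mean = sum(P) / len(P)
        for d in range(1, lag_max + 1):
            n = len(P) - d
            out.append(sum((P[i] - mean) * (P[i + d] - mean) for i in range(n)) / n)
    return out


def oracle_dcc(seq, props, lag_max):
    out = []
    for u1, p1 in enumerate(props):
        for u2, p2 in enumerate(props):
            if u1 == u2:
                continue
            P1, P2 = _series(seq, p1), _series(seq, p2)
            m1 = sum(P1) / len(P1)
            m2 = sum(P2) / len(P2)
            for d in range(1, lag_max + 1):
                n = len(P1) - d
                out.append(
                    sum((P1[i] - m1) * (P2[i + d] - m2) for i in range(n)) / n
                )
    return out


def oracle_mac(seq, props, lag_max):
    out = []
    for prop in props:
        P = _series(seq, prop)
        mean = sum(P) / len(P)
        var = sum((x - mean) ** 2 for x in P) / len(P)
        for d in range(1, lag_max + 1):
            n = len(P) - d
            num = sum((P[i] - mean) * (P[i + d] - mean) for i in range(n)) / n
            out.append(num / var if var > 0 else 0.0)
    return out


def oracle_nmbac(seq, props, lag_max):
    out = []
    for prop in props:
        P = _series(seq, prop)
        for d in range(1, lag_max + 1):
            n = len(P) - d
            out.append(sum(P[i] * P[i + d] for i in range(n)) / n)
    return out


def oracle_pc_pse_tnc(seq, tri_props, lam, w):
    """tri_props: list of dicts trinucleotide -> standardized value."""
    n = len(seq) - 2
    counts = {t: 0 for t in TRINUCS}
    for i in range(n):
        counts[seq[i : i + 3]] += 1
    f = [counts[t] / n for t in TRINUCS]

    def theta_pair(a, b):
        return sum((p[a] - p[b]) ** 2 for p in tri_props) / len(tri_props)

    thetas = []
    for j in range(1, lam + 1):
        m = n - j
        thetas.append(
            sum(theta_pair(seq[i : i + 3], seq[i + j : i + j + 3]) for i in range(m)) / m
        )
    denom = 1.0 + w * sum(thetas)
    return [x / denom for x in f] + [w * t / denom for t in thetas]


def oracle_motif(seq, motifs):
    out = []
    for m in motifs:
        out.append(sum(1 for i in range(len(seq) - len(m) + 1) if seq[i : i + len(m)] == m))
    return out


def props_as_dicts(names, values, words):
    """Turn a (n_props, n_words) array into a list of word->value dicts."""
    return [
        {w: float(values[u, j]) for j, w in enumerate(words)}
        for u in range(len(names))
    ]


# ---------------------------------------------------------------------------
# metrics


def oracle_confusion(scores, labels, t):
    pt = pf = nt = nf = 0
    for s, y in zip(scores, labels):
        if s >= t:
            if y == 1:
                pt += 1
            else:
                pf += 1
        else:
            if y == 0:
                nt += 1
            else:
                nf += 1
    return pt, pf, nt, nf


def oracle_metrics(pt, pf, nt, nf):
    total = pt + pf + nt + nf
    sens = 100 * pt / (pt + nf) if pt + nf else 0.0
    spec = 100 * nt / (nt + pf) if nt + pf else 0.0
    acc = 100 * (pt + nt) / total
    denom = (pt + pf) * (pt + nf) * (nt + pf) * (nt + nf)
    mcc = (pt * nt - pf * nf) / sqrt(denom) if denom else 0.0
    return sens, spec, acc, mcc


def oracle_auroc(scores, labels):
    """Exhaustive pairwise Mann-Whitney: Pr(s+ > s-) + 0.5 Pr(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
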