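"""Independent reference implementations used to validate the package.

These deliberately avoid the code paths they check: the local aligner
is a direct numba dynamic program (not Biopython), left alignment is an
exhaustive haplotype comparison, and the period finder tries every
candidate length.
"""

import numba
import numpy as np


@numba.njit
def _sw_core(q, t, match, mismatch, gap):
    nq, nt = len(q), len(t)
    H = np.zeros((nq + 1, nt + 1), dtype=np.int64)
    best = 0
    bi = bj = 0
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            if H[i - 1, j] + gap > v:
                v = H[i - 1, j] + gap
            if H[i, j - 1] + gap > v:
                v = H[i, j - 1] + gap
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    # traceback from the best cell to find the aligned query span
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if q[i - 1] == t[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return best, i, bi  # score, q_start, q_end


def _encode(s):
    return np.frombuffer(s.encode(), dtype=np.uint8)


def sw_local(query, target, match=1, mismatch=-4, gap=-6):
    """(score, q_start, q_end) of the best local alignment."""
    if not query or not target:
        return 0, 0, 0
    return _sw_core(_encode(query), _encode(target), match, mismatch, gap)


def sw_score(s1, s2, match=2, mismatch=-2, gap=-4):
    return sw_local(s1, s2, match, mismatch, gap)[0]


def tandem_dup_bruteforce(contig_seq, p, S, min_base_len=50, min_cov=0.80):
    """Exhaustive split-and-align tandem-duplication decision."""
    B = shortest_base_bruteforce(S, min_base_len)
    l = len(B)
    for m in range(l + 1):
        P_m, S_tail = B[:m], B[m:]
        ok = True
        if S_tail:
            region = contig_seq[max(0, p - len(S_tail)):p]
            if not region:
                ok = False
            else:
                _, qs, qe = sw_local(S_tail, region)
                ok = (qe - qs) >= min_cov * len(S_tail)
        if ok and P_m:
            region = contig_seq[p:p + m]
            if not region:
                ok = False
            else:
                _, qs, qe = sw_local(P_m, region)
                ok = (qe - qs) >= min_cov * len(P_m)
        if ok:
            return True
    return False


def shortest_base_bruteforce(S, min_len=50):
    """Base sequence by direct period scan, independent of failure fns.

    Finds the smallest period p that fits at least twice by checking
    S[i] == S[i-p] for every i, then takes the smallest multiple of p
    reaching min_len.
    """
    n = len(S)
    for p in range(1, n // 2 + 1):
        if all(S[i] == S[i - p] for i in range(p, n)):
            b = p
            while b < min_len:
                b += p
            return S[:b] if b < n else S
    return S


def left_align_bruteforce(ref, pos, seq):
    """Leftmost (pos', seq') giving the same alternate haplotype.

    ``pos`` counts reference bases before the insertion.  Tries every
    smaller position with every rotation of the inserted sequence and
    keeps the smallest position whose haplotype matches.
    """
    target = ref[:pos] + seq + ref[pos:]
    best = (pos, seq)
    for p in range(pos - 1, 0, -1):
        found = None
        for r in range(len(seq)):
            rot = seq[r:] + seq[:r]
            if ref[:p] + rot + ref[p:] == target:
                found = rot
                break
        if found is not None:
            best = (p, found)
    return best
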