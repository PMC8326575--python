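"""Brute-force affine local-alignment oracle (plain Python, no numpy).

Independent re-derivation of the Smith-Waterman-Gotoh contract used by the
package: three-state DP over dictionaries, explicit traceback with the
documented tie preference (match-state continuation, then vertical gap,
then horizontal gap, then termination; among co-optimal endpoints the
smallest (q_start, s_start, q_end, s_end) wins).  Intended for short
sequences only.
"""

NEG = float("-inf")


def oracle_align(q, s, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Return (score, q_start, q_end, s_start, s_end, matches, columns).

    Starts/ends are 1-based inclusive; (0, 0, 0, 0, 0, 0, 0) when no
    positive-scoring local alignment exists.
    """
    n, m = len(q), len(s)
    M = {}
    Ix = {}
    Iy = {}
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 or j == 0:
                M[i, j] = Ix[i, j] = Iy[i, j] = NEG
                continue
            sub = match if q[i - 1] == s[j - 1] else mismatch
            M[i, j] = max(0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + sub
            Ix[i, j] = max(M[i - 1, j] + gap_open + gap_extend, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open + gap_extend, Iy[i, j - 1] + gap_extend)
    best = 0
    for key, value in M.items():
        if value > best:
            best = value
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    def traceback(ei, ej):
        i, j, state = ei, ej, "M"
        matches = columns = 0
        while True:
            if state == "M":
                if q[i - 1] == s[j - 1]:
                    matches += 1
                    target = M[i, j] - match
                else:
                    target = M[i, j] - mismatch
                columns += 1
                i, j = i - 1, j - 1
                if M[i, j] == target:
                    state = "M"
                elif Ix[i, j] == target:
                    state = "Ix"
                elif Iy[i, j] == target:
                    state = "Iy"
                else:
                    return i + 1, j + 1, matches, columns
            elif state == "Ix":
                columns += 1
                state = "M" if M[i - 1, j] + gap_open + gap_extend == Ix[i, j] else "Ix"
                i -= 1
            else:
                columns += 1
                state = "M" if M[i, j - 1] + gap_open + gap_extend == Iy[i, j] else "Iy"
                j -= 1

    candidates = []
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i, j] == best:
                qs, ss, matches, columns = traceback(i, j)
                candidates.append((qs, ss, i, j, matches, columns))
    qs, ss, qe, se, matches, columns = min(candidates)
    return best, qs, qe, ss, se, matches, columns


def oracle_identity_coverage(q, s, **kwargs):
    """(score, identity %, coverage %) under the same contract."""
    score, qs, qe, _ss, _se, matches, columns = oracle_align(q, s, **kwargs)
    if score <= 0:
        return 0, 0.0, 0.0
    return score, 100.0 * matches / columns, 100.0 * (qe - qs + 1) / len(q)
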