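"""Independent brute-force oracles used across the test suite."""


def brute_local_score(mirna, target, params):
    """Plain-Python exhaustive Gotoh oracle for the complementarity DP."""
    rm = mirna[::-1]
    L, N = len(rm), len(target)
    NEG = -1e9
    M = [[NEG] * (N + 1) for _ in range(L + 1)]
    Ix = [[NEG] * (N + 1) for _ in range(L + 1)]
    Iy = [[NEG] * (N + 1) for _ in range(L + 1)]
    best = 0.0
    op, ex = -params.gap_open, -params.gap_extend
    for i in range(1, L + 1):
        pos = L - (i - 1)  # 1-based miRNA position from the 5' end
        scale = params.seed_scale if params.seed_start <= pos <= params.seed_end else 1.0
        for j in range(1, N + 1):
            s = params.pair_score(target[j - 1], rm[i - 1]) * scale
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i][j - 1] - op, Ix[i][j - 1] - ex)
            Iy[i][j] = max(M[i - 1][j] - op, Iy[i - 1][j] - ex)
            best = max(best, M[i][j])
    return best
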