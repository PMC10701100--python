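"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: the motif oracle
walks the token list with explicit backtracking instead of compiling a
regex, and the rank-test oracle recounts concordant pairs for every group
assignment instead of ranking once.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from degronkit.motifs import Token, parse_pattern


def _match_at(tokens: list[Token], seq: str, pos: int) -> int | None:
    """Length matched at ``pos`` (0-based) under leftmost-greedy semantics,
    or None. Repetition counts are tried in descending order with
    backtracking, mirroring how a greedy regex resolves bounded
    quantifiers."""
    if not tokens:
        return 0
    token, rest = tokens[0], tokens[1:]
    for k in range(token.max_repeat, token.min_repeat - 1, -1):
        if pos + k > len(seq):
            continue
        window = seq[pos : pos + k]
        ok = True
        for c in window:
            if c == "X":
                ok = token.wildcard
            else:
                ok = c in token.allowed
            if not ok:
                break
        if not ok:
            continue
        tail = _match_at(rest, seq, pos + k)
        if tail is not None:
            return k + tail
    return None


def brute_force_scan(pattern: str, seq: str) -> list[tuple[int, int]]:
    """Every (start, end) match of ``pattern`` in ``seq``, 1-based inclusive,
    one greedy match per start offset."""
    tokens = parse_pattern(pattern)
    out = []
    for pos in range(len(seq)):
        length = _match_at(tokens, seq, pos)
        if length is not None:
            out.append((pos + 1, pos + length))
    return out


def mann_whitney_exact_oracle(x, y) -> tuple[float, float]:
    """Two-tailed exact Mann–Whitney by direct pair counting.

    For every assignment of the pooled values to a group of size n_x, U is
    recomputed as (# pairs x > y) + 0.5 * (# tied pairs); the p-value is the
    fraction of assignments at least as extreme (|U - n_x*n_y/2|) as the
    observed split.
    """
    pooled = list(x) + list(y)
    n_x, n_y = len(x), len(y)

    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(x, y)
    centre = n_x * n_y / 2
    dev = abs(u_obs - centre)
    hits = 0
    idx = range(n_x + n_y)
    for chosen in combinations(idx, n_x):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen_set]
        if abs(u_of(xs, ys) - centre) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / comb(n_x + n_y, n_x)
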