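"""Brute-force oracle for collinear-block chaining.

Finds the maximum-score gap-bounded monotone chain by exhaustive depth-first
enumeration of every chain (independent of the dynamic program under test),
then applies the same greedy extraction loop: remove the best chain, emit it
when it reaches match_size, repeat. Tie-break mirrors the documented rule:
higher score, then leftmost query rank, then forward orientation, then
lexicographic rank sequence.
"""

from __future__ import annotations


def _better(a, b, rows):
    if a[0] != b[0]:
        return a[0] > b[0]
    qa, qb = rows[a[1][0]][0], rows[b[1][0]][0]
    if qa != qb:
        return qa < qb
    if a[2] != b[2]:
        return a[2] == "forward"
    ka = [(rows[i][0], rows[i][1]) for i in a[1]]
    kb = [(rows[i][0], rows[i][1]) for i in b[1]]
    return ka < kb


def exhaustive_best_chain(rows, max_gap):
    """rows: list of (q_rank, s_rank, score). Returns (score, indices,
    orientation) of the best chain, or None."""
    if not rows:
        return None
    best = None

    def extend(chain, score, orientation):
        nonlocal best
        cand = (score, list(chain), orientation)
        if best is None or _better(cand, best, rows):
            best = cand
        ql, sl = rows[chain[-1]][0], rows[chain[-1]][1]
        for j in range(len(rows)):
            q, s = rows[j][0], rows[j][1]
            if q <= ql or q - ql - 1 > max_gap:
                continue
            ds = (s - sl) if orientation == "forward" else (sl - s)
            if ds <= 0 or ds - 1 > max_gap:
                continue
            chain.append(j)
            extend(chain, score + rows[j][2] - (q - ql - 1) - (ds - 1), orientation)
            chain.pop()

    for orientation in ("forward", "inverted"):
        for i in range(len(rows)):
            extend([i], rows[i][2], orientation)
    return best


def exhaustive_blocks(rows, match_size, max_gap):
    """Greedy extraction with the exhaustive chain finder. Returns a list of
    (orientation, frozenset of (q_rank, s_rank)) block signatures."""
    remaining = list(range(len(rows)))
    out = []
    while remaining:
        sub = [rows[i] for i in remaining]
        found = exhaustive_best_chain(sub, max_gap)
        if found is None:
            break
        score, chain, orientation = found
        chosen = [remaining[i] for i in chain]
        remaining = [i for i in remaining if i not in set(chosen)]
        if len(chosen) >= match_size:
            out.append(
                (orientation, frozenset((rows[i][0], rows[i][1]) for i in chosen))
            )
    return out
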