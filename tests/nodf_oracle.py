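"""Brute-force NODF oracle: explicit all-pairs enumeration in pure python,
independent of the vectorised implementation it cross-checks."""


def _pair_contribution(u, v):
    fill_u, fill_v = sum(u), sum(v)
    if fill_u == fill_v or min(fill_u, fill_v) == 0:
        return 0.0
    if fill_v > fill_u:
        u, v, fill_v = v, u, fill_u
    overlap = sum(1 for a, b in zip(u, v) if a and b)
    return 100.0 * overlap / fill_v


def nodf_oracle(matrix):
    rows = [list(map(int, r)) for r in matrix]
    m, n = len(rows), len(rows[0])
    cols = [[rows[i][j] for i in range(m)] for j in range(n)]
    contributions = []
    for axis in (rows, cols):
        for i in range(len(axis)):
            for j in range(i + 1, len(axis)):
                contributions.append(_pair_contribution(axis[i], axis[j]))
    return sum(contributions) / len(contributions)


def is_degenerate(matrix):
    """True when fewer than 2 rows or 2 columns carry any links."""
    rows = [list(map(int, r)) for r in matrix]
    m, n = len(rows), len(rows[0])
    nonempty_rows = sum(1 for r in rows if sum(r) > 0)
    nonempty_cols = sum(1 for j in range(n) if sum(rows[i][j] for i in range(m)) > 0)
    return nonempty_rows < 2 or nonempty_cols < 2
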