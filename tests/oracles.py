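"""Independent brute-force oracles used to cross-check the scanners.

Everything here is a deliberately naive per-offset (or per-element)
re-computation with no code shared with the package implementation.
"""

from __future__ import annotations

from itertools import groupby


def oracle_consensus(seq: str, positions) -> list[int]:
    """Per-offset sliding-window check of a degenerate consensus."""
    w = len(positions)
    out = []
    for i in range(len(seq) - w + 1):
        if all(seq[i + j] in positions[j] for j in range(w)):
            out.append(i)
    return out


def oracle_pwm(seq: str, matrix, threshold: float) -> list[int]:
    """Per-offset summed score; any non-ACGT base disqualifies the offset."""
    order = "ACGT"
    w = len(matrix)
    out = []
    for i in range(len(seq) - w + 1):
        score = 0.0
        ok = True
        for j in range(w):
            c = seq[i + j]
            if c not in order:
                ok = False
                break
            score += matrix[j][order.index(c)]
        if ok and score >= threshold:
            out.append(i)
    return out


def oracle_cu_runs(seq: str, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal C/T runs via itertools.groupby."""
    out = []
    pos = 0
    for is_py, grp in groupby(seq, key=lambda c: c in "CT"):
        n = len(list(grp))
        if is_py and n >= min_len:
            out.append((pos, n))
        pos += n
    return out


def oracle_quantile(values, q: float) -> float:
    """Linear-interpolation quantile computed by hand (type-7)."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    h = (len(xs) - 1) * q
    lo = int(h)
    if lo == len(xs) - 1:
        return float(xs[lo])
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])
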