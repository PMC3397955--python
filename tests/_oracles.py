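"""Independent brute-force oracles used to validate the package implementations.

Everything here is deliberately written from first principles (divisor checks,
pair enumeration, exhaustive rotation sets) and stays independent of the code
paths it arbitrates.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(m: str) -> str:
    return "".join(_RC[c] for c in reversed(m))


def oracle_is_primitive(m: str) -> bool:
    """Divisor-based primitivity: no proper divisor-length prefix tiles m."""
    for d in range(1, len(m)):
        if len(m) % d == 0 and m == m[:d] * (len(m) // d):
            return False
    return True


def oracle_canonical(m: str) -> str:
    """Minimum over all rotations of m and of its reverse complement."""
    candidates = set()
    for s in (m, oracle_revcomp(m)):
        for i in range(len(s)):
            candidates.add(s[i:] + s[:i])
    return min(candidates)


def oracle_classes(k: int) -> set[str]:
    """Equivalence classes of primitive k-mers via explicit closure grouping."""
    from itertools import product

    seen: set[str] = set()
    classes: set[str] = set()
    for tup in product("ACGT", repeat=k):
        m = "".join(tup)
        if m in seen or not oracle_is_primitive(m):
            continue
        members = set()
        for s in (m, oracle_revcomp(m)):
            for i in range(k):
                members.add(s[i:] + s[:i])
        seen |= members
        classes.add(min(members))
    return classes


def oracle_scan(
    seq_id: str,
    seq: str,
    min_repetitions: dict[int, int] | None = None,
    count_partial: bool = True,
) -> list[tuple]:
    """Enumerate every maximal perfect period-u substring and filter.

    Returns tuples (seq_id, start, end, unit_length, canonical_motif,
    n_full_units) sorted by (start, unit_length).
    """
    if min_repetitions is None:
        min_repetitions = {1: 12, 2: 5, 3: 5, 4: 5, 5: 5, 6: 5}
    seq = seq.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    out = []
    for u in range(1, 7):
        for i in range(n - u):
            # left-maximality: cannot extend one base left with period u
            if i > 0 and valid[i - 1] and seq[i - 1] == seq[i - 1 + u]:
                continue
            if not all(valid[i : i + u + 1]):
                continue
            if seq[i] != seq[i + u]:
                continue
            j = i + u + 1
            while j < n and valid[j] and seq[j] == seq[j - u]:
                j += 1
            unit = seq[i : i + u]
            if not oracle_is_primitive(unit):
                continue
            full = (j - i) // u
            if full < min_repetitions[u]:
                continue
            end = j if count_partial else i + full * u
            out.append((seq_id, i, end, u, oracle_canonical(unit), full))
    out.sort(key=lambda t: (t[1], t[3]))
    return out


def oracle_rank_sum_w(x, y) -> float:
    """W by pair enumeration: wins plus half-ties for the first sample."""
    w = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                w += 1.0
            elif xi == yj:
                w += 0.5
    return w


def oracle_midranks(values) -> list[float]:
    """Average-rank (mid-rank) assignment computed by sorting copies."""
    order = sorted(values)
    ranks = []
    for v in values:
        lo = order.index(v) + 1
        hi = lo + order.count(v) - 1
        ranks.append((lo + hi) / 2.0)
    return ranks


def oracle_spearman(x, y) -> float:
    rx = np.array(oracle_midranks(list(x)))
    ry = np.array(oracle_midranks(list(y)))
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_moran_permutation_mean(x, w) -> float:
    """Exact mean of I over all value permutations (small n only)."""
    x = list(x)
    total, count = 0.0, 0
    for perm in permutations(x):
        total += _plain_moran(np.array(perm, dtype=float), w)
        count += 1
    return total / count


def _plain_moran(x: np.ndarray, w: np.ndarray) -> float:
    z = x - x.mean()
    return (x.size / w.sum()) * float(z @ w @ z) / float(z @ z)


def oracle_moran_permutation_p(x, w, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p for Moran's I (distance from E = -1/(n-1))."""
    x = np.asarray(x, dtype=float)
    n = x.size
    expected = -1.0 / (n - 1)
    obs = abs(_plain_moran(x, w) - expected)
    hits = 1  # include the observed arrangement
    for _ in range(n_perm):
        perm = rng.permutation(x)
        if abs(_plain_moran(perm, w) - expected) >= obs - 1e-12:
            hits += 1
    return hits / (n_perm + 1)
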