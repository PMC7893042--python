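"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from its definition by a different
route (exhaustive scan, set algebra, union-find closure, count-based formula)
and never call the code paths they check.
"""

from __future__ import annotations

from typing import Mapping, Sequence


def mh_from_counts(xa: Mapping[str, int], xb: Mapping[str, int]) -> float:
    """Count-based Morisita-Horn: 2*sum(x_i*y_i)/((sum x_i^2/X^2 + sum y_i^2/Y^2)*X*Y)."""
    total_a = sum(xa.values())
    total_b = sum(xb.values())
    cross = sum(x * xb.get(k, 0) for k, x in xa.items())
    da = sum(x * x for x in xa.values()) / (total_a * total_a)
    db = sum(y * y for y in xb.values()) / (total_b * total_b)
    return 2.0 * cross / ((da + db) * total_a * total_b)


def scan_tpm_filter(tpms_keyed: Sequence[tuple[float, tuple]],
                    h: float) -> list[tuple[float, tuple]]:
    """Exhaustive scan over prefix sizes M for the minimal one meeting the
    cumulative-TPM inequality."""
    ordered = sorted(tpms_keyed, key=lambda tk: (-tk[0], tk[1]))
    total = sum(t for t, _ in ordered)
    if total == 0:
        return ordered
    for m in range(1, len(ordered) + 1):
        if sum(t for t, _ in ordered[:m]) >= h * total - 1e-12 * total:
            return ordered[:m]
    return ordered


def scan_top_fraction(counts: Sequence[tuple[str, int]], fraction: float) -> int:
    """Exhaustive scan over m for the minimal prefix reaching the target mass."""
    ordered = sorted(counts, key=lambda kc: (-kc[1], kc[0]))
    total = sum(c for _, c in ordered)
    for m in range(1, len(ordered) + 1):
        if sum(c for _, c in ordered[:m]) >= fraction * total - 1e-9 * total:
            return m
    raise AssertionError("unreachable")


def _brute_filtered_sets(cell, h):
    """The F_h filter re-derived by prefix scan on each locus."""
    out = []
    for chains in (cell.alpha, cell.beta):
        keyed = [(c.tpm, c.identity_key) for c in chains]
        out.append(frozenset(k for _, k in scan_tpm_filter(keyed, h)))
    return tuple(out)  # (alpha_keys, beta_keys)


def _brute_equivalent(sets_a, sets_b, relation) -> bool:
    (a1, b1), (a2, b2) = sets_a, sets_b
    if relation == 1:
        return bool(a1) and bool(a2) and a1 == a2
    if relation == 2:
        return bool(b1) and bool(b2) and b1 == b2
    if relation == 3:
        u1, u2 = a1 | b1, a2 | b2
        return bool(u1) and bool(u2) and u1 == u2
    return (bool(a1) and bool(b1) and bool(a2) and bool(b2)
            and a1 == a2 and b1 == b2)


def brute_cluster(cells, relation, h=0.95, max_alpha=2, max_beta=2):
    """O(n^2) pairwise equivalence + union-find transitive closure.

    Returns (partition, excluded_ids) where the partition is a set of
    frozensets of cell ids over the eligible cells.
    """
    eligible = []
    excluded = []
    for cell in cells:
        alpha, beta = _brute_filtered_sets(cell, h)
        if len(alpha) > max_alpha or len(beta) > max_beta:
            excluded.append(cell.cell_id)
            continue
        needs = {1: bool(alpha), 2: bool(beta), 3: bool(alpha | beta),
                 4: bool(alpha) and bool(beta)}[relation]
        if not needs:
            excluded.append(cell.cell_id)
            continue
        eligible.append((cell.cell_id, (alpha, beta)))

    parent = {cid: cid for cid, _ in eligible}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (ca, sets_a) in enumerate(eligible):
        for cb, sets_b in eligible[i + 1:]:
            if _brute_equivalent(sets_a, sets_b, relation):
                parent[find(ca)] = find(cb)

    groups: dict[str, set[str]] = {}
    for cid, _ in eligible:
        groups.setdefault(find(cid), set()).add(cid)
    return {frozenset(g) for g in groups.values()}, set(excluded)


def bisect_binomial_upper(k: int, n: int, tail: float,
                          tol: float = 1e-13) -> float:
    """Upper exact binomial confidence limit by bisection on the lower-tail
    probability P(X <= k; p) = tail, using only the binomial pmf."""
    from math import comb

    def lower_tail(p: float) -> float:
        return sum(comb(n, j) * p**j * (1 - p)**(n - j) for j in range(k + 1))

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if lower_tail(mid) > tail:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
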