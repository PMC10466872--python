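"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic by direct enumeration, independently of
the package's implementation path.
"""

from __future__ import annotations

from itertools import combinations

from scipy.stats import hypergeom


def fisher_two_sided_enumerated(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums, over every table with the same margins, the probabilities that do
    not exceed the observed table's (with a 1e-7 relative slack for float
    ties, the conventional treatment).
    """
    total = n1 + n2
    carriers = a + b
    support = range(max(0, carriers - n2), min(carriers, n1) + 1)
    pmf = {k: hypergeom.pmf(k, total, carriers, n1) for k in support}
    observed = pmf[a]
    return float(sum(p for p in pmf.values() if p <= observed * (1 + 1e-7)))


# --- ACMG combining, literal clause transcription -----------------------------

_PATHOGENIC_CLAUSES = [
    lambda vs, s, m, p: vs and s >= 1,
    lambda vs, s, m, p: vs and m >= 2,
    lambda vs, s, m, p: vs and m >= 1 and p >= 1,
    lambda vs, s, m, p: vs and p >= 2,
    lambda vs, s, m, p: s >= 2,
    lambda vs, s, m, p: s >= 1 and m >= 3,
    lambda vs, s, m, p: s >= 1 and m >= 2 and p >= 2,
    lambda vs, s, m, p: s >= 1 and m >= 1 and p >= 4,
]

_LIKELY_CLAUSES = [
    lambda vs, s, m, p: vs and m >= 1,
    lambda vs, s, m, p: s >= 1 and 1 <= m <= 2,
    lambda vs, s, m, p: s >= 1 and p >= 2,
    lambda vs, s, m, p: m >= 3,
    lambda vs, s, m, p: m >= 2 and p >= 2,
    lambda vs, s, m, p: m >= 1 and p >= 4,
]


def combine_acmg_enumerated(codes) -> str:
    """Category by testing every clause of the combining table literally."""
    names = {c if isinstance(c, str) else c.value for c in codes}
    vs = "PVS1" in names
    s = sum(1 for c in names if c.startswith("PS"))
    m = sum(1 for c in names if c.startswith("PM"))
    p = sum(1 for c in names if c.startswith("PP"))
    if any(clause(vs, s, m, p) for clause in _PATHOGENIC_CLAUSES):
        return "pathogenic"
    if any(clause(vs, s, m, p) for clause in _LIKELY_CLAUSES):
        return "likely_pathogenic"
    return "vus"


def rank_sum_two_sided_enumerated(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments and
    counting pairwise wins (ties count one half)."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)

    def u_stat(group):
        rest = [pooled[i] for i in range(n) if i not in group]
        vals = [pooled[i] for i in group]
        return sum(
            (1.0 if xi > yj else 0.5 if xi == yj else 0.0)
            for xi in vals
            for yj in rest
        )

    u_obs = u_stat(tuple(range(n1)))
    us = [u_stat(idx) for idx in combinations(range(n), n1)]
    eps = 1e-9
    p_le = sum(1 for u in us if u <= u_obs + eps) / len(us)
    p_ge = sum(1 for u in us if u >= u_obs - eps) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))
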