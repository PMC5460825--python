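"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own scanning/probability code
paths: motif matching goes through the ``re`` module, and negative-
binomial probabilities are computed with ``math.lgamma`` in pure Python.
"""

from __future__ import annotations

import math
import re

IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def revcomp_pattern(pattern: str) -> str:
    return "".join(_COMP[c] for c in reversed(pattern))


def regex_hits(seq: str, patterns) -> set[tuple[int, int, str]]:
    """(start, end, strand) hit set, palindromic duplicates collapsed to +.

    Uppercase-only character classes, so lowercase (masked) bases never
    match — mirroring the scanner's masking convention.
    """
    hits: set[tuple[int, int, str]] = set()
    for pat in patterns:
        L = len(pat)
        fwd = re.compile("(?=" + "".join(IUPAC_RE[c] for c in pat) + ")")
        rev = re.compile("(?=" + "".join(
            IUPAC_RE[c] for c in revcomp_pattern(pat)) + ")")
        fwd_starts = {m.start() for m in fwd.finditer(seq)}
        rev_starts = {m.start() for m in rev.finditer(seq)}
        for s in fwd_starts:
            hits.add((s, s + L, "+"))
        for s in rev_starts - fwd_starts:
            hits.add((s, s + L, "-"))
    return hits


def _log_nb_pmf(k: int, mu: float, var: float) -> float:
    """log pmf of NB given mean/variance; Poisson when var <= mu."""
    if var <= mu * (1 + 1e-12):
        return k * math.log(mu) - mu - math.lgamma(k + 1) if mu > 0 else \
            (0.0 if k == 0 else -math.inf)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return (math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(p) + k * math.log(1 - p))


def exact_test_oracle(k_a: int, k_b: int, sum_sa: float, sum_sb: float,
                      alpha: float, sum_sa2: float, sum_sb2: float,
                      mid_p: bool = True) -> float:
    """Exhaustive-enumeration conditional NB test p-value.

    Mirrors the mid-p definition: splits exactly as likely as the
    observed one (to 1e-9 relative tolerance) contribute half their mass.
    """
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0
    q0 = k_s / (sum_sa + sum_sb)
    mu_a, mu_b = q0 * sum_sa, q0 * sum_sb
    var_a = mu_a + alpha * q0 * q0 * sum_sa2
    var_b = mu_b + alpha * q0 * q0 * sum_sb2
    probs = [math.exp(_log_nb_pmf(a, mu_a, var_a)
                      + _log_nb_pmf(k_s - a, mu_b, var_b))
             for a in range(k_s + 1)]
    total = sum(probs)
    observed = probs[k_a]
    tol = 1e-9 * observed
    below = sum(p for p in probs if p < observed - tol)
    equal = sum(p for p in probs if abs(p - observed) <= tol)
    mass = below + (0.5 * equal if mid_p else equal)
    return min(1.0, mass / total)
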