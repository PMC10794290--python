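"""Independent brute-force oracles used to freeze expected values.

Everything here is exact rational (or high-precision) arithmetic in the
linear domain, deliberately sharing no code with the log-space
implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Iterator


def compositions(k: int) -> Iterator[tuple[int, int, int, int]]:
    """All (R, M, X1, X2) with R+M+X1+X2 = k and M >= X1 >= X2."""
    for r in range(k + 1):
        rest = k - r
        for m in range(rest + 1):
            for x1 in range(min(m, rest - m) + 1):
                x2 = rest - m - x1
                if x2 <= x1:
                    yield (r, m, x1, x2)


def all_compositions(k: int) -> Iterator[tuple[int, int, int, int]]:
    """All ordered (R, M, X1, X2) with R+M+X1+X2 = k (no ordering constraint)."""
    for r in range(k + 1):
        for m in range(k - r + 1):
            for x1 in range(k - r - m + 1):
                yield (r, m, x1, k - r - m - x1)


def multinomial_coef(k: int, r: int, m: int, x1: int, x2: int) -> int:
    return math.factorial(k) // (
        math.factorial(r) * math.factorial(m) * math.factorial(x1) * math.factorial(x2)
    )


def rational_null_likelihood(r: int, m: int, x1: int, x2: int, e: Fraction) -> Fraction:
    k = r + m + x1 + x2
    return multinomial_coef(k, r, m, x1, x2) * (1 - e) ** r * (e / 3) ** (k - r)


def rational_alt_likelihood_at_theta(r: int, m: int, x1: int, x2: int,
                                     e: Fraction, theta: Fraction) -> Fraction:
    k = r + m + x1 + x2
    p_r = theta * e / 3 + (1 - theta) * (1 - e)
    p_m = theta * (1 - e) + (1 - theta) * e / 3
    return multinomial_coef(k, r, m, x1, x2) * p_r**r * p_m**m * (e / 3) ** (x1 + x2)


def rational_alt_likelihood_mixture(r: int, m: int, x1: int, x2: int,
                                    e: Fraction, atoms: Iterable[Fraction]) -> Fraction:
    atoms = list(atoms)
    return sum(rational_alt_likelihood_at_theta(r, m, x1, x2, e, t) for t in atoms) / len(atoms)


def rational_lfdr(p0: Fraction, p1: Fraction, pi0: Fraction) -> Fraction:
    num = pi0 * p0
    den = pi0 * p0 + (1 - pi0) * p1
    return num / den


def log_of_fraction(f: Fraction) -> float:
    """Natural log of a positive rational, exact up to float rounding even
    when the rational itself over/underflows a double."""
    if f <= 0:
        return -math.inf
    return math.log(f.numerator) - math.log(f.denominator)


def posterior_expected_loss(delta, psi, l_i: float, l_ii: float) -> float:
    """Sum_i [delta_i * l_I * psi_i + (1-delta_i) * l_II * (1-psi_i)]."""
    return sum(
        (l_i * p if d else l_ii * (1.0 - p)) for d, p in zip(delta, psi)
    )


def best_decision_by_enumeration(psi, l_i: float, l_ii: float) -> float:
    """Minimum posterior expected loss over all 2^p decision vectors."""
    p = len(psi)
    best = math.inf
    for mask in range(1 << p):
        delta = [(mask >> i) & 1 for i in range(p)]
        best = min(best, posterior_expected_loss(delta, psi, l_i, l_ii))
    return best
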