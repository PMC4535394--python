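"""Independent brute-force oracles in exact rational arithmetic.

These deliberately share no code with the package: probabilities and
likelihood ratios are exact ``Fraction`` values, so ordering comparisons
and tail sums carry no floating-point error.
"""

import math
from fractions import Fraction

from simon2stage import SimonDesign
from simon2stage.design import support_paths


def frac_pmf(d: SimonDesign, n2a: int, m: int, s: int, p: Fraction) -> Fraction:
    if m == 1:
        return math.comb(d.n1, s) * p**s * (1 - p) ** (d.n1 - s)
    total = Fraction(0)
    for x1 in range(max(d.r1 + 1, s - n2a), min(s, d.n1) + 1):
        total += math.comb(d.n1, x1) * math.comb(n2a, s - x1)
    return total * p**s * (1 - p) ** (d.n1 + n2a - s)


def frac_lr(s: int, n: int, p0: Fraction) -> Fraction:
    ph = Fraction(s, n)
    num = ph**s * (1 - ph) ** (n - s)
    den = p0**s * (1 - p0) ** (n - s)
    return num / den


def midp_oracle(d: SimonDesign, n2a: int, m: int, s: int, p0: Fraction) -> Fraction:
    """Mid-p value of path (m, s): strictly-larger-LR mass plus half its own."""
    n_obs = d.n1 if m == 1 else d.n1 + n2a
    t_obs = frac_lr(s, n_obs, p0)
    total = Fraction(0)
    for mm, ss in support_paths(d, n2a):
        nn = d.n1 if mm == 1 else d.n1 + n2a
        f = frac_pmf(d, n2a, mm, ss, p0)
        if (mm, ss) == (m, s):
            total += Fraction(1, 2) * f
        elif frac_lr(ss, nn, p0) > t_obs:
            total += f
    return total
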