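"""Independent brute-force oracles used only by the tests."""

import math

from scipy.integrate import quad


def t_pvalue_numeric(values) -> float:
    """Two-sided one-sample t p-value against 0 from first principles.

    The t statistic is computed with the textbook formula and its tail
    probability by numeric integration of the explicit Student-t density
    (gamma-function normalization), independent of any distribution
    implementation in the package's code path.
    """
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    t = mean / (math.sqrt(var) / math.sqrt(n))
    df = n - 1
    norm = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(u: float) -> float:
        return norm * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t), math.inf, epsabs=1e-13, epsrel=1e-12)
    return 2.0 * tail


def legend_group(cs_b, p_b, cs_a, p_a, alpha=0.05) -> int:
    """Nine-group rules transcribed literally, one clause per group.

    A score of exactly 0 carries no direction, so it can satisfy neither a
    '>0' nor a '<0' clause and falls into the not-significant row/column.
    """
    b_up = p_b < alpha and cs_b > 0
    b_down = p_b < alpha and cs_b < 0
    a_up = p_a < alpha and cs_a > 0
    a_down = p_a < alpha and cs_a < 0
    b_ns = not (b_up or b_down)
    a_ns = not (a_up or a_down)
    if b_up and a_down:
        return 1
    if b_up and a_ns:
        return 2
    if b_up and a_up:
        return 3
    if b_ns and a_down:
        return 4
    if b_ns and a_ns:
        return 5
    if b_ns and a_up:
        return 6
    if b_down and a_down:
        return 7
    if b_down and a_ns:
        return 8
    if b_down and a_up:
        return 9
    raise AssertionError("unreachable")
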