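"""Independent brute-force oracles, kept free of the implementation under test.

The ICC oracle computes the two-way ANOVA mean squares with explicit
double-loop sums of squares and applies the absolute-agreement
single-measure formula directly; it shares no code with
``hragree.agreement``.
"""

from __future__ import annotations


def icc_a1_bruteforce(table: list[list[float]]) -> float:
    """ICC(A,1) from explicit loops over an n-subjects x k-raters table."""
    n = len(table)
    k = len(table[0])
    total = 0.0
    count = 0
    for row in table:
        assert len(row) == k
        for x in row:
            total += x
            count += 1
    grand = total / count

    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]

    ss_rows = 0.0
    for rm in row_means:
        ss_rows += k * (rm - grand) ** 2
    ss_cols = 0.0
    for cm in col_means:
        ss_cols += n * (cm - grand) ** 2
    ss_total = 0.0
    for row in table:
        for x in row:
            ss_total += (x - grand) ** 2
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def mean_and_sd(values: list[float]) -> tuple[float, float]:
    """Plain-arithmetic mean and sample SD for hand-checked fixtures."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var**0.5
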