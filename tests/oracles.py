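"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and the special functions)
used by the package: the conditional pmf is built by a product
recurrence, the hypergeometric tail by exact integer combinatorics,
and the site scan by an explicit base-by-base window comparison.
"""

from __future__ import annotations

import math

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def conditional_pmf_oracle(t: int, n_a: int, n_b: int, phi: float) -> list[float]:
    """P(group-A sum = s | total = t) by a product recurrence."""
    if phi == 0.0:
        p = n_a / (n_a + n_b)
        ratio = lambda s: (t - s) / (s + 1) * p / (1 - p)  # noqa: E731
    else:
        r1, r2 = n_a / phi, n_b / phi
        ratio = lambda s: (s + r1) / (s + 1) * (t - s) / (t - s - 1 + r2)  # noqa: E731
    w = [1.0]
    for s in range(t):
        w.append(w[-1] * ratio(s))
    total = math.fsum(w)
    return [x / total for x in w]


def exact_test_oracle(counts_a, counts_b, phi: float) -> float:
    """Two-sided minimum-likelihood exact p by full enumeration."""
    sa, sb = sum(counts_a), sum(counts_b)
    t = sa + sb
    if t == 0:
        return 1.0
    pmf = conditional_pmf_oracle(t, len(counts_a), len(counts_b), phi)
    obs = pmf[sa]
    return min(1.0, math.fsum(p for p in pmf if p <= obs * (1 + 1e-12)))


def site_scan_oracle(mirna_seq: str, target_seq: str, circular: bool):
    """Exhaustive window scan: every target position checked base by
    base against miRNA positions 2-7 (+8 / A1 extensions)."""
    scan = target_seq + target_seq[:7] if circular else target_seq
    limit = len(target_seq) if circular else len(scan)
    sites = []
    for i in range(min(limit, len(scan) - 5)):
        window = scan[i:i + 6]
        # window position i+k pairs miRNA position 7-k (1-based)
        if all(COMP[window[k]] == mirna_seq[6 - k] for k in range(6)):
            has_m8 = i > 0 and COMP[scan[i - 1]] == mirna_seq[7]
            has_a1 = i + 6 < len(scan) and scan[i + 6] == "A"
            kind = ("8mer" if has_m8 and has_a1 else
                    "7mer-m8" if has_m8 else
                    "7mer-A1" if has_a1 else "6mer")
            sites.append((i, kind))
    return sites


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) by exact integer combinatorics."""
    denom = math.comb(N, n)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(K, n) + 1))
    return num / denom
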