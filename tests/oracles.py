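"""Independent reference implementations used only for cross-checking.

These deliberately take different routes from the package: the speciation
oracle uses a different set of published zero-salinity constants
(Harned & Davis 1943 K1, Harned & Scholes 1941 K2, Weiss 1974 K0) and a
DIC-based formulation; the Strahler oracle is a plain recursive descent.
"""

from __future__ import annotations

import math
import sys
from collections import defaultdict


def oracle_pco2(pH: float, alkalinity_ueq_L: float, temp_C: float) -> float:
    """pCO2 (uatm) via DIC speciation fractions with independent constants."""
    T = temp_C + 273.15
    K1 = 10.0 ** (-3404.71 / T + 14.8435 - 0.032786 * T)  # Harned & Davis (1943)
    K2 = 10.0 ** (-2902.39 / T + 6.4980 - 0.02379 * T)  # Harned & Scholes (1941)
    ln_K0 = -58.0931 + 90.5069 * (100.0 / T) + 22.2940 * math.log(T / 100.0)  # Weiss (1974), S=0
    K0 = math.exp(ln_K0)
    pKw = 4470.99 / T - 6.0875 + 0.01706 * T  # Harned & Owen fit
    Kw = 10.0**-pKw

    h = 10.0**-pH
    denom = 1.0 + K1 / h + K1 * K2 / h**2
    a0 = 1.0 / denom
    a1 = (K1 / h) / denom
    a2 = (K1 * K2 / h**2) / denom
    ca = alkalinity_ueq_L * 1e-6
    dic = (ca - Kw / h + h) / (a1 + 2.0 * a2)
    if dic <= 0:
        raise ValueError("alkalinity inconsistent with pH")
    return dic * a0 / K0 * 1e6


def oracle_strahler(edges: dict[str, str | None]) -> dict[str, int]:
    """Recursive Strahler ordering (brute force)."""
    ups: dict[str, list[str]] = defaultdict(list)
    for seg, down in edges.items():
        if down is not None:
            ups[down].append(seg)
    sys.setrecursionlimit(max(10_000, len(edges) * 4))

    def order(seg: str) -> int:
        children = [order(u) for u in ups[seg]]
        if not children:
            return 1
        m = max(children)
        return m + 1 if children.count(m) >= 2 else m

    return {seg: order(seg) for seg in edges}


def random_tree(rng, n: int) -> dict[str, str | None]:
    """Random forest-toward-outlet: node i drains to a random earlier node."""
    edges: dict[str, str | None] = {"n0": None}
    for i in range(1, n):
        edges[f"n{i}"] = f"n{int(rng.integers(0, i))}"
    return edges
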