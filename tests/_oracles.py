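"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive -- per-base set arithmetic, quadratic
double loops, exhaustive ECDF sweeps -- and shares no code with the package
implementations it verifies.
"""

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


def overlap_bases(a_start: int, a_end: int, b_start: int, b_end: int,
                  same_chrom: bool = True) -> int:
    """Per-base set intersection of two half-open spans."""
    if not same_chrom:
        return 0
    return len(set(range(a_start, a_end)) & set(range(b_start, b_end)))


def count_overlapping_pairs(
    elements: Sequence[Tuple[str, int, int]],
    peaks: Sequence[Tuple[str, int, int]],
    min_overlap: int = 1,
) -> List[int]:
    """All-pairs double-loop peak counting per element."""
    counts = []
    for ec, es, ee in elements:
        n = 0
        for pc, ps, pe in peaks:
            if ec == pc and min(ee, pe) - max(es, ps) >= min_overlap:
                n += 1
        counts.append(n)
    return counts


def chain_base_map(blocks: Sequence[Tuple[int, int, int]],
                   source_start: int, target_start: int) -> Dict[int, int]:
    """Walk a chain block list into an explicit source-base -> target-base map."""
    out: Dict[int, int] = {}
    s, t = source_start, target_start
    for size, ds, dt in blocks:
        for k in range(size):
            out[s + k] = t + k
        s += size + ds
        t += size + dt
    return out


def liftover_span(
    base_map: Dict[int, int],
    q_start: int,
    q_end: int,
    min_match: float,
    target_strand: str = "+",
    target_size: int = 0,
) -> Optional[Tuple[int, int]]:
    """Per-base lift of a query through one chain's base map."""
    mapped = [base_map[x] for x in range(q_start, q_end) if x in base_map]
    if not mapped or len(mapped) / (q_end - q_start) < min_match:
        return None
    lo, hi = min(mapped), max(mapped) + 1
    if target_strand == "-":
        lo, hi = target_size - hi, target_size - lo
    return lo, hi


def per_base_mean(
    track: Sequence[Tuple[int, int, float]],
    e_start: int,
    e_end: int,
    policy: str,
) -> float:
    """Per-base averaging over an element, with zero or exclude missing policy."""
    values: Dict[int, float] = {}
    for s, e, v in track:
        for x in range(s, e):
            values[x] = v
    acc = []
    for x in range(e_start, e_end):
        if x in values:
            acc.append(values[x])
        elif policy == "zero":
            acc.append(0.0)
    if not acc:
        return float("nan")
    return float(np.mean(acc))


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """sup |ECDF_A - ECDF_B| evaluated over every sample point."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        d = abs(np.mean(a <= x) - np.mean(b <= x))
        best = max(best, d)
    return best


def binomial_envelope(p: float, n: int, alpha: float = 0.01) -> Tuple[float, float]:
    """Central (1 - alpha) interval of Binomial(n, p) as fractions."""
    from scipy import stats

    lo = stats.binom.ppf(alpha / 2, n, p) / n
    hi = stats.binom.ppf(1 - alpha / 2, n, p) / n
    return float(lo), float(hi)
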