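"""Independent brute-force oracles, written separately from the package.

These deliberately use naive string scans, literal draw enumeration, and
exact rational arithmetic so that agreement with the package's vectorised /
log-space implementations is meaningful.
"""

from fractions import Fraction
from itertools import combinations, product
from math import comb


def brute_met_in_window(sequence: str, position: int, half_width: int,
                        discount_nterm: bool = True) -> bool:
    """Literal scan of sequence[position-k .. position+k] for Met."""
    for p in range(position - half_width, position + half_width + 1):
        if p == position or p < 1 or p > len(sequence):
            continue
        if sequence[p - 1] == "M":
            if discount_nterm and p == 1:
                continue
            return True
    return False


def brute_composition(sequences: list[str], discount_nterm: bool = True):
    """Letter counts over the 20 standard residues by direct scan."""
    counts: dict[str, int] = {}
    for seq in sequences:
        body = seq[1:] if discount_nterm and seq.startswith("M") else seq
        for aa in body:
            if aa in "ACDEFGHIKLMNPQRSTVWY":
                counts[aa] = counts.get(aa, 0) + 1
    return counts


def brute_positional_counts(sequences_by_id: dict[str, str],
                            sites: list[tuple[str, int]], residue_class: str,
                            half_width: int, discount_nterm: bool = True):
    """(counts, denominators) per offset by direct scan."""
    offsets = [d for d in range(-half_width, half_width + 1) if d != 0]
    counts = {d: 0 for d in offsets}
    denoms = {d: 0 for d in offsets}
    for pid, pos in sites:
        seq = sequences_by_id[pid]
        for d in offsets:
            p = pos + d
            if p < 1 or p > len(seq):
                continue
            denoms[d] += 1
            aa = seq[p - 1]
            if aa in residue_class:
                if aa == "M" and discount_nterm and p == 1:
                    continue
                counts[d] += 1
    return counts, denoms


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] as an exact rational via the counting formula."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


def hypergeom_upper_by_draws(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] by literally enumerating every size-n draw from N items."""
    annotated = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(annotated.intersection(draw)) >= k)
    return Fraction(hits, comb(N, n))


def ptm_states_by_enumeration(n_sites: int, n_ptm_types: int) -> int:
    """Count distinct site-state assignments by generating all of them."""
    states = range(n_ptm_types + 1)  # 0 = unmodified
    return len(set(product(states, repeat=n_sites)))
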