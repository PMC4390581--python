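"""Independent reference implementations used to check the package.

These are deliberately written from first principles (naive sliding
windows, exact rational arithmetic) and share no code with the package
internals they validate.
"""

from fractions import Fraction
from math import comb

# Independently transcribed IUPAC table (do not import from the package).
IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _window_matches(window: str, consensus: str) -> bool:
    for base, letter in zip(window, consensus):
        allowed = IUPAC_ORACLE[letter]
        if letter == "N":
            allowed += "N"  # subject N only ever matches a motif-side N
        if base not in allowed:
            return False
    return True


def brute_force_scan(seq: str, consensus: str, strands: str = "both"):
    """Test every window of seq (and of its reverse complement, mapped back
    to forward coordinates) against the consensus."""
    length = len(consensus)
    hits = []
    if strands in ("forward", "both"):
        for i in range(len(seq) - length + 1):
            if _window_matches(seq[i : i + length], consensus):
                hits.append((i, "+", seq[i : i + length]))
    if strands in ("reverse", "both"):
        rc = revcomp_oracle(seq)
        for j in range(len(rc) - length + 1):
            if _window_matches(rc[j : j + length], consensus):
                i = len(seq) - length - j
                hits.append((i, "-", seq[i : i + length]))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def hypergeom_pmf_oracle(k: int, total: int, successes: int, draws: int) -> Fraction:
    return Fraction(
        comb(successes, k) * comb(total - successes, draws - k),
        comb(total, draws),
    )


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Full hypergeometric enumeration with exact rational arithmetic;
    two-sided by summing every table no more probable than the observed."""
    total = a + b + c + d
    row = a + b
    col = a + c
    if row == 0 or col == 0 or row == total or col == total:
        return Fraction(1)
    p_obs = hypergeom_pmf_oracle(a, total, col, row)
    lo = max(0, row - (total - col))
    hi = min(col, row)
    return sum(
        (p for k in range(lo, hi + 1)
         if (p := hypergeom_pmf_oracle(k, total, col, row)) <= p_obs),
        Fraction(0),
    )
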