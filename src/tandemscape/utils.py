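"""Small shared helpers: percentage formatting, sequence utilities, RNG derivation."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_DNA_RE = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Upper-case *seq* and reject anything outside the ACGTN alphabet."""
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    s = seq.upper()
    if not _DNA_RE.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"{name}: non-ACGTN symbols {bad}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pct_half_up(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage ``100 * n / d`` rounded half-up to *ndigits* decimals.

    Returns 0.0 for an empty denominator so degenerate summaries stay well defined.
    """
    numerator, denominator = float(numerator), float(denominator)
    if denominator == 0:
        return 0.0
    frac = Decimal(repr(numerator)) * 100 / Decimal(repr(denominator))
    q = Decimal(1).scaleb(-ndigits)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def mean_pct(values, ndigits: int = 2) -> float:
    """Unweighted mean of per-genotype percentages, rounded half-up."""
    vals = list(values)
    if not vals:
        return 0.0
    return round_half_up(sum(vals) / len(vals), ndigits)


def derive_seed(seed: int, *salt: int) -> int:
    """Deterministically derive a sub-seed below 2**31 from *seed* and salt integers."""
    ss = np.random.SeedSequence([int(seed) % (2**31), *[int(s) % (2**31) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))
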