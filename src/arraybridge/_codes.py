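"""Integer genotype-call codes shared across the package.

Calls are held as int8 arrays.  Visible codes are what a calling algorithm
emits (AA/AB/BB/missing); null-aware codes (AN, BN, NN) extend them after
null-allele curation.  ``NN`` here always means the double-null genotype,
serialized as ``NN*`` so it can never be confused with a plain call token.
"""
from __future__ import annotations

import numpy as np

MISSING: int = -1
AA: int = 0
AB: int = 1
BB: int = 2
AN: int = 3
BN: int = 4
NN: int = 5

VISIBLE_CODES = (AA, AB, BB)
NULL_CODES = (AN, BN, NN)
ALL_CODES = (MISSING, AA, AB, BB, AN, BN, NN)

CODE_TO_STR = {MISSING: "NC", AA: "AA", AB: "AB", BB: "BB",
               AN: "AN", BN: "BN", NN: "NN*"}

# tokens accepted on read; dialects may extend the missing synonyms
DEFAULT_MISSING_TOKENS = ("NC", "--", "---", "NoCall", "NN", "")
_BASE_TOKENS = {"AA": AA, "AB": AB, "BB": BB, "AN": AN, "BN": BN, "NN*": NN}


def token_map(extra_missing: tuple[str, ...] = ()) -> dict[str, int]:
    m = dict(_BASE_TOKENS)
    for tok in DEFAULT_MISSING_TOKENS + tuple(extra_missing):
        m[tok] = MISSING
    return m


# lookup indexed by code+1: null-aware -> visible call
_VIS = np.full(8, MISSING, dtype=np.int8)
for _c in (AA, AB, BB):
    _VIS[_c + 1] = _c
_VIS[AN + 1] = AA
_VIS[BN + 1] = BB
_VIS[NN + 1] = MISSING


def visible(calls: np.ndarray) -> np.ndarray:
    """Project null-aware codes onto the visible call space (AN->AA etc.)."""
    return _VIS[np.asarray(calls, dtype=np.int8) + 1]


# allele multisets for Mendelian set logic; alleles as bitmasks A=1, B=2, N=4
_A, _B, _N = 1, 2, 4
CODE_ALLELES = {
    AA: (_A, _A), AB: (_A, _B), BB: (_B, _B),
    AN: (_A, _N), BN: (_B, _N), NN: (_N, _N),
}
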