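"""Amino-acid alphabet and integer encoding.

The canonical residue order is the PAML/phylogenetics convention
``ARNDCQEGHILKMFPSTWYV``; profile libraries, frequency vectors and rate
matrices all follow it.  Gaps (``-``) and fully ambiguous residues (``X``)
are treated as missing data and share a single code.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20

#: integer code for gap / unknown residue (missing data)
MISSING = 20

_CODE = {aa: i for i, aa in enumerate(AA_ORDER)}
_CODE["-"] = MISSING
_CODE["X"] = MISSING

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _ch, _i in _CODE.items():
    _LOOKUP[ord(_ch)] = _i
    _LOOKUP[ord(_ch.lower())] = _i


class AlphabetError(ValueError):
    """A residue outside the 22-symbol alphabet (20 amino acids, '-', 'X')."""


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as int8 codes (0-19 amino acids, 20 missing)."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _LOOKUP[np.minimum(raw, 127)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise AlphabetError(f"invalid residue symbol(s): {bad!r}")
    return codes.astype(np.int8)


def decode(codes: np.ndarray) -> str:
    """Decode int codes back to a residue string (missing becomes 'X')."""
    chars = np.array(list(AA_ORDER + "X"))
    return "".join(chars[np.asarray(codes, dtype=int)])
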