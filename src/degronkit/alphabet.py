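"""Amino-acid alphabet and physicochemical reference tables.

All scales are standard literature tables shipped in-repo so that scoring is
fully reproducible without any external lookup:

* hydropathy — Kyte & Doolittle (1982), range 9.0 (−4.5 for Arg to +4.5 for Ile);
* side-chain formal charge at pH 7 — Asp/Glu −1, Lys/Arg +1, His treated as
  neutral (formal charge; imidazole pKa ≈ 6), range 2.0;
* side-chain volume — Zamyatnin (1972), Å³.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
AA_WITH_X = AA20 + UNKNOWN

PHOSPHO_ACCEPTORS = frozenset("STY")
UBIQUITIN_ACCEPTOR = "K"

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
HYDROPATHY_RANGE = 9.0

CHARGE_PH7 = {aa: 0.0 for aa in AA20}
CHARGE_PH7.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0})
CHARGE_RANGE = 2.0

SIDE_CHAIN_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
VOLUME_RANGE = max(SIDE_CHAIN_VOLUME.values()) - min(SIDE_CHAIN_VOLUME.values())


def is_valid_sequence(seq: str) -> bool:
    """True if ``seq`` is non-empty and uses only the 20 residues plus 'X'."""
    return len(seq) >= 1 and all(c in AA_WITH_X for c in seq)
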