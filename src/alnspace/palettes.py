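"""Fixed color conventions for the residue views.

The exact hex values are conventions of this package, not published
constants: the amino-acid-properties scheme follows the familiar
Clustal-style physicochemical grouping, and the hydrophobicity scheme maps
the Kyte-Doolittle index linearly from +4.5 (red) to -4.5 (blue).  Gaps
render white, unknown residues gray.
"""

from __future__ import annotations

import numpy as np

from . import alphabet

RGB = tuple[int, int, int]


def _hex(code: str) -> RGB:
    return tuple(int(code[i:i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]


#: physicochemical classes -> color (Clustal-style convention)
AA_PROPERTY_CLASSES: dict[str, str] = {
    "AVLIMFW": "#80A0F0",   # hydrophobic / aromatic
    "KR":      "#F01505",   # basic
    "DE":      "#C048C0",   # acidic
    "STNQ":    "#15C015",   # polar
    "C":       "#F08080",   # cysteine
    "G":       "#F09048",   # glycine
    "P":       "#C0C000",   # proline
    "HY":      "#15A4A4",   # histidine / tyrosine
}

GAP_COLOR: RGB = (255, 255, 255)
UNKNOWN_COLOR: RGB = (128, 128, 128)

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def aa_properties_palette() -> dict[str, RGB]:
    """Residue -> RGB under the amino-acid-properties scheme."""
    palette: dict[str, RGB] = {}
    for members, color in AA_PROPERTY_CLASSES.items():
        for aa in members:
            palette[aa] = _hex(color)
    palette[alphabet.UNKNOWN] = UNKNOWN_COLOR
    palette[alphabet.GAP] = GAP_COLOR
    return palette


def hydrophobicity_palette() -> dict[str, RGB]:
    """Residue -> RGB, red (+4.5, hydrophobic) to blue (-4.5, hydrophilic)."""
    palette: dict[str, RGB] = {}
    for aa, kd in KYTE_DOOLITTLE.items():
        t = (kd + 4.5) / 9.0  # 0 = most hydrophilic, 1 = most hydrophobic
        red = np.array([220, 30, 30], dtype=float)
        blue = np.array([30, 60, 220], dtype=float)
        palette[aa] = tuple(int(round(v)) for v in blue + t * (red - blue))
    palette[alphabet.UNKNOWN] = UNKNOWN_COLOR
    palette[alphabet.GAP] = GAP_COLOR
    return palette


def desaturate(color: RGB, keep: float = 0.25) -> RGB:
    """Blend a color toward white, keeping ``keep`` of its saturation."""
    return tuple(int(round(255 - keep * (255 - c))) for c in color)  # type: ignore[return-value]
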