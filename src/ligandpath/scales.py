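"""Static physico-chemical lookup tables.

Van der Waals radii, atomic masses, the Kyte-Doolittle hydropathy scale and a
residue-level hydrogen-bond donor/acceptor classification.  All tables are
keyed by upper-case element symbols or three-letter residue codes.
"""

from __future__ import annotations

import logging
from pathlib import Path

logger = logging.getLogger(__name__)

# Bondi-style radii for the elements that dominate protein structures (Angstrom).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Fallback radius for elements outside the table (Angstrom).
DEFAULT_VDW_RADIUS = 1.70

# Standard atomic masses (unified amu) for the common biomolecular elements.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "CL": 35.45,
    "BR": 79.904,
    "F": 18.998,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "NA": 22.990,
    "K": 39.098,
    "CA": 40.078,
}

DEFAULT_ATOMIC_MASS = 12.011

# Kyte & Doolittle hydropathy index; positive = hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5,
    "VAL": 4.2,
    "LEU": 3.8,
    "PHE": 2.8,
    "CYS": 2.5,
    "MET": 1.9,
    "ALA": 1.8,
    "GLY": -0.4,
    "THR": -0.7,
    "SER": -0.8,
    "TRP": -0.9,
    "TYR": -1.3,
    "PRO": -1.6,
    "HIS": -3.2,
    "GLU": -3.5,
    "GLN": -3.5,
    "ASP": -3.5,
    "ASN": -3.5,
    "LYS": -3.9,
    "ARG": -4.5,
}

# Residue-level hydrogen-bond role of the side chain: acceptor, donor, both
# or none.  Static approximation; no protonation-state modelling.
DONOR_ACCEPTOR: dict[str, str] = {
    "ASP": "acceptor",
    "GLU": "acceptor",
    "LYS": "donor",
    "ARG": "donor",
    "TRP": "donor",
    "SER": "both",
    "THR": "both",
    "TYR": "both",
    "ASN": "both",
    "GLN": "both",
    "HIS": "both",
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
}

_warned_elements: set[str] = set()


def vdw_radius(element: str) -> float:
    """Van der Waals radius of ``element``; unknown elements fall back to
    the carbon-like default with a one-time warning."""
    el = element.strip().upper()
    radius = VDW_RADII.get(el)
    if radius is None:
        if el not in _warned_elements:
            logger.warning(
                "No vdW radius for element %r; using default %.2f A",
                element, DEFAULT_VDW_RADIUS,
            )
            _warned_elements.add(el)
        return DEFAULT_VDW_RADIUS
    return radius


def atomic_mass(element: str) -> float:
    """Standard atomic mass of ``element`` (amu), carbon fallback."""
    return ATOMIC_MASSES.get(element.strip().upper(), DEFAULT_ATOMIC_MASS)


def hydrophobicity_scale(name_or_path: str) -> dict[str, float]:
    """Return a named hydrophobicity scale, or load one from a two-column
    whitespace/comma separated file (``RES value`` per line)."""
    key = name_or_path.lower()
    if key in HYDROPHOBICITY_SCALES:
        return dict(HYDROPHOBICITY_SCALES[key])
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"Unknown hydrophobicity scale {name_or_path!r}; "
            f"known scales: {sorted(HYDROPHOBICITY_SCALES)}"
        )
    scale: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"Malformed scale line in {path}: {line!r}")
        scale[parts[0].upper()] = float(parts[1])
    return scale
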