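"""Atom-name tables used to classify donors, acceptors and charged groups.

Classification is purely name-based (standard PDB/CHARMM dialects), so
topologies without bond records still work.  Phosphoserine oxygens are
covered in both O1P/O2P/O3P and OP1/OP2/OP3 spellings.
"""

from __future__ import annotations

# Side-chain / backbone nitrogens and oxygens that carry at least one
# polar hydrogen in standard protonation states.
DONOR_NAMES = frozenset(
    {
        "N",  # backbone amide
        "NE", "NH1", "NH2",  # Arg
        "NZ",  # Lys
        "ND1", "NE2",  # His (either tautomer)
        "ND2",  # Asn
        "OG", "OG1",  # Ser / Thr hydroxyl
        "OH",  # Tyr
        "SG",  # Cys
        "NE1",  # Trp
        "OW",  # water
    }
)

# Lone-pair-bearing oxygens/nitrogens.
ACCEPTOR_NAMES = frozenset(
    {
        "O", "OXT", "OT1", "OT2",  # backbone carbonyl / terminus
        "OD1", "OD2",  # Asp / Asn
        "OE1", "OE2",  # Glu / Gln
        "OG", "OG1", "OH",  # hydroxyls
        "ND1", "NE2",  # His
        "SD",  # Met
        "OW",
        # phosphate oxygens (phosphoserine, both naming dialects)
        "O1P", "O2P", "O3P", "OP1", "OP2", "OP3",
    }
)

# Basic side-chain nitrogens (salt-bridge cations).
BASIC_NITROGENS = frozenset({"NZ", "NH1", "NH2", "NE", "ND1", "NE2"})

# Acidic / phosphate / hydroxylate oxygens (salt-bridge anions).
ACIDIC_OXYGENS = frozenset(
    {
        "OD1", "OD2", "OE1", "OE2",
        "O1P", "O2P", "O3P", "OP1", "OP2", "OP3",
        "OG",  # phospho-Ser bridging oxygen
        "OXT", "OT1", "OT2",
    }
)

# Fallback masses (amu) by element symbol.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "ZN": 65.38,
}


def element_from_name(name: str) -> str:
    """Guess the element from a PDB atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in {"MG", "NA", "CL", "ZN", "FE", "MN", "CA"} and len(name.strip()) <= 2:
        # bare ion names only; "CA" in a protein residue is a carbon
        return two
    return stripped[0].upper()


def mass_from_element(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 12.011)
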