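"""Residue annotation templates.

Each template lists, by atom name, the hydrogen-bond donors (heavy, H)
pairs, the acceptors with their class ("ON" for oxygen/nitrogen, "S" for
methionine sulphur, which carries a longer distance cutoff), planar
aromatic rings, named proton equivalence groups, the residue charge class
and the molecule class. Annotation is strict: a residue name absent from
this table is a hard error, because silently skipping residues would
corrupt interaction counts.
"""

from __future__ import annotations


def _aa(charge: str = "neutral", donors=None, acceptors=None, rings=None,
        equivalence=None) -> dict:
    base_donors = [("N", "H")]
    base_acceptors = {"O": "ON"}
    d = dict(
        molecule="protein",
        charge=charge,
        donors=base_donors + list(donors or []),
        acceptors={**base_acceptors, **(acceptors or {})},
        rings=[list(r) for r in (rings or [])],
        equivalence={k: list(v) for k, v in (equivalence or {}).items()},
    )
    return d


RESIDUE_TEMPLATES: dict[str, dict] = {
    "ALA": _aa(),
    "ARG": _aa("positive",
               donors=[("NE", "HE"), ("NH1", "HH11"), ("NH1", "HH12"),
                       ("NH2", "HH21"), ("NH2", "HH22")]),
    "ASN": _aa(donors=[("ND2", "HD21"), ("ND2", "HD22")],
               acceptors={"OD1": "ON"}),
    "ASP": _aa("negative", acceptors={"OD1": "ON", "OD2": "ON"}),
    "CYS": _aa(),
    "GLN": _aa(donors=[("NE2", "HE21"), ("NE2", "HE22")],
               acceptors={"OE1": "ON"}),
    "GLU": _aa("negative", acceptors={"OE1": "ON", "OE2": "ON"}),
    "GLY": _aa(),
    "HIS": _aa(donors=[("NE2", "HE2")], acceptors={"ND1": "ON"},
               rings=[["CG", "ND1", "CE1", "NE2", "CD2"]]),
    "ILE": _aa(),
    "LEU": _aa(equivalence={"LEU-CH3": ["HD11", "HD12", "HD13"]}),
    "LYS": _aa("positive",
               donors=[("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")]),
    "MET": _aa(acceptors={"SD": "S"},
               equivalence={"MET-CH3": ["HE1", "HE2", "HE3"]}),
    "PHE": _aa(rings=[["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]]),
    "PRO": _aa(donors=[]),
    "SER": _aa(donors=[("OG", "HG")], acceptors={"OG": "ON"}),
    "THR": _aa(donors=[("OG1", "HG1")], acceptors={"OG1": "ON"}),
    "TRP": _aa(donors=[("NE1", "HE1")],
               rings=[["CG", "CD1", "NE1", "CE2", "CD2"],
                      ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]]),
    "TYR": _aa(donors=[("OH", "HH")], acceptors={"OH": "ON"},
               rings=[["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]]),
    "VAL": _aa(equivalence={"VAL-CH3": ["HG11", "HG12", "HG13"]}),
    "HOH": dict(
        molecule="solvent", charge="water",
        donors=[("O", "H1"), ("O", "H2")],
        acceptors={"O": "ON"},
        rings=[], equivalence={},
    ),
    "CA": dict(  # calcium ion
        molecule="ion", charge="ion",
        donors=[], acceptors={}, rings=[], equivalence={},
    ),
    "NA": dict(
        molecule="ion", charge="ion",
        donors=[], acceptors={}, rings=[], equivalence={},
    ),
    # Synthetic three-ring polyphenol-like ligand used by the toy complex.
    # All hydroxyls are rotatable donors and every oxygen is an acceptor.
    "EGX": dict(
        molecule="ligand", charge="neutral",
        donors=[("OA1", "HOA1"), ("OA2", "HOA2"),
                ("OB1", "HOB1"), ("OB2", "HOB2"), ("OB3", "HOB3"),
                ("OP1", "HOP1"), ("OP2", "HOP2"), ("OP3", "HOP3")],
        acceptors={"OA1": "ON", "OA2": "ON",
                   "OB1": "ON", "OB2": "ON", "OB3": "ON",
                   "OP1": "ON", "OP2": "ON", "OP3": "ON",
                   "OL1": "ON"},
        rings=[["CA1", "CA2", "CA3", "CA4", "CA5", "CA6"],   # A/C
               ["CB1", "CB2", "CB3", "CB4", "CB5", "CB6"],   # B
               ["CP1", "CP2", "CP3", "CP4", "CP5", "CP6"]],  # B'
        equivalence={"H12/H13": ["H12", "H13"],
                     "H16/H17": ["H16", "H17"],
                     "H9/H10": ["H9", "H10"]},
    ),
}

#: Named rotatable dihedrals of the synthetic ligand (atom names).
LIGAND_DIHEDRALS: dict[str, tuple[str, str, str, str]] = {
    "chi1": ("CA1", "CL1", "CB1", "CB2"),
    "chi2": ("CL1", "CL2", "OL1", "CP1"),
    "chi3": ("CL2", "OL1", "CP1", "CP2"),
}

#: Atom names considered part of the peptide backbone (salt-bridge
#: detection is restricted to side-chain atoms).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}
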