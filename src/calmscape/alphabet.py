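"""Shared amino-acid alphabet constants.

The fixed residue order gives deterministic indexing for column counts and
PSSM matrices across the whole package.
"""

# 20 standard amino acids, fixed order (one-letter codes).
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}
N_AA: int = 20

GAP_CHARS: frozenset[str] = frozenset("-.")
# Ambiguity / nonstandard one-letter codes that may appear in real sequence
# data; counted separately, never as one of the 20.
NONSTANDARD: frozenset[str] = frozenset("BZXUOJ*")

# Three-letter -> one-letter for PDB residue names.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
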