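"""Amino-acid alphabets shared across the package.

The scoring alphabet drops tryptophan and cysteine: both are rare in
intrinsically disordered regions, too rare for their matrix cells to be
constrained by realistically sized training sets.
"""

# 20 canonical residues, alphabetical one-letter order.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

# Residues carrying matrix scores: canonical minus W and C.
MATRIX_AA: str = "ADEFGHIKLMNPQRSTVY"

#: Unknown residue; accepted in sequences, contributes zero to scores.
UNKNOWN: str = "X"

#: Pad character marking positions beyond a sequence terminus in a window.
PAD: str = "-"

#: Alphabet accepted inside protein sequences.
SEQUENCE_AA: str = CANONICAL_AA + UNKNOWN

#: Residues a window may contain.
WINDOW_AA: str = SEQUENCE_AA + PAD

#: Residues that may occupy a window center (glycosylation acceptors).
CENTER_AA: str = "ST"

MATRIX_AA_INDEX = {aa: i for i, aa in enumerate(MATRIX_AA)}
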