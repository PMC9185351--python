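"""The 20-letter amino-acid alphabet shared by every module."""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Labels of the binary classification task: anticancer / non-anticancer peptide.
ACP = "ACP"
NACP = "NACP"
LABELS = (ACP, NACP)
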