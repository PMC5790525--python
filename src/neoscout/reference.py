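"""Published reference inputs for the validated mICAM1 neoantigen.

These are inputs, not results: the mutant-ICAM1 missense notation and the
28-residue synthetic long peptide used for vaccination, as printed in the
study this pipeline reimplements.  They anchor the worked examples and the
acceptance checks.
"""

MICAM1_NOTATION = "P315L"
"""The ICAM1 missense change restricted by H-2Kb."""

MICAM1_SLP = "DQILETQRTLTVYNFSALVLTLSQLEVS"
"""The mICAM1 synthetic long peptide sequence (28 residues)."""

MICAM1_SLP_LENGTH = 28
"""Stated length of the synthetic long peptide."""
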