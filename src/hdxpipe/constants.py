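"""Physical constants used across the package.

All masses are in daltons. ``MASS_DH`` is the mass gained when a backbone
amide hydrogen is replaced by a deuterium; ``MASS_PROTON`` is used for
m/z <-> neutral-mass conversion of positive ions.
"""

MASS_DH: float = 1.00628
MASS_PROTON: float = 1.00728

#: One-letter codes of the 20 canonical amino acids.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
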