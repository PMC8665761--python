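"""Exception types raised by founderpan."""


class FounderPanError(Exception):
    """Base class for founderpan errors."""


class UnphasedGenotypeError(FounderPanError):
    """A multi-copy genotype without phasing was encountered in strict mode."""


class UnsupportedAlleleError(FounderPanError):
    """Symbolic, breakend or otherwise non-sequence alleles are not supported."""


class ReferenceMismatchError(FounderPanError):
    """A VCF REF allele disagrees with the reference FASTA."""


class OverlappingVariantError(FounderPanError):
    """Two variants chosen on one haplotype overlap on the reference."""
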