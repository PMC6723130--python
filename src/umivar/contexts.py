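"""Substitution classes and trinucleotide-context canonicalisation.

Complementary changes (C>T and G>A, etc.) describe the same event on
opposite strands and are combined into six pyrimidine-centred classes.
"""

#: complementary-collapsed substitution classes, pyrimidine-centred
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-centred class (e.g. G>A -> C>T)."""
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}"


def collapse_context(context: str, alt: str) -> tuple[str, str]:
    """Canonical (context, alt) with a pyrimidine centre base."""
    if context[1] in "AG":
        context = "".join(_COMP[b] for b in reversed(context))
        alt = _COMP[alt]
    return context, alt
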