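"""Fixed sensory-attribute vocabulary for expert panel scores.

Fifteen attributes total: eleven aroma descriptors and four taste /
mouthfeel descriptors. Attribute-feature networks are usually built
separately for the two groups.
"""

AROMA_ATTRIBUTES: tuple[str, ...] = (
    "spice",
    "woody",
    "smoky",
    "coffee/chocolate",
    "vegetal",
    "animal",
    "herbal",
    "red berries",
    "stone fruits",
    "nuts",
    "caramel",
)

TASTE_ATTRIBUTES: tuple[str, ...] = (
    "astringency",
    "acidity",
    "bitterness",
    "sweetness",
)

SENSORY_ATTRIBUTES: tuple[str, ...] = AROMA_ATTRIBUTES + TASTE_ATTRIBUTES
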