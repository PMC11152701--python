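"""Reference pigment contents from spectrophotometer absorbances.

0.1 g of leaf tissue extracted in 10 mL of 95% ethanol, read at 665, 649
and 470 nm; the standard coefficient set converts the absorbance triple to
chlorophyll a/b, total chlorophyll and carotenoid contents in mg per g.
"""

from leafspec.chemistry import ExtractionContext, pigments_from_absorbance

panel = pigments_from_absorbance(
    a665=0.82, a649=0.28, a470=0.55, ctx=ExtractionContext(sample_mass=0.1, extract_volume=10.0)
)
print(panel.round(4).to_string(index=False))
print("\nContents are mg per g fresh weight; chlt is chla + chlb by "
      "definition. Doubling the extract volume would double every content; "
      "doubling the weighed mass would halve it.")
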