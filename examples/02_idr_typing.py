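"""Type disordered regions: RS-like, poly-P/Q, G-rich, charged, SS-IDR.

Classifies hand-built segments that mimic an SR-protein RS domain, a
glutamine homorepeat, and an RGG box, then shows the SS-IDR override.
"""

from idrscope import (ProteinRecord, Region, RegionKind,
                      SecondaryStructureProfile, annotate_ss_idr, classify_cb,
                      find_motifs)

examples = {
    "RS domain":     "RSRSRSRSRSRSRSRSRSRSRSRSRSRSRS",
    "poly-Q tract":  "ASTNHMLVAIFQQQQQQQQASTNHMLVAIF",
    "RGG box":       "RGGNAYGGRGGNAYGGRGGNAYGGRGGNAY",
    "acidic/basic":  "EKEDKEKEDEKEKDEKEKEDKEKEDEKEKD",
}
for name, seq in examples.items():
    rec = ProteinRecord("X", seq)
    region = Region("X", 1, len(seq), RegionKind.DISORDERED)
    typed = classify_cb(rec, region)
    print(f"{name:14s} -> {typed.subtype.value}")
# RS beats charged for the RS domain (precedence RS > G > PQ > CHARGED).

print("\nGly-centred motifs in the RGG box:")
for motif, start, end in find_motifs(examples["RGG box"],
                                     {"RGG", "XGG", "RXT"})[:5]:
    print(f"  {motif:4s} at {start}-{end}")

# A disordered region whose residues mostly sit in a long helix run is an
# SS-IDR (a conformationally transitional segment); the CB call survives
# in cb_subtype.
ss = SecondaryStructureProfile("X", "C" * 5 + "H" * 22 + "C" * 3)
region = classify_cb(ProteinRecord("X", examples["RS domain"]),
                     Region("X", 1, 30, RegionKind.DISORDERED))
typed = annotate_ss_idr(region, ss)
print(f"\nhelix-rich RS region -> {typed.subtype.value} "
      f"(alpha {typed.alpha_frac:.2f}, CB retained: {typed.cb_subtype.value})")
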