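"""Enumerate the theoretical fragment catalogue of one isomer.

Builds the full catalogue for T-Car-T — conventional b/y ions, the
combinatorial neutral-loss series, and scrambled/internal b ions from
macrocycle reopening — and shows how scrambling changes what the catalogue
can explain.
"""

from collections import Counter

from isofrag import CatalogueConfig, T_CAR_T, build_catalogue

full = build_catalogue(T_CAR_T, CatalogueConfig(scrambling=True))
plain = build_catalogue(T_CAR_T, CatalogueConfig(scrambling=False))

print(f"T-Car-T catalogue with scrambling:    {len(full):6d} ions")
print(f"T-Car-T catalogue without scrambling: {len(plain):6d} ions")
print("\nIon kinds (with scrambling):")
for kind, n in Counter(i.kind.value for i in full.ions).most_common():
    print(f"  {kind:12s} {n:6d}")

print("\nCandidates near the T-Car-T diagnostic peak m/z 772.98:")
df = full.to_dataframe()
near = df[(df.mz > 772.96) & (df.mz < 773.00)]
print(near.to_string(index=False))
print(
    "\nNote the exact mass degeneracy: the scrambling-route ion "
    "[int(RRRPSGRKKRRQ)-H2O]2+ and the conventional [b12-CH2N2]2+ have "
    "identical elemental composition, so m/z alone cannot separate them."
)

full.to_tsv("t_car_t_catalogue.tsv")
print(f"\nwrote t_car_t_catalogue.tsv ({len(full)} rows)")
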