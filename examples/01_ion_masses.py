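"""Monoisotopic masses and m/z values for the carnosine-TAT1 isomers.

Builds the three isomeric peptides (carnosine = βAla-His grafted onto
TAT1 = GRKKRRQRRRPS at the N-terminus, centre, or C-terminus), and prints
the ion m/z values that anchor the whole analysis: the shared doubly
protonated precursor, the halved neutral-loss shifts that dominate its
CID spectra, and the isomer-specific fragments.
"""

from isofrag import (
    CAR_TAT1,
    T_CAR_T,
    TAT1_CAR,
    IonKind,
    IonSpec,
    ResidueTable,
    default_losses,
    delta_mz,
    ion_mz,
    peptide_mass,
)

table = ResidueTable.default()
losses = default_losses()

print("Neutral monoisotopic masses (Da) — all three are isomers:")
for seq in (CAR_TAT1, T_CAR_T, TAT1_CAR):
    print(f"  {seq.id:10s} {seq}  ->  {peptide_mass(seq, table):.4f}")

prec = IonSpec(IonKind.PRECURSOR, TAT1_CAR.residues, 2)
print(f"\nDoubly protonated precursor [M+2H]2+: m/z {ion_mz(prec, table):.2f}")

print("\nNeutral-loss m/z shifts on the 2+ precursor (mass halved by charge):")
for name in ("ammonia", "water", "carbodiimide", "guanidine"):
    l = losses[name]
    shifted = ion_mz(prec.with_losses(l), table)
    print(
        f"  -{l.formula:5s} ({name:12s}) shift {delta_mz(l, 2):+7.2f} "
        f"-> m/z {shifted:.2f}"
    )

print("\nIsomer-specific ions:")
b2 = IonSpec(IonKind.B, CAR_TAT1.residues[:2], 1)
y12 = IonSpec(IonKind.Y, CAR_TAT1.residues[2:], 2)
print(f"  Car-TAT1 charge-separation pair: b2 {ion_mz(b2, table):.2f} (1+) / "
      f"y12 {ion_mz(y12, table):.2f} (2+)")
b_beta = IonSpec(IonKind.INTERNAL_B, (T_CAR_T.residues * 2)[9:21], 2)
print(f"  T-Car-T scrambled b-type 12-mer RRRPSGRKKRRQ: {ion_mz(b_beta, table):.2f} (2+), "
      f"-H2O {ion_mz(b_beta.with_losses(losses['water']), table):.2f}")
b10 = IonSpec(IonKind.B, TAT1_CAR.residues[:10], 2)
print(f"  TAT1-Car b10-CH2N2: "
      f"{ion_mz(b10.with_losses(losses['carbodiimide']), table):.2f} (2+)")
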