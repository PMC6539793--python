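"""Annotate an Amadori-glycated tryptic peptide by theoretical m/z.

Computes the neutral monoisotopic mass of a glycated albumin peptide, its
multiply protonated ion m/z values, the ppm error against an observed ion,
and the diagnostic water/formaldehyde neutral-loss ladder that confirms the
glucose-derived Amadori modification.
"""

from glycomark import (
    amadori_loss_ladder,
    enumerate_charge_states,
    monoisotopic_mass,
    parse_modified_sequence,
    ppm_error,
)

# albumin peptide FKDLGEENFK glycated at K12 of the mature protein
peptide = parse_modified_sequence("FK*DLGEENFK")
mass = monoisotopic_mass(peptide)
print(f"peptide {peptide}  neutral mass {mass:.4f} Da")

observed = {3: 463.5581, 2: 694.8330}  # centroids from an annotated run
for ion in enumerate_charge_states(peptide, z_min=2, z_max=3):
    err = ppm_error(observed[ion.charge], ion.mz)
    print(f"  [M+{ion.charge}H]{ion.charge}+  theoretical m/z {ion.mz:.4f}  "
          f"observed {observed[ion.charge]:.4f}  error {err:+.1f} ppm")

precursor = enumerate_charge_states(peptide, 3, 3)[0]
print("Amadori neutral-loss ladder of the 3+ precursor:")
for label, mz in amadori_loss_ladder(precursor):
    print(f"  {label:>14s}  m/z {mz:.4f}")
print("Losses of up to 3 H2O and one CH2O below the precursor are the")
print("fingerprint of a glucose-derived Amadori (fructosamine) adduct.")
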