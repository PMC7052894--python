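"""Ion masses and equimolar dosing for paclitaxel and its prodrug.

Computes the monoisotopic m/z of the quantitative ions used for the two
compounds, and the prodrug dose that delivers the same molar amount as a
37.5 mg/kg paclitaxel dose.
"""

from vcqmsi.pk_stats import ELECTRON_MASS, adduct_mz, equimolar_dose

ptx_na = adduct_mz("C47H51NO14", "[M+Na]+")
print(f"paclitaxel [M+Na]+           m/z {ptx_na:.4f}")

# prodrug neutral mass back-calculated from its radical cation [M]+ ion
prodrug_ion = 983.4172
prodrug_mass = prodrug_ion + ELECTRON_MASS
ptx_mass = ptx_na - 22.9897693 + ELECTRON_MASS
dose = equimolar_dose(37.5, ptx_mass, prodrug_mass)
print(f"paclitaxel neutral mass      {ptx_mass:.4f} Da")
print(f"prodrug neutral mass         {prodrug_mass:.4f} Da")
print(f"equimolar prodrug dose       {dose} mg/kg for 37.5 mg/kg paclitaxel")
# The dose scales by the molar-mass ratio so both regimens inject the same
# number of molecules per kg of body weight.
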