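"""Physical constants and unit conversions.

Internal conventions: lengths in nm, energies in kJ/mol, times in ps,
temperatures in K.  Free-energy surfaces are *reported* in kcal/mol.
"""

#: Boltzmann constant in kJ/(mol K).
KB = 0.0083144621

#: kJ per kcal.
KJ_PER_KCAL = 4.184

#: Angstrom per nm (PDB files store Angstrom; everything internal is nm).
ANGSTROM_PER_NM = 10.0

#: Residue-numbering offset between mature-protein (PDB) numbering and the
#: convention that counts the 24-residue membrane-targeting signal peptide.
SIGNAL_PEPTIDE_OFFSET = 24


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol at ``temperature`` K."""
    return KB * temperature
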