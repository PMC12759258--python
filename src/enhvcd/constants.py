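"""Physical constants and unit conversions used throughout the package.

All internal arithmetic is done in Hartree atomic units (hbar = e = m_e = 1,
c = 1/alpha). Magnetic quantities (AAT blocks, magnetic dipole transition
moments) follow the convention in which the 1/c of the magnetic dipole
operator is absorbed into the stored number, so a stored magnetic moment of
``alpha/2`` corresponds to one Bohr magneton and the unit of the stored value
is ``e * a0`` — the same as the electric dipole. Purely imaginary quantities
(AAT, MDTM) are stored as their real-valued imaginary parts.

Values are CODATA 2018.
"""

# -- fundamental -------------------------------------------------------------
SPEED_OF_LIGHT_AU = 137.035999084     # 1/alpha
AMU_TO_ME = 1822.888486209            # atomic mass unit in electron masses

# -- length / energy ---------------------------------------------------------
BOHR_TO_ANGSTROM = 0.529177210903
HARTREE_TO_EV = 27.211386245988
HARTREE_TO_CM = 219474.6313632        # hartree -> wavenumber (cm^-1)
EV_TO_CM = HARTREE_TO_CM / HARTREE_TO_EV   # 8065.5439... cm^-1 per eV

# -- dipole / strength output units ------------------------------------------
# e * a0 in esu*cm (Gaussian units); with the 1/c-absorbed convention this is
# the unit of both the electric and the stored magnetic transition moments.
EA0_ESU_CM = 2.541746473e-18

# rotational strength: internal a.u. -> conventional 10^-44 esu^2 cm^2
R_AU_TO_CGS44 = EA0_ESU_CM**2 / 1e-44      # ~6.4605e8
# dipole strength: internal a.u. -> conventional 10^-40 esu^2 cm^2
D_AU_TO_CGS40 = EA0_ESU_CM**2 / 1e-40      # ~6.4605e4

# -- band-shape prefactors ----------------------------------------------------
# Standard relations between band areas and strengths (Gaussian-unit esu^2 cm^2):
#   D_i = 9.184e-39 * integral( eps / nu ) d nu
#   R_i = 2.296e-39 * integral( d_eps / nu ) d nu
# so, with unit-area line shapes L(nu) and strengths in the conventional
# 10^-40 / 10^-44 units:
#   eps(nu)   = nu * sum_i D_i * L_i(nu) * IR_EPS_PREFACTOR
#   d_eps(nu) = nu * sum_i R_i * L_i(nu) * VCD_EPS_PREFACTOR
IR_EPS_PREFACTOR = 1e-40 / 9.184e-39       # ~1.0889e-2
VCD_EPS_PREFACTOR = 1e-44 / 2.296e-39      # ~4.3554e-6
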