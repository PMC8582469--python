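"""Physical constants (CODATA values, truncated to the precision used here)."""

AVOGADRO = 6.02214076e23        # 1/mol
ELECTRON_REST_KEV = 510.99895   # m_e c^2 in keV
RE_CM = 2.8179403262e-13        # classical electron radius, cm
KEV_TO_JOULE = 1.602176634e-16
GRAY_PER_KEV_PER_G = KEV_TO_JOULE * 1e3   # Gy per (keV deposited per gram)
BOHR_ANGSTROM = 0.529177
HC_KEV_ANGSTROM = 12.39842      # photon E[keV] * lambda[Angstrom]
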