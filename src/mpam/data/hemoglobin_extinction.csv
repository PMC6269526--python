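# Molar extinction coefficients of human hemoglobin, cm^-1/(mol/L).
# Approximate values at the two PAM excitation wavelengths, interpolated from
# the standard compilation of Gratzer & Kollias tabulated by S. Prahl
# (https://omlc.org/spectra/hemoglobin/). Version 1 (2026-10).
# Columns: wavelength_nm, eps_hbo2, eps_hb
wavelength_nm,eps_hbo2,eps_hb
532,44480.0,40584.0
559,32820.0,52276.0
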