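# Molar extinction coefficients of human hemoglobin, cm^-1/M.
# Source: standard compiled tabulation of oxy-/deoxyhemoglobin spectra
# (S. Prahl, Optical absorption of hemoglobin, OMLC compilation).
# The 558 nm row is interpolated from the tabulated grid and approximate;
# all package tests rely on forward-inverse self-consistency, not on the
# specific values.
wavelength_nm,eps_hbo2,eps_hb
532,44480.0,40584.0
558,33512.0,52912.0
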