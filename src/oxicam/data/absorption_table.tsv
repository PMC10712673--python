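# Molar absorption (extinction) coefficients of human hemoglobin at the three
# LED band centers, in L mol^-1 cm^-1 (natural-log convention is irrelevant:
# only ratios and differences enter the SpO2 inversion).
# Values follow the standard OMLC (Prahl) compilation of oxy-/deoxyhemoglobin
# spectra, interpolated to the band centers.
# columns: band	center_nm	eps_hbo2	eps_hb
G	524	23400.0	24600.0
R	630	610.0	5148.8
NIR	850	1058.0	691.32
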