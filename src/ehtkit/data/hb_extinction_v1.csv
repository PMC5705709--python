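# Molar extinction coefficients of oxy- and deoxyhemoglobin (cm^-1 / (mol/L)),
# compiled from a standard published tabulation, resampled at the 11 acquisition
# wavelengths. Version 1 -- the forward phantom model and the inverse unmixing
# model must both read this file.
wavelength_nm,eps_hbo2,eps_hb
500,20932.8,20862.0
510,20035.2,25773.6
520,24202.4,31589.6
530,39956.8,39036.4
540,53236.0,46592.0
550,43016.0,52276.0
560,32613.2,53788.0
570,44496.0,45092.0
580,50104.0,37020.0
590,14400.8,28324.4
600,3200.0,14677.2
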