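proton_water_stopping_synthetic.csv: synthetic reconstruction of the
stopping power of protons in liquid water (total, unit density).
Generated from the package's calibrated piecewise model (velocity power
law merged with an empirical logarithmic branch below 0.5 MeV and a
relativistic Bethe term above), with coefficients calibrated to
published anchor values known to about 5 percent. Not a copy of any
published data file. Units: MeV per nucleon; keV per micrometre.
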