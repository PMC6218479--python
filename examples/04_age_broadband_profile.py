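"""Frequency-resolved correlation of broadband power with age.

In the generator, older hemispheres have faster-decaying, lower
low-frequency broadband and a higher noise floor.  Correlating each
hemisphere's fitted broadband curve with age, bin by bin, recovers a
significant negative band at low frequencies and a positive band at
high frequencies (BH-FDR across the 1-200 Hz profile).
"""

from stnbeta import analyze_cohort, gen_cohort

res = analyze_cohort(gen_cohort(seed=11), n_boot=0, profile_covariates=("age",))
prof = res["profiles"]["age"]

neg = prof[prof.reject & (prof.rho < 0)]
pos = prof[prof.reject & (prof.rho > 0)]
print("significant NEGATIVE age correlation: %d bins, %.0f-%.0f Hz"
      % (len(neg), neg.frequency_hz.min(), neg.frequency_hz.max()))
print("significant POSITIVE age correlation: %d bins, %.0f-%.0f Hz"
      % (len(pos), pos.frequency_hz.min(), pos.frequency_hz.max()))
print()
print("The low-frequency decline and high-frequency rise with age mirror the")
print("physiological signature expected of genuine (non-instrumental)")
print("broadband activity.")
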