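"""Fit a single-agent dose-response curve and interpolate effect levels.

Samples a 10-point two-fold dilution series (20 nM - 20 uM) from a known
four-parameter logistic with realistic plate noise, refits it, and reads
concentrations at chosen effect levels off the fitted curve.
"""

from synletscreen import simulate
from synletscreen.dose_response import fit_logistic, ic50

profile = simulate.gen_dose_response_curve(
    ic50=13.4, hill=1.2, sigma=0.02, seed=2, compound="EZH2i", cell_line="KB1P-G3"
)
fit = fit_logistic(profile)

print(f"true IC50 13.40 uM; fitted {fit.ic50:.2f} uM (hill {fit.hill:.2f}, "
      f"top {fit.top:.2f}, bottom {fit.bottom:.2f}, converged={fit.converged})")
print(f"concentration for 75% viability: {ic50(fit, 0.75):.2f} uM")
print(f"concentration for 50% viability: {ic50(fit, 0.50):.2f} uM")
print(
    "\nEffect levels are read off the fitted logistic, not the raw points; with\n"
    "plateaus at exactly 1 and 0 the 50% level coincides with the fitted midpoint."
)
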