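"""Standard-addition quantitation and spiked recovery.

Extrapolates a measured-vs-added line to its x-intercept to recover the
original sample concentration (matrix-effect-free), then computes the
spiked-recovery percentage and replicate RSD.
"""

import numpy as np

import voltpls as vp

# A diluted urine-like sample containing 3 µM analyte, measured after
# additions of 0/2/4/6 µM with a 30-fold prior dilution.
added = np.array([0.0, 2.0, 4.0, 6.0])
measured = 1.0 * (3.0 + added)  # ideal linear response
series = vp.StandardAdditionSeries(added, measured, dilution_factor=30.0)
estimate = vp.standard_addition_estimate(series)
print(f"extrapolated original concentration: {estimate:.1f} uM (true 90.0)")

# Spiked recovery from found-before/added/found-after values:
rec = vp.recovery_percent(found_before=0.15, added=35.0, found_after=36.4)
print(f"recovery: {rec:.1f}% (rounds to 104%)")

# Replicate precision:
replicates = [35.9, 36.4, 36.8, 36.1, 36.6]
print(f"RSD over {len(replicates)} replicates: {vp.rsd(replicates):.2f}%")
# Recovery near 100% and single-digit RSD indicate the calibration
# transfers to the spiked matrix without bias.
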