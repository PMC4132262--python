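"""ADCC dose-response: 4PL fits, EC50 comparison by the extra-sum-of-squares
F-test, and relative potency.
"""

import numpy as np

from fabrefine.cytotoxicity import compare_ec50, fit_4pl, relative_potency
from fabrefine.synthetic_data import make_dose_response

reference = make_dose_response({"log_ec50": float(np.log10(2.61e-3))},
                               noise_sd=3.0, seed=1, sample="parental")
enhanced = make_dose_response({"log_ec50": float(np.log10(0.46e-3))},
                              noise_sd=3.0, seed=2, sample="enhanced")

fit_ref = fit_4pl(reference)
fit_enh = fit_4pl(enhanced)
print(f"parental EC50 = {fit_ref.ec50 * 1e3:.2f} x10^-3 ug/mL "
      f"(hill {fit_ref.hill:.2f})")
print(f"enhanced EC50 = {fit_enh.ec50 * 1e3:.2f} x10^-3 ug/mL "
      f"(hill {fit_enh.hill:.2f})")

f_stat, p = compare_ec50(reference, enhanced, fit_ref, fit_enh)
rp = relative_potency(fit_ref.ec50, fit_enh.ec50)
print(f"\nF = {f_stat:.1f}, p = {p:.2g}; relative potency = {rp}")
# Relative potency ~5-6 with p << 0.05: the enhanced construct kills target
# cells at roughly one-sixth the antibody concentration.
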