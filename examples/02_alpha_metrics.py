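"""Alpha-peak fit and summary measures for one synthetic subject.

The eyes-closed occipital spectrum is fit with a Gaussian over a 1/f
background; alpha power is integrated in [f_p - 2, f_p + 2] Hz per
condition and the reactivity R = 1 - P_EO / P_EC summarises the
suppression of alpha by eye opening.
"""

from restspectra import (CohortSpec, alpha_summary, average_reference, epoch,
                         fit_alpha_peak, generate_cohort, welch_psd)
from restspectra.data import CHANNELS_DEMO

spec = CohortSpec(n_per_group=1, channels=list(CHANNELS_DEMO), srate=128.0,
                  seed=3, background_rms=3.0)
metas, recs, truth = generate_cohort(spec, return_truth=True)
es = average_reference(epoch(recs[0]))
psd_eo, psd_ec = welch_psd(es.select("EO")), welch_psd(es.select("EC"))

fit = fit_alpha_peak(psd_ec)
summ = alpha_summary(psd_eo, psd_ec)
print(f"subject {metas[0].id}, age {metas[0].age:.1f}")
print(f"fitted peak: f_p = {fit.f_p:.2f} Hz (injected "
      f"{truth.f_p[0]:.2f} Hz), background exponent {fit.powerlaw_b:.2f}")
print(f"alpha power: EO {summ.p_eo:.1f} uV^2, EC {summ.p_ec:.1f} uV^2")
print(f"reactivity R = {summ.r:.2f} (injected {truth.r_target[0]:.2f})")
print("\nR near its target shows the EC>EO alpha boost is measured "
      "correctly from 2 min per condition.")
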