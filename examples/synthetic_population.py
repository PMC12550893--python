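"""Generate a synthetic SP/MP population and recover its structure.

Single-peaked (SP) units get one von Mises bump; multipeaked (MP) units get
several narrow, well-separated bumps plus a sign-specific angular-velocity
gain.  The analysis pipeline should recover the class labels, preferred
directions and peak widths it was given.
"""

import numpy as np

import headcode as hc

spec = hc.SyntheticPopSpec(
    n_sp=16, n_mp=6, mp_peak_width=0.5, ahv_gain_class="mp",
    base_rate=20.0, noise_model="poisson", seed=42,
)
session = hc.make_session(spec, n_steps=48_000)
print(f"session: {session.n_units} units, {session.duration/60:.0f} min")

metrics = hc.compute_unit_metrics(session, alpha=0.10, n_shuffles=200, seed=0)
truth = session.meta["labels"]
recovered = metrics["label"].to_numpy()
agree = np.mean([t == r for t, r in zip(truth, recovered)])
print(metrics[["mi_hd", "pr_ahv", "mvl", "fwhm", "label"]].round(3))
print(f"\nclassification agreement with ground truth: {agree:.0%}")
print(
    "mean FWHM  SP: %.2f rad   MP: %.2f rad (generator MP width %.2f)"
    % (
        metrics[metrics.label == "SP"].fwhm.mean(),
        metrics[metrics.label == "MP"].fwhm.mean(),
        spec.mp_peak_width,
    )
)
# SP units show high MVL and mutual information; MP units show low MVL,
# narrow per-peak FWHM and (because the AHV gain was assigned to them)
# higher partial correlation with angular velocity.
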