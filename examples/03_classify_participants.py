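"""Identify participants from single movements by posterior distance.

Simulates three participants whose movements differ mostly in timing, then
runs chronological 5-fold cross-validation: for each fold the model is
fitted on the training repetitions and each held-out curve is assigned to
the participant whose fitted template (theta + phi_i) o nu_i has the least
negative log posterior after re-predicting only the test curve's random
warp.  An unwarped nearest-mean-template classifier is run for comparison.
"""

import movewarp as mw

sim = mw.PavpopSimConfig(
    n_participants=3, n_repetitions=10, n_timepoints=40,
    phi_scale=0.06, sigma2=4e-3, tau2=1.0, alpha=5.0, gamma2=2.0,
    nu_scale=0.08, seed=23,
)
samples, _ = mw.simulate_pavpop(sim)
fit_config = mw.PavpopConfig(n_knots=12, n_w=2, mu=1.0, i_max=3)

tms_correct = base_correct = total = 0
for train_ids, test_ids in mw.chronological_cv_folds(10, 5):
    train = [s for s in samples if s.repetition_id in train_ids]
    test = [s for s in samples if s.repetition_id in test_ids]
    fit = mw.fit_pavpop(train, fit_config)
    # unwarped baseline: L2 distance to the pointwise mean training curve
    import numpy as np
    by_pid = {}
    for s in train:
        by_pid.setdefault(s.participant_id, []).append(s.values)
    templates = {pid: np.mean(v, axis=0) for pid, v in sorted(by_pid.items())}
    for s in test:
        total += 1
        tms_correct += mw.classify_tms(s, fit) == s.participant_id
        dists = {pid: float(np.sum((s.values - tpl) ** 2)) for pid, tpl in templates.items()}
        base_correct += min(sorted(dists), key=lambda p: dists[p]) == s.participant_id

print(f"chronological 5-fold CV over {total} held-out curves:")
print(f"  posterior-distance (warping model) accuracy: {tms_correct / total:.2f}")
print(f"  unwarped nearest-template baseline:          {base_correct / total:.2f}")
print("the warping classifier separates timing traits from amplitude noise,")
print("so it keeps discriminating when random warps smear the mean templates")
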