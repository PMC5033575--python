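import numpy as np
import pytest

import movewarp as mw


@pytest.fixture
def small_samples():
    """Three functional samples with ids, irregular grids and a masked point."""
    rng = np.random.default_rng(7)
    out = []
    for pid, rid in [(1, 1), (1, 2), (2, 1)]:
        t = np.sort(rng.uniform(0, 1, 17))
        v = np.sin(2 * np.pi * t) + 0.1 * rng.standard_normal(17)
        mask = np.zeros(17, dtype=bool)
        if pid == 1 and rid == 2:
            mask[5] = True
        out.append(
            mw.FunctionalSample(
                participant_id=pid,
                repetition_id=rid,
                condition_id="c30M",
                times=t,
                values=v,
                missing_mask=mask,
            )
        )
    return out


def nearest_template_baseline(train, test):
    """Unwarped nearest-template classifier: assign each test curve to the
    participant whose pointwise mean training curve is closest in L2.

    All curves must share a common time grid.  Used as the comparison
    baseline for the warping classifier.
    """
    by_pid = {}
    for s in train:
        by_pid.setdefault(s.participant_id, []).append(s.values)
    templates = {pid: np.mean(v, axis=0) for pid, v in sorted(by_pid.items())}
    preds = []
    for s in test:
        dists = {pid: float(np.sum((s.values - tpl) ** 2)) for pid, tpl in templates.items()}
        preds.append(min(sorted(dists), key=lambda p: dists[p]))
    return preds
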