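import numpy as np
import pytest

from moveholdlab.io import TrialMeta, TrialRecord
from moveholdlab.synthetic import (
    BiasFieldParams,
    CohortConfig,
    ControllerParams,
    GatingMode,
    SubjectSpec,
    simulate_cohort,
)


def quiet_bias(**kw) -> BiasFieldParams:
    """Bias field with every stochastic term switched off."""
    defaults = dict(noise_sd_force=0.0, visit_jitter_sd=0.0)
    defaults.update(kw)
    return BiasFieldParams(**defaults)


def quiet_controller(**kw) -> ControllerParams:
    defaults = dict(motor_noise_sd=0.0)
    defaults.update(kw)
    return ControllerParams(**defaults)


def make_reach_meta(start, target, trial_type="reach_unperturbed", pulse_sign="none",
                    release_dir=None, trial_id="t0", **kw) -> TrialMeta:
    defaults = dict(
        subject_id="S1",
        group="control",
        arm="dominant-proxy",
        side="right",
        support="airsled",
        experiment="reach",
        block=0,
    )
    defaults.update(kw)
    return TrialMeta(
        trial_type=trial_type,
        start_pos=tuple(start),
        target_pos=tuple(target),
        pulse_sign=pulse_sign,
        release_direction_deg=release_dir,
        trial_id=trial_id,
        **defaults,
    )


def make_trial(t, x, y, fx=None, fy=None, meta=None, events=None) -> TrialRecord:
    t = np.asarray(t, dtype=float)
    z = np.zeros_like(t)
    if meta is None:
        meta = make_reach_meta((0.0, 0.0), (0.0, 10.0))
    return TrialRecord(
        meta=meta,
        t=t,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        fx=z if fx is None else np.asarray(fx, dtype=float),
        fy=z if fy is None else np.asarray(fy, dtype=float),
        events=events or {},
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """Two patients + one control, one reach block, full rest protocol."""
    cfg = CohortConfig(
        [
            SubjectSpec("P1", impairment=0.8, side="left"),
            SubjectSpec("P2", impairment=0.3, side="right"),
            SubjectSpec("C1", group="control", impairment=0.0, side="right"),
        ],
        arms=("paretic",),
        n_exp2_blocks=1,
        n_exp1_positions=15,
    )
    return simulate_cohort(cfg, seed=7)
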