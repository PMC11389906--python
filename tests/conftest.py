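import warnings

import numpy as np
import pandas as pd
import pytest

from pdacstack.simulate import PDAC, SimulationConfig, generate_cohort

warnings.filterwarnings("ignore", message="complete separation")
warnings.filterwarnings("ignore", message="SMOTE needs")


def two_by_two(case_exp, case_unexp, ctrl_exp, ctrl_unexp):
    """Design/outcome arrays for a 2x2 exposure-disease table."""
    x = np.r_[
        np.ones(case_exp), np.zeros(case_unexp), np.ones(ctrl_exp), np.zeros(ctrl_unexp)
    ]
    y = np.r_[np.ones(case_exp + case_unexp), np.zeros(ctrl_exp + ctrl_unexp)]
    return np.column_stack([np.ones_like(x), x]), y


def small_config(classes, n_per_class, n_cases, panel, effect_map=None, **kw):
    stage = {"I": 0, "II": 0, "III": 0, "IV": 0, "unknown": 0}
    left = n_cases
    for s in ("II", "IV", "III", "I", "unknown"):
        take = min(left, max(1, n_cases // 4))
        stage[s] = take
        left -= take
        if left == 0:
            break
    stage["II"] += left
    return SimulationConfig(
        n_per_control_class={c: n_per_class for c in classes},
        n_cases=n_cases,
        stage_counts=stage,
        marker_panel=list(panel),
        elisa_markers=[m for m in panel if m in ("CA19-9", "IL6ST", "VWF", "PKM2", "THBS2")],
        effect_map=effect_map or {},
        **kw,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (539 samples, 97 markers)."""
    return generate_cohort(SimulationConfig(), seed=11)


@pytest.fixture()
def tiny_cohort():
    """Three control classes + cases, 6 markers, with planted case signal."""
    panel = ["M1", "M2", "M3", "M4", "CA19-9", "VWF"]
    cfg = small_config(
        ["Healthy", "Chronic Pancreatitis", "Gallstone Disease"],
        n_per_class=18,
        n_cases=18,
        panel=panel,
        effect_map={("CA19-9", PDAC): 1.6, ("M1", PDAC): 1.2},
    )
    cfg.batch_model.offset_sd = 0.05  # keep batch structure from masking signal
    return generate_cohort(cfg, seed=7)


@pytest.fixture()
def null_xy():
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(40, 5)), columns=[f"f{i}" for i in range(5)])
    y = np.r_[np.zeros(24, int), np.ones(16, int)]
    return X, y
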