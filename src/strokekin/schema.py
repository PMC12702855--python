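"""Channel and feature naming conventions shared by every stage.

The hand-to-mouth (HTM) task is analysed over four upper-limb degrees of
freedom (elbow flexion/extension ``elb``, shoulder elevation ``elv``,
shoulder internal/external rotation ``rot``, shoulder flexion ``fle``) and
seven muscles (brachioradialis ``BR``, biceps brachii ``BB``, lateral
triceps ``TRL``, anterior/middle/posterior deltoid ``AD``/``MD``/``PD``,
pectoralis major ``PM``).  Per phase p in 1..4 the biomarker set is:

* ``W_<elem>_<p>``   mechanical work (J), elem one of the 11 channels
* ``S_<elem>_<p>``   spectral-arc-length smoothness (dimensionless, <= 0)
* ``CCI_<pair>_<p>`` co-contraction index in [0, 1] for 4 muscle pairs
* ``IC_elb_elv_<p>`` elbow/shoulder-elevation angle correlation in [-1, 1]
* ``TD_<p>``         peak trunk (sternum) displacement (cm)

which yields (11 + 11 + 4 + 1 + 1) * 4 = 112 features.
"""

from __future__ import annotations

JOINTS = ("elb", "elv", "rot", "fle")
MUSCLES = ("BR", "BB", "TRL", "AD", "MD", "PD", "PM")
ELEMENTS = JOINTS + MUSCLES
CCI_PAIRS = (("AD", "PD"), ("TRL", "BB"), ("MD", "PM"), ("TRL", "BR"))
PHASES = (1, 2, 3, 4)
PHASE_NAMES = {
    1: "Reach to object",
    2: "Transfer to mouth",
    3: "Transfer to object",
    4: "Return to start",
}


def feature_names() -> list[str]:
    """The 112 biomarker names in the documented fixed order (family-major)."""
    names: list[str] = []
    names += [f"W_{e}_{p}" for e in ELEMENTS for p in PHASES]
    names += [f"S_{e}_{p}" for e in ELEMENTS for p in PHASES]
    names += [f"CCI_{a}_{b}_{p}" for a, b in CCI_PAIRS for p in PHASES]
    names += [f"IC_elb_elv_{p}" for p in PHASES]
    names += [f"TD_{p}" for p in PHASES]
    return names


FEATURE_NAMES = tuple(feature_names())
N_FEATURES = len(FEATURE_NAMES)  # 112

#: Trial CSV column order (header mandatory; SI units, angles in degrees).
TRIAL_COLUMNS = (
    ["t"]
    + [f"wrist_{ax}" for ax in "xyz"]
    + [f"sternum_{ax}" for ax in "xyz"]
    + [f"ang_{j}" for j in JOINTS]
    + [f"vel_{j}" for j in JOINTS]
    + [f"tau_{j}" for j in JOINTS]
    + [f"F_{m}" for m in MUSCLES]
    + [f"v_{m}" for m in MUSCLES]
)

MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "cohort",
    "impairment",
    "fma_ul",
    "trial_1",
    "trial_2",
    "trial_3",
    "trial_4",
    "trial_5",
)

FEATURE_TABLE_META = ("subject_id", "group", "cohort", "fma_ul")
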