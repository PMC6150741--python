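"""Canonical 46-feature registry.

Single source of truth for feature names, class membership and output order.
The panel spans seven classes: global first-order histogram (7) and
model-based fractal (4) features, local second-order GLCM (12) and GLDM (3)
features, and local-regional high-order NGTDM (4), gray-level run-length (7)
and gray-level zone-size (9) features.  Every feature named in the underlying
study is present; remaining slots are filled from the classical panels of
each family (Haralick, Galloway/Chu, Thibault) and documented as such.
"""

from __future__ import annotations

from .features.fractal import FRACTAL_FEATURES
from .features.higher_order import GLRL_FEATURES, GLZSM_FEATURES, NGTDM_FEATURES
from .features.histogram import HISTOGRAM_FEATURES
from .features.second_order import GLCM_FEATURES, GLDM_FEATURES

#: class name -> ordered feature names; classes ordered as in the output tables
FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "histogram": HISTOGRAM_FEATURES,
    "fractal": FRACTAL_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "glrl": GLRL_FEATURES,
    "glzsm": GLZSM_FEATURES,
}

#: classes summarizing the whole-tumor distribution vs local-regional structure
GLOBAL_CLASSES = ("histogram", "fractal")
SECOND_ORDER_CLASSES = ("glcm", "gldm")
HIGH_ORDER_CLASSES = ("ngtdm", "glrl", "glzsm")

ALL_FEATURES: tuple[str, ...] = tuple(
    name for names in FEATURE_CLASSES.values() for name in names
)

N_FEATURES = len(ALL_FEATURES)
assert N_FEATURES == 46, f"feature registry must hold 46 features, has {N_FEATURES}"
assert len(set(ALL_FEATURES)) == N_FEATURES, "feature names must be unique"


def feature_class(name: str) -> str:
    for cls, names in FEATURE_CLASSES.items():
        if name in names:
            return cls
    raise KeyError(f"unknown feature {name!r}")
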