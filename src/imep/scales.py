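"""Published IMEP scale constants, shipped as packaged JSON resources.

These are the constants derived on the original 75-child cohort: the
inversion constants (cte = 350 for SLB, 300 for TBT, 80 for YBT), the
demographic correction-factor regressions, and the adjusted-score ranges
used in the min-max rescale. Loading one gives a :class:`ScaleDefinition`
that scores new children exactly as the published web application does.
"""

from __future__ import annotations

import json
from importlib import resources

from imep.types import ScaleDefinition

_FILES = {"SLB": "slb_scale.json", "TBT": "tbt_scale.json", "YBT": "ybt_scale.json"}


def published_scale(test_type: str) -> ScaleDefinition:
    """Return the published scale for one test ("SLB", "TBT" or "YBT")."""
    try:
        fname = _FILES[test_type]
    except KeyError:
        raise ValueError(f"no published scale for test_type {test_type!r}") from None
    payload = json.loads(
        resources.files("imep.data").joinpath(fname).read_text(encoding="utf-8")
    )
    return ScaleDefinition(**payload)


def published_scales() -> dict[str, ScaleDefinition]:
    """All three published scales keyed by test type."""
    return {t: published_scale(t) for t in _FILES}
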