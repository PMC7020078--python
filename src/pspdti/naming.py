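"""Feature-name grammar for regional diffusion percentile features.

A feature name is ``{METRIC}{PCTL}_{label_code}``, e.g. ``MD50_PhG_L_6_1``:
the 50th percentile of mean diffusivity over the voxels of atlas region
``PhG_L_6_1`` (left parahippocampal gyrus, subregion 6/1 in the
modified-cytoarchitecture labelling). Label codes may contain further
underscores (``FA10_VM_Put_R``), so parsing splits on the first underscore
after the metric/percentile prefix only.
"""

from __future__ import annotations

import re
from typing import NamedTuple

METRICS = ("FA", "MD")

_NAME_RE = re.compile(r"^(FA|MD)(\d{1,2})_(.+)$")


class FeatureName(NamedTuple):
    """Parsed feature name: diffusion metric, percentile, atlas label code."""

    metric: str
    percentile: int
    label_code: str


def render_feature_name(metric: str, percentile: int | float, label_code: str) -> str:
    """Render a (metric, percentile, label_code) triple into the canonical name."""
    if metric not in METRICS:
        raise ValueError(f"unknown diffusion metric {metric!r}; expected one of {METRICS}")
    pctl = int(percentile)
    if pctl != percentile or not 0 < pctl < 100:
        raise ValueError(f"percentile must be an integer in (0, 100), got {percentile!r}")
    if not label_code or label_code.startswith("_"):
        raise ValueError(f"invalid atlas label code {label_code!r}")
    return f"{metric}{pctl}_{label_code}"


def parse_feature_name(name: str) -> FeatureName:
    """Parse a feature column name back into its components.

    Raises ``ValueError`` for names outside the grammar (covariate columns
    such as ``age`` or ``protocol_B`` do not parse, which is how they are
    told apart from imaging features).
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"{name!r} does not follow the METRIC+PCTL_label grammar")
    metric, pctl, code = m.group(1), int(m.group(2)), m.group(3)
    if not 0 < pctl < 100:
        raise ValueError(f"{name!r}: percentile {pctl} outside (0, 100)")
    return FeatureName(metric, pctl, code)


def is_feature_name(name: str) -> bool:
    """True if *name* parses under the feature grammar."""
    try:
        parse_feature_name(name)
    except ValueError:
        return False
    return True
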