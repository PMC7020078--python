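"""Clinical severity scales and their normalisation conventions.

Four scales are modelled:

* ``UPDRS3`` — motor subscale of the Unified Parkinson's Disease Rating
  Scale, 0-108 points.
* ``PIGD`` — postural instability and gait disorder score (sum of UPDRS
  items 13, 14, 15, 29, 30), integer 0-20. The only scale where missing
  values are tolerated.
* ``MHY`` — modified Hoehn and Yahr stage, 1 to 5 in half steps. Ordinal at
  generation, treated as numeric during regression.
* ``LEDD`` — levodopa equivalent daily dose, mg/day, unbounded above.

Percent errors (MAE%) are normalised by the scale maximum for bounded
scales and by the per-subject observed value for LEDD, which has no fixed
ceiling. Both conventions are explicit in :class:`ScaleSpec` so either can
be forced.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleSpec:
    """One clinical scale: name, range and MAE% denominator convention."""

    name: str
    kind: str  # "bounded" | "unbounded"
    minimum: float = 0.0
    maximum: float | None = None  # bounded scales only
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("bounded", "unbounded"):
            raise ValueError(f"scale kind must be bounded/unbounded, got {self.kind!r}")
        if self.kind == "bounded" and (self.maximum is None or self.maximum <= 0):
            raise ValueError(f"bounded scale {self.name} needs a positive maximum")


SCALES: dict[str, ScaleSpec] = {
    "UPDRS3": ScaleSpec("UPDRS3", "bounded", 0.0, 108.0),
    "PIGD": ScaleSpec("PIGD", "bounded", 0.0, 20.0, allow_missing=True),
    "MHY": ScaleSpec("MHY", "bounded", 1.0, 5.0),
    "LEDD": ScaleSpec("LEDD", "unbounded", 0.0, None),
}

SCALE_NAMES = tuple(SCALES)


def get_scale(name: str) -> ScaleSpec:
    try:
        return SCALES[name]
    except KeyError:
        raise KeyError(f"unknown clinical scale {name!r}; known: {sorted(SCALES)}") from None
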