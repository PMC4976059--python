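"""Reference study conditions: three sequential-scan cases.

Each case bundles a scan schedule (hours post-mortem) with the linear
trends of combined lateral-ventricle volume (ml) and mean CSF attenuation
(HU) against the post-mortem interval, as published for three sequentially
scanned subjects. They are the default conditions for the synthetic phantom
and for parameter-recovery studies. ``se`` is the reported standard error
of the slope and ``r2`` the coefficient of determination of the original
fit. Default simulation noise levels (0.5 ml, 0.8 HU) are this package's
own choices for measurement scatter, not reported values.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Trend:
    slope: float
    intercept: float
    se: float
    r2: float


@dataclass(frozen=True)
class ReferenceCase:
    case_id: str
    schedule_h: tuple[float, ...]
    volume: Trend
    hu: Trend


#: default measurement-noise standard deviations for recovery simulations
VOLUME_NOISE_SD_ML = 0.5
HU_NOISE_SD = 0.8

REFERENCE_CASES: dict[str, ReferenceCase] = {
    "case1": ReferenceCase(
        case_id="case1",
        schedule_h=tuple(float(t) for t in range(2, 21)),
        volume=Trend(slope=-0.27, intercept=27.08, se=0.62, r2=0.98),
        hu=Trend(slope=0.23, intercept=11.12, se=0.33, r2=0.92),
    ),
    "case2": ReferenceCase(
        case_id="case2",
        schedule_h=tuple(float(t) for t in range(1, 17)),
        volume=Trend(slope=-0.16, intercept=37.45, se=0.20, r2=0.89),
        hu=Trend(slope=0.34, intercept=11.28, se=0.41, r2=0.97),
    ),
    "case3": ReferenceCase(
        case_id="case3",
        schedule_h=(1.0, 2.0, 3.0, 5.0, 6.0, 9.0, 12.0, 18.0, 24.0),
        volume=Trend(slope=-0.16, intercept=53.39, se=0.51, r2=0.87),
        hu=Trend(slope=0.42, intercept=11.74, se=1.13, r2=0.95),
    ),
}

#: combined-ventricle volumes (ml) of the worked segmentation example:
#: the first case measured at 2 h and 20 h post-mortem
WORKED_EXAMPLE_VOLUMES_ML = {2.0: 26.8, 20.0: 21.8}
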