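"""Published per-sample measurements from the ex vivo sheep heart study of
free-running Purkinje fibers that motivates this package.

Five left-ventricle samples, each containing a free-running Purkinje fiber,
its myocardial junction (PMJ) and working myocardium, were imaged with three
selected ihMT saturation protocols and sectioned for Picrosirius-red
histology.  The values below are the per-sample summary rows of that study:
ihMTR ROI means averaged over the three protocols, and histological
composition percentages averaged over slides/images.  They serve as
row-level inputs to the aggregation functions (regression fixtures and the
default compositions the synthetic histology generator emulates) — the
underlying images are not public.
"""

from __future__ import annotations

from .core import ProtocolParams

#: Per-sample mean ihMTR (%) per region, averaged over the three selected
#: protocols (samples S1..S5).
IHMTR_PER_SAMPLE: dict[str, list[float]] = {
    "free_running": [10.6, 11.9, 11.0, 14.1, 10.2],
    "pmj": [6.3, 7.7, 9.5, 13.8, 7.9],
    "myocardium": [8.1, 12.7, 13.9, 11.0, 6.5],
}

#: Per-sample histology composition (%), per measure and region.
#: total_collagen / adipocyte are area fractions of the analyzed region;
#: type1 / type3 are fractions of total collagen under polarized light.
HISTOLOGY_PER_SAMPLE: dict[str, dict[str, list[float]]] = {
    "total_collagen": {
        "free_running": [84.3, 77.7, 87.7, 49.4, 62.9],
        "pmj": [44.7, 45.5, 25.1, 16.8, 23.4],
    },
    "adipocyte": {
        "free_running": [5.7, 1.8, 0.1, 6.4, 5.1],
        "pmj": [17.0, 8.5, 20.0, 11.4, 4.8],
    },
    "type1": {
        "free_running": [93.5, 96.4, 95.7, 88.7, 91.7],
        "pmj": [87.3, 93.1, 80.0, 86.2, 81.7],
    },
    "type3": {
        "free_running": [2.2, 0.4, 0.5, 7.1, 4.6],
        "pmj": [8.6, 3.0, 9.0, 9.4, 14.1],
    },
}

#: The three saturation protocols retained after screening (Hann pulses,
#: B1RMS 9 uT over the burst repetition time).
SELECTED_PROTOCOLS: tuple[ProtocolParams, ...] = (
    ProtocolParams(name="Pr1", pw_ms=1.0, dt_ms=1.1, pulses_per_burst=12,
                   n_bursts=32, btr_ms=48.0, df_khz=20.0, b1rms_ut=9.0),
    ProtocolParams(name="Pr2", pw_ms=0.5, dt_ms=0.625, pulses_per_burst=24,
                   n_bursts=32, btr_ms=48.0, df_khz=18.0, b1rms_ut=9.0),
    ProtocolParams(name="Pr3", pw_ms=0.5, dt_ms=0.625, pulses_per_burst=60,
                   n_bursts=17, btr_ms=90.0, df_khz=18.0, b1rms_ut=9.0),
)

#: Reported temperature sensitivity of free-running-fiber ihMTR (absolute
#: ihMTR % per deg C); used as ground truth of the recovery property.
TEMPERATURE_SLOPE_PCT_PER_C: float = 0.29

#: Region-mean ihMTR (%) the default phantom prescribes for
#: (free-running fiber, PMJ, myocardium) — the across-sample study means.
DEFAULT_REGION_IHMTR: tuple[float, float, float] = (11.5, 9.0, 8.0)
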