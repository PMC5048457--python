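"""Compare measurement error under different lighting-flicker models.

Artificial light ripples at 100 Hz (twice the mains frequency); sampled
at ≤50 frames/s the ripple aliases and can interfere with the
measurement.  Each lighting preset applies its ripple depth to the same
scene and the pipeline's median error is measured against the truth.
"""

from dataclasses import replace

from pulsecam import FLICKER_PRESETS, SceneConfig
from pulsecam.evaluation import scene_error

base = SceneConfig(
    shape=(120, 160), skin_ellipse=(60, 80, 45, 60),
    duration_s=20.0, seed=12,
)

for name in ("daylight", "incandescent", "led", "fluorescent"):
    config = replace(base, flicker=FLICKER_PRESETS[name])
    rec = scene_error(config)
    print(f"{name:>13}: median delta {rec['median_delta']:.2f} beats/min "
          f"({rec['n_significant']} significant readings)")
# Daylight (no ripple) is the baseline; the 100 Hz ripple aliases far
# outside the 30–180 beats/min pass band at this frame rate, so the
# artificial sources should cost little extra error here.
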