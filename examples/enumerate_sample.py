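"""Turn detected slide events into events per mL of blood.

The volume of blood a slide represents is recovered from the number of
white blood cells the assay detects on it divided by the patient's CBC
WBC concentration; category counts over that volume give events/mL.
"""

from raresight import FrameSpec, aggregate_test, generate_frame
from raresight.pipeline import slide_profile
from raresight.simulate import WBC

wbc_cbc = 6.75  # million WBC per mL whole blood (a typical CBC value)

profiles = []
for slide in range(2):  # a test is two slides from the same draw
    stacks = []
    for frame in range(3):
        spec = FrameSpec(
            shape=(512, 512),
            counts={WBC: 120, "CK|Vim|CD45/CD31": 1, "LEV CK only": 1},
        )
        stack, _ = generate_frame(
            spec, seed=100 * slide + frame, frame_id=f"s{slide}_f{frame}"
        )
        stacks.append(stack)
    profiles.append(
        slide_profile(stacks, "patient_A", "BCa", wbc_cbc=wbc_cbc)
    )

test = aggregate_test(profiles)
ml = sum(test.ml_analyzed_per_slide)
print(f"WBCs detected per slide: {test.wbcs_detected_per_slide}")
print(f"blood analyzed: {ml:.2e} mL across {test.slides} slides")
for cat in ("CK|Vim|CD45/CD31", "LEV CK only", "total rare events"):
    print(f"{cat:25s} {test.events_per_ml[cat]:12.1f} /mL")
# Rates look enormous because three 512x512 frames hold ~360 WBCs,
# i.e. ~5e-5 mL of blood; a real slide carries ~3 million cells.
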