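"""Generate annotated synthetic pen scenes and write image + VOC XML pairs.

The generator stands in for overhead farm footage: goat-shaped blobs whose
pose encodes the behavior (lying / stand / drink / eat), a trough strip, a
water corner, and day or night lighting.  Everything is determined by the
seed.
"""

from pathlib import Path

from goatvision.formats_io import write_image, write_voc_xml
from goatvision.synthetic import PenSceneConfig, generate_pen_image

out = Path("scratch/example_scenes")
out.mkdir(parents=True, exist_ok=True)

for lighting in ("day", "night"):
    cfg = PenSceneConfig(image_size=(1280, 720), n_goats=12, density="low",
                         lighting=lighting, seed=7)
    scene = generate_pen_image(cfg)
    write_image(scene.pixels, out / f"pen_{lighting}.png")
    write_voc_xml(scene, out / f"pen_{lighting}.xml")
    counts = {}
    for b in scene.boxes:
        counts[b.cls] = counts.get(b.cls, 0) + 1
    print(f"{lighting:5s}: {len(scene.boxes)} goats, per class {counts}")

# The class mix follows the annotated farm data set's label proportions
# (lying-heavy), and the same seed always reproduces the same pens.
print(f"wrote images and VOC annotations to {out}/")
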