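"""Label-exact augmentation: vertical stitching versus mosaic.

Stitching two 1280x720 frames gives one 1280x1440 composite whose aspect
ratio is closer to the square detector input, so less of the letterboxed
canvas is wasted on gray padding — and, unlike mosaic, no label is ever cut.
"""

from goatvision.augment import (MosaicParams, gray_fill_fraction, mosaic,
                                vertical_stitch)
from goatvision.synthetic import PenSceneConfig, generate_pen_image

a = generate_pen_image(PenSceneConfig(image_size=(1280, 720), n_goats=10, seed=1))
b = generate_pen_image(PenSceneConfig(image_size=(1280, 720), n_goats=10, seed=2))

stitched = vertical_stitch(a, b)
print(f"stitched size: {stitched.size[0]}x{stitched.size[1]} "
      f"(labels {len(a.boxes)} + {len(b.boxes)} -> {len(stitched.boxes)})")
print(f"gray padding fraction at 640x640 input: "
      f"{gray_fill_fraction((1280, 720)):.4f} (single frame) vs "
      f"{gray_fill_fraction(stitched.size):.4f} (stitched)")

quads = [generate_pen_image(PenSceneConfig(image_size=(640, 360), n_goats=6,
                                           seed=10 + i)) for i in range(4)]
m = mosaic(quads, MosaicParams(out_size=(1280, 720), scale_range=(0.5, 1.5),
                               min_box_area_frac=0.25, seed=3))
n_in = sum(len(q.boxes) for q in quads)
print(f"mosaic: {n_in} input labels -> {len(m.boxes)} kept "
      f"({n_in - len(m.boxes)} lost to crop/scale clipping)")
# Stitching conserves every label; mosaic's random cropping typically loses
# a few — the behavior that motivates stitching for crowded pens.
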