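"""Scratch-assay quantification: local entropy, Otsu threshold, open-wound
percentage per timepoint, scored against the generator's wound masks."""

import imageio.v3 as iio
import pandas as pd

from common import RESULTS, default_bundle
from opsccrna.imaging import quantify_series
from opsccrna.io_core import write_table

cfg, paths = default_bundle()
images = [iio.imread(p) for p in paths["images"]]
masks = paths["truth"]["masks"]

meas = quantify_series(images, radius=5)
rows = []
for m, mask, frac in zip(meas, masks, cfg.wound_fraction_trajectory):
    rows.append(
        {
            "timepoint": m.timepoint,
            "threshold_bits": m.threshold_bits,
            "area_px": m.area_px,
            "open_wound_pct": m.open_wound_pct,
            "true_mask_px": int(mask.sum()),
            "true_fraction": frac,
        }
    )
tab = pd.DataFrame(rows).set_index("timepoint")
print(tab.round(2).to_string())
write_table(tab, RESULTS / "wound.tsv", index_label="timepoint")
print("->", RESULTS / "wound.tsv")
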