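"""Build three-class (BG / NM / M) label maps from binary lesion masks.

The Otsu route thresholds air from body and subtracts the annotated
metastasis (M) regions; the negative-mining route harvests a
positives-only model's false-positive predictions instead.
"""

import numpy as np

from scintiseg import (
    PhantomConfig,
    encode_three_class,
    generate_phantom,
    make_nm_mask_otsu,
    mine_negative_masks,
    build_double_unet,
    tiny_config,
)

ph = generate_phantom(
    PhantomConfig(view_shape=(64, 64), n_lesions=2, lesion_sigma_frac=(0.03, 0.05))
)

nm = make_nm_mask_otsu(ph.ap_view, ph.lesion_mask_ap)
labels = encode_three_class(nm, ph.lesion_mask_ap)
frac = np.bincount(labels.classes.ravel(), minlength=3) / labels.classes.size
print("Otsu route     BG/NM/M fractions: %.3f / %.3f / %.3f" % tuple(frac))

# Mining needs a model trained on positive samples; an untrained tiny model
# demonstrates the API (its 'false positives' are arbitrary).
model = build_double_unet(tiny_config(seed=0))
neg = generate_phantom(PhantomConfig(view_shape=(64, 64), n_lesions=0))
(mined,) = mine_negative_masks(model, [neg.ap_view.astype(np.float32)])
print("mined NM pixels from an untrained model:", int(mined.mask.sum()))
print("Otsu NM pixels on the same image scale: ", int(nm.mask.sum()))

# After training, mined NM regions are typically far smaller than Otsu body
# masks -- they mark only the places the model actually confuses.
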