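"""Split touching nuclei with the corrected watershed.

Renders synthetic inner/contour class score maps for a pair of touching
nuclei whose interface is mostly contour-scored but carries a mis-scored
bridge, so plain thresholding of inner-minus-contour merges the pair.  The
corrected watershed proposes a separation along the watershed line, accepts
it because the summed contour-minus-inner score along it is positive, and
recovers both nuclei; segmentation quality is summarized as F1 over IoU
thresholds against the ground-truth labels.
"""

import numpy as np

from snapcycle.seg_eval import f1_curve, match_and_score
from snapcycle.simulate import make_score_maps
from snapcycle.watershed import corrected_watershed, nuclei_from_scores

maps, truth = make_score_maps(n_nuclei=2, image_size=160, touching=True, seed=17)

merged = nuclei_from_scores(maps)
split = corrected_watershed(maps, sigma=2.5)
print(f"thresholding alone finds {merged.max()} nucleus(ei); "
      f"corrected watershed finds {split.max()}")

res = match_and_score(truth, split, t=0.6)
print(f"matching at IoU > 0.6: TP={res.tp} FN={res.fn} FP={res.fp} F1={res.f1:.2f}")

curve = f1_curve(truth, split, np.arange(0.55, 1.0, 0.1))
print("F1 over IoU thresholds:", [(round(t, 2), round(f, 2)) for t, f in curve])
# F1 = 1.0 up to high thresholds means both nuclei were found with accurate
# boundaries; the curve can only decrease as the overlap requirement tightens.
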