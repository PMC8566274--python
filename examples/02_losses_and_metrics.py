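"""Training losses and evaluation metrics on tiny hand-checkable inputs.

The squared two-way Chamfer form is the training loss; the non-squared,
mm-scale Chamfer mean and the symmetric Hausdorff distance are the
evaluation metrics.  The GMM loss scores the target points under a mixture
of Gaussians centred on the (transformed) source points, with a uniform
outlier component.
"""

import numpy as np

import freept as fp

A = np.array([[0.0, 0.0, 0.0]])
B = np.array([[3.0, 4.0, 0.0]])
print(f"Chamfer LOSS (squared, both ways) singleton pair: "
      f"{fp.chamfer_loss(A, B).data:.1f}  (= 2 * 5^2)")
print(f"Chamfer DISTANCE (mm, evaluation):                "
      f"{fp.chamfer_distance_mm(A, B):.1f}  (= 5 mm)")

cfg = fp.GMMLossConfig(sigma2=1 / (2 * np.pi), u=0.0)
print(f"GMM NLL, coincident points, sigma^2 = 1/(2*pi):   "
      f"{fp.gmm_nll_loss([[1, 2, 3]], [[1, 2, 3]], cfg).data:.4f}  (= 0)")
cfg_u1 = fp.GMMLossConfig(u=1.0)
print(f"GMM NLL, pure uniform component (u=1), 7 targets: "
      f"{fp.gmm_nll_loss(np.zeros((4, 3)), np.zeros((7, 3)), cfg_u1).data:.4f}"
      f"  (= 7 ln 7 = {7 * np.log(7):.4f})")

lm = fp.LandmarkSet([([[0, 0, 0]], [[3, 0, 0]], "apex"),
                     ([[0, 0, 0]], [[0, 4, 0]], "base")])
print(f"TRE of two pairs at 3 and 4 mm: {fp.tre_mm(lm):.4f} mm "
      f"(= sqrt((9+16)/2))")
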