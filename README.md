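# nssfuse

Pixel-level fusion of co-registered image pairs — multi-modal medical
(CT/MR/PET), multi-focus and infrared–visible — in the **nonsubsampled
contourlet transform (NSCT)** domain, with **sparse-representation** low-pass
fusion and a **Sum-Modified-Laplacian (SML)** high-pass rule.

## Who this is for

Researchers and engineers who need a transparent, fully testable
implementation of NSCT-domain fusion: medical-imaging groups combining
modalities with complementary contrast, computational-photography work
assembling all-in-focus images from focal stacks, and surveillance
applications merging infrared and visible frames.

## Method

Given registered sources `I_A`, `I_B`:

1. **Decompose.** A shift-invariant NSCT splits each source into a low-pass
   band `L` and directional band-pass bands `I^{l,k}` (level `l`, direction
   `k`; defaults: 4 levels with 4, 8, 8, 16 directions).  Every stage is a
   two-channel nonsubsampled filter bank whose kernels satisfy the Bezout
   identity `H0·G0 + H1·G1 = 1`, so the transform is exactly invertible and
   every band keeps the image size.
2. **Fuse low-pass by sparse coding.**  8×8 patches are slid over `L_A`,
   `L_B` (stride 1), vectorised and mean-removed.  The pooled patches are
   clustered jointly (k-means, k = 8) and each cluster contributes the
   smallest number *p* of PCA eigenvectors whose eigenvalue mass reaches
   δ = 0.95; concatenating the sub-dictionaries gives the aggregate
   dictionary Φ.  Each patch pair is coded over Φ with simultaneous
   orthogonal matching pursuit (shared support, residual target ε), merged by
   the **Max-L1 rule** `α_F = α_A if ‖α_A‖₁ > ‖α_B‖₁ else α_B`, rebuilt as
   `Φ α_F + v̄_F·1`, and overlap-averaged into `L_F`.
3. **Fuse high-pass by SML-MAX.**  Per band,
   `ML(i,j) = |2I − I(i−s,·) − I(i+s,·)| + |2I − I(·,j−s) − I(·,j+s)|`,
   `SML = Σ window ML²`, and the fused coefficient copies whichever source
   has the larger SML.
4. **Reconstruct.** Inverse NSCT of `(L_F, {H_F})`, clipped to [0, 1].

Quality metrics (`MI`, the gradient index `Q^{AB/F}`, Yang's structural
`Q_Y`) are included for evaluation.

## Worked example

No external data is needed — the `synth` module generates deterministic
multi-focus pairs with an all-in-focus ground truth:

```python
import numpy as np
from nssfuse import FusionConfig, SynthSpec, evaluate, fuse, make_multifocus_pair

spec = SynthSpec(size=(256, 256), blur_sigma=3.0, seed=0)
a, b, gt, mask = make_multifocus_pair(spec)   # a blurred left, b blurred right
fused = fuse(a, b, FusionConfig(seed=0))

rmse = lambda x: np.sqrt(np.mean((x - gt) ** 2))
print(f"RMSE vs ground truth  A={rmse(a):.4f}  B={rmse(b):.4f}  fused={rmse(fused):.4f}")
report = evaluate(a, b, fused)
print(f"MI={report.mi:.3f}  QAB/F={report.q_abf:.3f}  QY={report.q_y:.3f}")
```

Output:

```
RMSE vs ground truth  A=0.0609  B=0.0604  fused=0.0084
MI=5.156  QAB/F=0.786  QY=0.997
```

The fused image is ~7× closer to the all-in-focus ground truth than either
source (each source is sharp on only half the field), and scores far above
the naive averaging baseline on all three metrics (for the same pair,
averaging gives MI = 3.44, QAB/F = 0.47, QY = 0.85).

The same pipeline is available from the shell:

```sh
nssfuse synth multifocus --size 256 --seed 0 -o demo/
nssfuse fuse demo/a.png demo/b.png -o demo/fused.png
nssfuse metrics demo/a.png demo/b.png demo/fused.png
```

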