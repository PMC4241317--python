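# wtbmdu

Compressed-sensing MRI reconstruction from undersampled k-space data by a
**weighted two-level Bregman method with dictionary updating**.

Accelerated MRI acquires only a fraction ρ of the k-space (spatial
frequency) grid; naive zero-filled reconstruction then shows aliasing,
blur and noise amplification.  This package reconstructs the image by
combining three ingredients:

* a **patch-dictionary prior**: every s×s image patch `R_l u` is modeled
  as a sparse combination `D α_l` of unit-norm atoms, with the dictionary
  `D` initialized as a (possibly overcomplete) 2D DCT and adapted to the
  image during the solve;
* a **nonconvex sparsity penalty**: beyond the plain `l1` coding
  (the TBMDU baseline), the coefficients can be penalized by an
  `lp` quasi-norm (0 < p ≤ 1) approximated by iteratively reweighted `l1`
  or `l2` surrogates — weights `W = 1/(|α|^{1−p} + ε)` or
  `1/(|α|^{2−p} + ε)` computed from the previous iterate, with ε on a
  geometric continuation schedule (WTBMDU-L1 / WTBMDU-L2);
* a **two-level Bregman / augmented-Lagrangian solver**: inner
  alternating sweeps update weights, coefficients (complex
  soft-thresholding or a closed-form weighted ridge step), the auxiliary
  patch residual, the multiplier and the dictionary; a closed-form
  frequency-domain update solves the image block exactly; the outer loop
  feeds the data misfit back (`f_{k+1} = f_k + f − F_p u^{k+1}`) until
  `‖F_p u − f‖₂` reaches the noise bound σ√(2Q).

The formulation, update rules and solver composition are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import wtbmdu as w
from wtbmdu.reconstruction import SolverConfig, reconstruct

ref = w.shepp_logan(128)                                   # [0,255] phantom
mask = w.make_mask("radial", (128, 128), fraction=0.30, seed=1)
data = w.simulate_acquisition(ref, mask, sigma=0.0, seed=1)

zf = w.fourier_adjoint(data)                               # zero-filled
print(f"zero-filled:   PSNR {w.psnr(ref, zf):.2f} dB  HFEN {w.hfen(ref, zf):.1f}")

cfg = SolverConfig(variant="wtbmdu_l1", p=0.5, k_max=10)
rec, hist = reconstruct(data, cfg, reference=ref)
print(f"WTBMDU-L1 p=0.5: PSNR {hist['psnr'][-1]:.2f} dB  "
      f"HFEN {hist['hfen'][-1]:.1f}  ({hist['n_outer']} outer iterations)")
```

prints

```
zero-filled:   PSNR 20.00 dB  HFEN 523.3
WTBMDU-L1 p=0.5: PSNR 25.22 dB  HFEN 149.4  (10 outer iterations)
```

The pseudo-radial mask keeps ~30% of k-space (3.4× acceleration).  The
zero-filled image has streak artifacts (20 dB peak signal-to-noise ratio
against the ground truth; the high-frequency error norm, HFEN, measures
edge/detail fidelity — lower is better).  Ten outer Bregman iterations of
the reweighted-l1 variant recover 5.2 dB of PSNR and cut the HFEN by ×3.5.
`hist` also carries per-iteration residuals and a JSON-ready per-sweep log.

## Command line

```sh
wtbmdu simulate --phantom shepp_logan --size 128 --mask-kind radial \
       --fraction 0.3 --seed 1 --out k.h5
wtbmdu reconstruct k.h5 --variant wtbmdu_l1 --p 0.5 --outer 10 --out rec.h5
wtbmdu evaluate rec.h5 ref.h5
wtbmdu mask --kind spiral --shape 256 256 --fraction 0.2 --out mask.png
wtbmdu experiment manifest.yaml --out results/
```

Every `reconstruct` run writes a JSON manifest (input paths, full config,
seed, package version) sufficient to repeat it exactly; `experiment` runs
a simulate→reconstruct→evaluate grid from a YAML manifest and writes
per-cell metric reports plus a CSV summary.

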