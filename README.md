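# sononet

2D / 3D / (2+1)D SonoNet-style convolutional classifiers for grayscale
ultrasound video, implemented in pure NumPy (explicit forward/backward passes,
Adam, batch norm — no deep-learning framework required), together with:

- **models** — declarative layer specs + executable networks for SonoNet16/32/64
  (2D), 3D-SonoNet, and the factorised (2+1)D variants (plain, the
  parameter-matched `*` variant, and a no-mid-BN ablation);
- **audit** — closed-form and enumerated parameter counting plus MAC/FLOP
  estimation for any configuration;
- **datapipe** — exam manifests, non-overlapping constant-label clip
  extraction, matched central-frame 2D datasets, patient-disjoint splits,
  inverse-frequency weighted sampling, and clip-consistent augmentation
  (flips / gamma / resize / rotation);
- **synthdata** — a seeded synthetic exam generator (speckled background +
  elliptical phantoms over 5 protocolised scans) in which one class is
  distinguishable from background **only by its temporal pulsation**;
- **training** — Adam + weight decay, reduce-on-plateau scheduling, early
  stopping on validation loss, optional scan-prior logit masking, and a
  fixed-test-set multi-seed hold-out harness;
- **evaluation** — clip- and per-video accuracy, confusion matrices with
  class-wise mean accuracy (MA/SD), and prior-masked inference.

## CLI

```sh
# architecture audit (parameter counts both ways + MAC estimate)
sononet audit --variant 2d --base 32 --classes 7 --input 64x64 --json audit.json
sononet audit --variant 2p1d-star --base 32 --clip-len 10

# synthetic data -> clips -> split -> train -> eval
sononet synth --patients 20 --seed 0 --size 64 --out data/
sononet clips --manifest data/manifest.json --clip-len 10 --out clips.csv
sononet split --manifest data/manifest.json --test-frac 0.15 --seed 0 --out split.json
sononet train --manifest data/manifest.json --split split.json --variant 3d \
    --base 8 --clip-len 10 --out runs/3d
sononet eval --checkpoint runs/3d/checkpoint.npz --manifest data/manifest.json \
    --split split.json --clip-len 10 --priors data/priors.json --per-video --out report/
```

Variants: `2d`, `3d`, `2p1d`, `2p1d-star`; `--no-mid-bn` reproduces the
no-intermediate-BN ablation of the factorised blocks.

## Notes

- Parameter counts reproduce the published table exactly for the 2D variants
  (930,334 / 3,715,630 / 14,851,150) and the 3D variant (11,070,574). The
  published (2+1)D rows are not exactly derivable from the stated
  construction; the plain rule (mid-width = output width) gives 5,077,678
  (within 0.33% of the printed 5,094,381) and the `*` rule gives 11,077,504
  (within 0.1% of both the 3D count and the printed value).
- FLOP figures are reported as 2 × MACs with pooling/BN/activations excluded;
  the published G-FLOPS column's input resolution and convention are unstated,
  so no equality is asserted.
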