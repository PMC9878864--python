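# specunmix

Automated spectral unmixing of multispectral fluorescence images.

Multiplex fluorescence assays — 4-plex smFISH with spectrally adjacent Opal
dyes, a DAPI nuclear stain, and (in post-mortem human brain) pervasive
lipofuscin autofluorescence — are acquired as *lambda stacks*: 4-D images
(x, y, z, wavelength band) recording each voxel's emission spectrum across
~32 narrow bands. Because fluorescent emissions mix linearly, the stack
factorizes as

    F = S A

with F the C×n matrix of band intensities over n pixels, S the C×k matrix
of per-source emission signatures ("fingerprints" / endmembers), and A the
k×n per-pixel abundances. `specunmix` is a toolbox for biologists and image
analysts who need this factorization without proprietary microscope
software, at batch scale, with autofluorescence handled as just another
channel:

* **Endmember extraction** — vertex component analysis (VCA) finds the
  fingerprints automatically, from single-positive stacks (k = 2:
  fluorophore + background per slide) or from one multiplex stack in a
  single run; no manual pixel picking. Reference fingerprints can also be
  loaded from CSV.
* **Abundance estimation** — three solvers: exact fully constrained least
  squares (FCLSU: a ≥ 0, Σa = 1, active-set, vectorized over pixels), the
  extended linear mixing model (ELMM: per-pixel scalar scaling of each
  endmember), and its generalization (GELMM: per-pixel per-band scaling
  with smoothness across bands).
* **Reconstruction & metrics** — per-fluorophore intensity stacks
  (OME-TIFF), float abundance maps, a binary lipofuscin mask for downstream
  autofluorescence masking, and RMSE / SSIM / Dice comparison tables.
* **Synthetic ground truth** — a generator that renders realistic lambda
  stacks (dual-peaked DAPI, four Opal-like dyes with long red tails, broad
  lipofuscin, calibrated SNR) with exact per-pixel truth, so the whole
  pipeline is testable at desk scale.

Everything is deterministic: one master seed, per-image seeds derived from
image names, byte-identical outputs on rerun, batch results independent of
file order and worker count.

## Worked example

Simulate a six-member scene, unmix it with FCLSU against the generator's
panel, and score the result against the known truth:

```python
import specunmix as su

panel = su.make_panel()                      # DAPI, 4 Opal dyes, lipofuscin, background
scene = su.make_scene((4, 128, 128), seed=0)
stack, truth = su.render(panel, scene, noise=su.NoiseModel(target_snr_db=30), seed=1)

pixels = su.normalize_stack(stack)
abund  = su.fclsu(pixels, truth.endmembers)

for j, label in enumerate(truth.labels[:-1]):          # background not scored
    d = su.dice(abund.A[j] >= 0.1, truth.A[j] >= 0.1)  # detection threshold 0.1
    print(f"{label:12s} dice={d:.4f}")
```

Output from this exact snippet:

```
DAPI         dice=1.0000
Opal520      dice=0.9920
Opal570      dice=0.9914
Opal620      dice=0.9914
Opal690      dice=0.9891
lipofuscin   dice=0.9942
```

Every channel — including lipofuscin, treated as its own endmember — is
separated with Dice ≥ 0.99 against the ground-truth masks at 30 dB SNR.
Noise-free, the same pipeline recovers abundances to RMSE ≈ 2e-6 and Dice
exactly 1.0.

The same workflow from the shell:

```sh
specunmix simulate --shape 4 128 128 --snr-db 30 --seed 0 --out sim/
specunmix fingerprint sp_*.ome.tif --mode single_positive --labels DAPI,Opal520 --out fp.csv
specunmix unmix sim/synthetic.ome.tif --endmembers sim/synthetic_panel.csv --algorithm fclsu --out out/
specunmix evaluate --est out/synthetic --ref zen_unmixed/ --out metrics.json
specunmix batch --config runs.yaml --jobs 8
```

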