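# optoreg

Photogrammetry-based fNIRS optode registration and validation.

`optoreg` carries optode coordinates picked on a photogrammetric head
reconstruction into MNI space via a five-fiducial affine fit (nasion, inion,
Cz, left/right preauricular points), projects scalp positions onto a
cortical surface mesh, builds source–detector measurement channels, and
provides the metric suite used to validate such registrations against an
MRI-based gold standard:

- **displacement** — per-optode per-axis absolute differences and Euclidean
  distance between two registered coordinate sets;
- **composite standard deviation** — `Csd = sqrt(sdx² + sdy² + sdz²)` of a
  participant group, per optode (sample standard deviation, n−1);
- **sphere overlap** — volumetric overlap of two equal spheres (default
  radius 20 mm) centred on the channel positions from each method, in
  closed form;
- **region estimation** — Monte-Carlo tabulation of the atlas regions
  sampled by each channel (uniform ball sampling, default r = 10 mm,
  n = 10,000, nearest-voxel label lookup).

A synthetic-data module generates ellipsoid heads with fiducials, a
6-source/12-detector cap yielding exactly 23 channels at 28 mm separation,
parcellation volumes with analytically known geometry, and multi-participant
sessions with placement jitter, an MRI "supine shift", and photo-frame
measurement noise under a known ground-truth affine — so the whole pipeline
is testable end to end without any external download.

## Command-line usage

All commands accept `--config cfg.json` (flags override config values),
log to stderr (`--quiet` to silence), and write CSV reports with a `#`
metadata header. Exit codes: 0 success, 1 computational failure, 2 input
validation failure.

```sh
# generate a synthetic dataset (meshes, landmarks, per-participant sessions)
optoreg simulate --out-dir data --participants 5 --seed 1

# fit the landmark affine and carry optodes into MNI space
optoreg register --landmarks data/P01/por_pre_landmarks.csv \
    --optodes data/P01/por_pre_optodes.csv \
    --template-landmarks data/template_landmarks.csv --out-dir out/P01

# project registered positions onto a cortical surface
optoreg project --points out/P01/optodes_mni.csv --cortex data/cortex.ply \
    --method closest --out out/P01/cortical.csv

# build the channel table (cortical midpoints if a cortex is given)
optoreg channels --optodes data/cap_optodes_mni.csv \
    --cortex data/cortex.ply --sep 28 --tol 0.2 --out out/channels.csv

# compare two registrations: displacement, axis summary, overlap, Csd
optoreg compare --a out/P01/optodes_mni.csv --b data/P01/mri_optodes.csv \
    --out-dir out/cmp

# Monte-Carlo region estimation against a label volume
optoreg regions --channels out/channels_points.csv --atlas data/atlas.nii \
    --labels data/atlas_labels.json --r 10 --n 10000 --seed 1 \
    --out out/regions.csv
```

Passing `--a` twice to `compare` averages the two coordinate sets before
comparison (how pre- and post-MRI photo sessions are combined).

## File formats

- Meshes: triangular PLY (ASCII or binary little-endian) or OBJ; quads are
  rejected.
- Landmarks: CSV `name,x,y,z` with exactly nasion, inion, cz, lpa, rpa.
- Optodes: CSV `id,role,x,y,z` with role in {source, detector}.
- Point tables: CSV `id,x,y,z`. Atlas: NIfTI integer label volume plus a
  JSON `{label-id: region-name}` map (label 0 is background).
- All coordinates are millimetres; MNI axes: x left-negative, y
  anterior-positive, z dorsal-positive.

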