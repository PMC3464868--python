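# cinestrain

Global myocardial strain from routine cine cardiac image sequences.

Quantifying how much the heart muscle shortens during contraction (strain)
normally requires dedicated acquisitions (tagging) or ultrasound speckle
tracking. Two approaches work directly on standard bright-blood cine images:

* **Endocardial border delineation (EBD)** — the operator marks sparse
  points on the blood–muscle border in every frame; the border is densified
  by shape-preserving piecewise cubic Hermite interpolation, its length is
  measured as the sum of Euclidean point distances, and global Lagrangian
  strain follows

  ε = 100% · (L − L₀) / L₀

  with L₀ the maximal (end-diastolic) and L the current border length. Peak
  global strain is reported as an absolute value.

* **Feature tracking (FT)** — the border is drawn on a single frame only
  and followed automatically through the cycle by combining 2-D template
  matching on local brightness features (normalised cross-correlation,
  sub-pixel peak localisation), 1-D refinement perpendicular to the border
  onto the blood–muscle edge, spatial smoothing along the contour, and
  cyclic drift compensation. Global longitudinal and circumferential strain
  are the border-length strain of the tracked contour; radial strain uses
  point displacement toward the cavity centroid; segmental strain applies
  the same formula per equal-arc-length segment.

The package is aimed at researchers who want to compute, validate, or
compare these strain measures without patient data: it ships a deforming
synthetic phantom (short-axis ring and four-chamber U geometries) whose
deformation — and therefore strain — is known in closed form, plus the
agreement statistics used to compare strain methods (Bland–Altman bias with
limits at ±2 SD of the paired differences, and the coefficient of
variability COV = 100 · SD(differences) / grand mean). An analytic
truncated-cone model demonstrates why through-plane motion makes
circumferential strain read low on fixed imaging planes.

## Worked example

Generate a 25-phase ring phantom with 20% true circumferential shortening
and moderate noise, then measure the strain with both methods:

```sh
cinestrain phantom --strain 20 --noise-sd 0.05 --seed 5 --out demo/ph
# phantom written to demo/ph.npz (truth peak 20.00%)

cinestrain ebd --contours demo/ph_truth_contours.csv --out demo/ebd
# peak global strain 20.00% (reference frame 0)

cinestrain track --cine demo/ph.npz --init-contour demo/ph_truth_contours.csv \
    --direction circumferential --segments 6 --out demo/ft
# circumferential peak strain 19.81%
```

EBD on the (noise-free) truth contours recovers the prescribed 20% exactly;
the feature tracker, working only on the rendered noisy images from a
single initial contour, lands within 0.2 strain-points. Each command also
writes per-frame strain curves (`*_strain.csv`), tracked contours and JSON
summaries.

The same comparison at suite scale — 20 phantoms spanning strains of
10–25% and noise levels 0–0.1, alternating both geometries:

```sh
cinestrain validate --seed 1 --out demo/run
# 20 phantoms: FT max |error| 0.74 strain-points, EBD-vs-FT COV 1.34%
```

Python API equivalents live in `cinestrain` (`make_phantom`,
`interpolate_border`, `ebd_strain`, `track_contour`, `ft_global_strain`,
`ft_segmental_strain`, `bland_altman`, `cov`, `simulate_out_of_plane`,
`run_validate`); see `docs/methods.md` for the models and parameter
choices.

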