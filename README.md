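# lanthakit

Analysis toolkit for protein-based lanthanide MRI contrast agents: a
fusion construct whose parvalbumin EF-hand domain carries Gd³⁺ for T1
contrast while an IgG-binding Z domain targets the agent to antibody-
decorated cells. The package reimplements the full quantitative chain
such a study needs, as a tested library plus numbered analysis drivers:

* **Binding equilibria** (`lanthakit.binding`) — mass-action speciation
  of a two-site metal-binding protein (high-affinity EF site, ~5.5×
  weaker CD site) with competing metals (Tb³⁺, Gd³⁺, Ca²⁺) and
  chelators (NTA), a weighted terbium-luminescence signal model, and the
  Cheng–Prusoff conversions between apparent and true dissociation
  constants:
  `K_app = K_D(1 + [competitor]/K_D,competitor)` and its transposition.
* **Titration fitting** (`lanthakit.fitting`) — Hill, hyperbolic
  competition `I([M]) = I_∞ + (I_0 − I_∞)·K_app/(K_app + [M])`, the
  depletion-exact one-site anisotropy isotherm, normalise-and-invert
  preprocessing, and first-derivative melting-point extraction.
* **Relaxometry** (`lanthakit.relaxometry`) — T1 from the
  inversion-recovery nulling time (`T1 = −T_I(0)/ln 0.5`), relaxivity
  `r1 = (1/T1 − 1/T1,buffer)/c(Gd³⁺)` with per-field summaries, NMRD
  profile referencing, the receptor-density detectability model, and
  voxel-volume arithmetic.
* **Trajectory analysis** (`lanthakit.trajectory`) — first-shell water
  counting (3.4 Å cutoff), COM/minimum inter-domain distances, RMSF,
  Kabsch-superposed RMSD, and greedy neighbour-count conformer
  clustering at a 1.7 Å RMSD cutoff.
* **Synthetic data** (`lanthakit.synthetic`) — seeded generators that
  are the exact forward models of the analyses plus Gaussian noise, so
  every stage is testable without laboratory data.
* **Pipeline & CLI** (`lanthakit.pipeline`, `lanthakit.cli`) —
  end-to-end runs (generate/read → fit → convert → report) and a
  `lanthakit` command with `simulate`, `fit`, `convert-kd`,
  `relaxometry` and `traj` subcommands.

## Worked example

Convert the apparent dissociation constant of the Gd³⁺ displacement
titration (4 µM protein + 10 µM Tb³⁺ titrated with Gd³⁺, fitted
midpoint K_app = 25 µM; Tb³⁺ EF-site affinity 3 × 10⁻¹³ M):

```pycon
>>> from lanthakit import cheng_prusoff_true_kd
>>> cheng_prusoff_true_kd(kapp=25e-6, competitor_conc=10e-6, competitor_kd=3e-13)
7.499999775000005e-13
```

i.e. a true protein:Gd³⁺ affinity of ~7 × 10⁻¹³ M — the 25 µM midpoint
is inflated by a factor ≈ 1 + [Tb³⁺]/K_D,Tb over the true constant.
The same call with K_app = 83 µM (Ca²⁺ displacement) gives
2.49 × 10⁻¹² M, so Gd³⁺ binds a factor 83/25 ≈ 3.3 more strongly than
Ca²⁺. Or from the shell:

```sh
$ lanthakit convert-kd --eq 2 --kapp 25e-6 --competitor-conc 10e-6 --competitor-kd 3e-13
{"true_kd_titrator_M": 7.499999775000005e-13, "kapp_M": 2.5e-05, "competitor_conc_M": 1e-05}
```

The numbered drivers under `analysis/` run the whole chain on synthetic
inputs (written to `scratch/inputs/`, summaries to `results/`):

```sh
$ python analysis/01_simulate_inputs.py
$ python analysis/02_metal_affinities.py
Gd3+: fitted K_app = 2.481e-05 M -> true KD = 7.44e-13 M
Ca2+: fitted K_app = 8.037e-05 M -> true KD = 2.41e-12 M
Gd3+ binds a factor 3.2 more strongly than Ca2+ (ratio of apparent KDs)
$ python analysis/04_relaxometry.py
1.5 T: r1 = 50.9 +/- 0.7 s^-1 mM^-1 (3 wells)
3.0 T: r1 = 25.1 +/- 0.2 s^-1 mM^-1 (3 wells)
7.0 T: r1 = 8.8 +/- 0.1 s^-1 mM^-1 (3 wells)
cell-averaged receptor concentration: 0.32 - 2.44 uM (1.6e6 receptors / 25 um cell to 2.6e6 / 15 um)
imaging voxel: 0.75 mm^3 (0.5 x 0.5 x 3 mm)
$ python analysis/05_trajectory.py
water coordination over 2000 frames: one water 62.1%, two waters 33.7%, >=1 water 95.8% of frames
inter-domain COM distance: 35.0 +/- 3.9 A
clustering 50 conformers at 1.7 A RMSD: 2 clusters, sizes [25, 25]
```

The fitted apparent constants recover the generator ground truth (25
and 83 µM) within the 2% noise level, and the relaxivity summaries
recover each field's ground-truth r1 from nothing but the
inversion-recovery nulling times.

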