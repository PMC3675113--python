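#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under scratch/inputs/:
  * Gd3+ and Ca2+ displacement titrations of 10 µM Tb3+ (probe-depletion-
    free regime) with 2% amplitude noise,
  * an antibody-binding anisotropy titration of a 120 nM labelled probe
    (true KD 470 nM),
  * inversion-recovery series for three sample wells plus buffer at each
    of 1.5, 3 and 7 T, consistent with one ground-truth r1 per field,
  * a 2000-frame toy ion/water/domain trajectory,
  * a 50-conformer set with two planted structural clusters.
"""

import json
from pathlib import Path

import numpy as np

from lanthakit.binding import BindingSystem, MixtureSpec, cheng_prusoff_true_kd
from lanthakit.io import write_ir_series, write_titration_table, write_xyz_trajectory
from lanthakit.synthetic import (
    GeneratorSpec,
    gen_anisotropy_titration,
    gen_competition_titration,
    gen_conformer_set,
    gen_ir_series,
    gen_toy_trajectory,
    log_grid,
)

SEED = 20260922
OUT = Path(__file__).resolve().parent.parent / "scratch" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

TB_CONC, TB_KD = 10e-6, 3e-13
GROUND_TRUTH = {
    "kapp_Gd_M": 25e-6,
    "kapp_Ca_M": 83e-6,
    "anisotropy_kd_M": 470e-9,
    "probe_total_M": 120e-9,
    "r1_by_field": {"1.5": 50.6, "3.0": 24.9, "7.0": 8.8},
    "t1_buffer_by_field_ms": {"1.5": 3100.0, "3.0": 3300.0, "7.0": 3500.0},
    "conc_gd_mM": [0.0395, 0.0197, 0.0099],
    "seed": SEED,
}

# --- displacement titrations -------------------------------------------------
for i, (metal, kapp) in enumerate((("Gd3+", 25e-6), ("Ca2+", 83e-6))):
    kd_true = cheng_prusoff_true_kd(kapp, TB_CONC, TB_KD)
    system = BindingSystem.two_site({"Tb3+": TB_KD, metal: kd_true})
    curve = gen_competition_titration(
        system, MixtureSpec(10e-9, {"Tb3+": TB_CONC}), metal,
        log_grid(kapp, 1.5, 25), spec=GeneratorSpec(seed=SEED + i, noise_sd=0.02),
    )
    write_titration_table(OUT / f"displacement_{metal[:2]}.csv", curve)
    print(f"wrote displacement titration for {metal} (true KD {kd_true:.2e} M)")

# --- anisotropy titration ----------------------------------------------------
aniso = gen_anisotropy_titration(
    470e-9, 120e-9, np.linspace(1e-9, 3e-6, 25),
    spec=GeneratorSpec(seed=SEED + 2, noise_sd=0.02),
)
write_titration_table(OUT / "anisotropy_antibody.csv", aniso)
print("wrote anisotropy titration (true KD 470 nM)")

# --- inversion-recovery wells ------------------------------------------------
for j, (field, r1) in enumerate(((1.5, 50.6), (3.0, 24.9), (7.0, 8.8))):
    t1_buffer = GROUND_TRUTH["t1_buffer_by_field_ms"][str(field)]
    for k, conc in enumerate(GROUND_TRUTH["conc_gd_mM"]):
        t1 = 1000.0 / (r1 * conc + 1000.0 / t1_buffer)
        series = gen_ir_series(
            t1, field=field, conc_gd=conc, label=f"{field}T_well{k}",
            spec=GeneratorSpec(seed=SEED + 10 * j + k, noise_sd=0.01),
        )
        write_ir_series(OUT / f"ir_{field}T_well{k}.csv", series)
    buffer_series = gen_ir_series(
        t1_buffer, field=field, conc_gd=0.0, label=f"{field}T_buffer",
        spec=GeneratorSpec(seed=SEED + 10 * j + 9, noise_sd=0.01),
    )
    write_ir_series(OUT / f"ir_{field}T_buffer.csv", buffer_series)
    print(f"wrote IR series at {field} T (ground-truth r1 {r1} s^-1 mM^-1)")

# --- trajectory and conformers ----------------------------------------------
traj = gen_toy_trajectory(n_frames=2000, spec=GeneratorSpec(seed=SEED + 50))
write_xyz_trajectory(OUT / "trajectory.xyz", traj)
print("wrote 2000-frame toy trajectory")

items, labels = gen_conformer_set(
    k_clusters=2, per_cluster=25, intra_spread=0.3, inter_sep=8.0,
    spec=GeneratorSpec(seed=SEED + 60),
)
with open(OUT / "conformers.xyz", "w") as fh:
    for idx, item in enumerate(items):
        fh.write(f"{len(item)}\n")
        fh.write(f"conformer={idx} label={labels[idx]}\n")
        for x, y, z in item:
            fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")
print("wrote 50-conformer set with two planted clusters")

(OUT / "ground_truth.json").write_text(json.dumps(GROUND_TRUTH, indent=2) + "\n")
print(f"all inputs under {OUT}")
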