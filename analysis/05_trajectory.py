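#!/usr/bin/env python
"""Trajectory post-processing: water coordination, inter-domain distances,
and conformer clustering.

Reads scratch/inputs/trajectory.xyz and conformers.xyz; writes
results/trajectory_analysis.json.
"""

import json
from pathlib import Path

from lanthakit.io import read_xyz_trajectory
from lanthakit.pipeline import RunConfig, run_traj_analysis
from lanthakit.trajectory import daura_cluster

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "scratch" / "inputs"

traj = read_xyz_trajectory(INPUTS / "trajectory.xyz")
report = run_traj_analysis(RunConfig(), traj=traj)
frac = report.results["coordination_fractions"]
print(f"water coordination over {len(traj)} frames: "
      f"one water {frac['1']:.1%}, two waters {frac['2']:.1%}, "
      f">=1 water {frac['>=1']:.1%} of frames")
com = report.results["com_distance_A"]
print(f"inter-domain COM distance: {com['mean']:.1f} +/- {com['sd']:.1f} A")

conformers = read_xyz_trajectory(INPUTS / "conformers.xyz")
items = [f.group("CA") for f in conformers.frames]
clusters = daura_cluster(items, cutoff=1.7)
sizes = {cid: len(clusters.members(cid)) for cid in clusters.centroids}
print(f"clustering {len(items)} conformers at 1.7 A RMSD: "
      f"{clusters.n_clusters} clusters, sizes {sorted(sizes.values(), reverse=True)}")

(ROOT / "results").mkdir(exist_ok=True)
out = ROOT / "results" / "trajectory_analysis.json"
out.write_text(json.dumps({
    "coordination_fractions": frac,
    "com_distance_A": com,
    "min_distance_A": report.results["min_distance_A"],
    "clustering": {"n_clusters": clusters.n_clusters,
                   "sizes": {str(k): v for k, v in sizes.items()},
                   "cutoff_A": 1.7},
}, indent=2) + "\n")
print(f"wrote {out}")
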