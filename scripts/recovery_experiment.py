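"""Bias and RMSE of inverse elasticity recovery across seeds.

Forward-simulates one P50 -> P00 transition at (E*, v*) = (5 kPa, 0.35) and
reruns the surrogate optimization under several seeds, reporting bias and
RMSE of the recovered parameters.

Usage:
    python scripts/recovery_experiment.py --seed 1 --n-seeds 5 [--out FILE]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from lungmech.ego import EGOConfig, ego_optimize, make_transition_objective
from lungmech.fem import SolverConfig, solve_displacement
from lungmech.materials import NH, Material, tumor_material
from lungmech.phantom import PhantomSpec, generate_phantom


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-seeds", type=int, default=5)
    parser.add_argument("--max-iter", type=int, default=92)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    truth_E, truth_v = 5.0, 0.35
    bundle = generate_phantom(PhantomSpec(seed=args.seed))
    m50 = bundle.mesh_for("P50")
    solver = SolverConfig(n_increments=2)
    sol = solve_displacement(m50, Material(NH, 1000.0 * truth_E, truth_v),
                             tumor_material(), bundle.boundary_field("P00"),
                             solver)
    tum = m50.submesh("tumor")
    ids = np.unique(m50.tets[m50.region == "tumor"])
    obs = tum.with_nodes(tum.nodes + sol.u[ids])
    objective = make_transition_objective(
        m50, bundle.surface_positions("P00"), obs, NH, solver_cfg=solver
    )

    E_hat, v_hat = [], []
    for k in range(args.n_seeds):
        rec = ego_optimize(objective, cfg=EGOConfig(seed=args.seed + 7 * k,
                                                    max_iter=args.max_iter))
        E_hat.append(rec.best_point[0])
        v_hat.append(rec.best_point[1])
        print(f"seed {args.seed + 7 * k}: E = {rec.best_point[0]:.3f} kPa, "
              f"v = {rec.best_point[1]:.4f} ({len(rec.evaluations)} evals)")

    E_hat, v_hat = np.array(E_hat), np.array(v_hat)
    stats = {
        "truth_E_kPa": truth_E,
        "truth_v": truth_v,
        "E_bias_kPa": float(np.mean(E_hat - truth_E)),
        "E_rmse_kPa": float(np.sqrt(np.mean((E_hat - truth_E) ** 2))),
        "v_bias": float(np.mean(v_hat - truth_v)),
        "v_rmse": float(np.sqrt(np.mean((v_hat - truth_v) ** 2))),
        "n_seeds": args.n_seeds,
    }
    print(json.dumps(stats, indent=2))
    if args.out is not None:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(json.dumps(stats, indent=2))


if __name__ == "__main__":
    main()
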