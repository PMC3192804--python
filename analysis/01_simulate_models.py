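#!/usr/bin/env python
"""Direct predictions of the candidate cost models on the bar task.

Solves the five-posture point-to-bar protocol for the default subject
under each of the eight basis costs and the hybrid (energy + angle
acceleration, 10:1) composite, and tabulates the endpoint and path
features each model predicts: reached point (RP), movement-vector angle
(MV), signed path curvature (sIPC), shoulder-elbow coupling, and the
speed-shape index.  Writes results/model_predictions.csv.

Expected pattern: joint-smoothness models produce perfectly coupled
joints (R² = 1); the hand-jerk model moves horizontally (MV ≈ 0°) along
straight paths; torque-family and energy models exploit gravity and
reach lower on the bar.
"""

from pathlib import Path

from armioc import ArmParams, CostWeights, SolverOptions
from armioc.cost_functions import BASIS_COSTS
from armioc.synthetic_data import simulate_protocol

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    params = ArmParams()
    options = SolverOptions(nodes=30, basis_size=6)
    models = {name: CostWeights.single(name) for name in BASIS_COSTS}
    models["hybrid"] = CostWeights.hybrid()
    table = simulate_protocol(models, subjects=[params], options=options)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "model_predictions.csv", index=False)
    cols = ["model", "posture", "RP", "MV_angle", "sIPC", "coupling_R2",
            "shape_index", "z_f", "status"]
    print(table[cols].to_string(index=False, float_format="%.3f"))
    ok = (table.status == "success").mean()
    print(f"\n{len(table)} model x posture cells solved "
          f"({ok:.0%} reporting clean convergence)")


if __name__ == "__main__":
    main()
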