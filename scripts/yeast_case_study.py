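#!/usr/bin/env python
"""Yeast alcoholic-fermentation case study (requires a local SBML model).

Applies the published fermentation bound recipe to a consensus yeast
genome-scale model (Yeast 5.01) supplied by the user as an SBML file:

    r_1714 (D-glucose exchange)                       lower bound  -10
    r_0438 (ferrocytochrome-c:oxygen oxidoreductase)  upper bound   10
    r_1054 (triose-phosphate isomerase)               upper bound    6
    all ±INF bounds capped to ±1000

then runs the wild-type FBA and reports the predicted ethanol and glycerol
exchange fluxes, and optionally the bi-objective (ethanol, biomass)
frontier under K deletions. The model is NOT bundled: download it from the
yeast-metabolism consensus repository and pass its path.

Usage:
    python scripts/yeast_case_study.py MODEL.xml --biomass-id r_2111 \\
        --ethanol-id r_1761 --glycerol-id r_1808 [--front -K 1]
"""

from __future__ import annotations

import argparse

from paretoflux import (
    BoundOverride,
    apply_bound_overrides,
    cap_infinite_bounds,
    knockout_candidates,
    load_model,
    solve_bop,
    solve_fba,
)

OVERRIDES = [
    BoundOverride("r_1714", "lower", -10.0),
    BoundOverride("r_0438", "upper", 10.0),
    BoundOverride("r_1054", "upper", 6.0),
]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("model", help="path to the yeast consensus SBML file")
    parser.add_argument("--biomass-id", default="r_2111", help="biomass pseudo-reaction id")
    parser.add_argument("--ethanol-id", default="r_1761", help="ethanol exchange id")
    parser.add_argument("--glycerol-id", default="r_1808", help="glycerol exchange id")
    parser.add_argument("--front", action="store_true", help="also solve the K-deletion frontier")
    parser.add_argument("-K", type=int, default=1)
    args = parser.parse_args()

    model = load_model(
        args.model,
        dialect="sbml",
        biomass_id=args.biomass_id,
        target_ids=(args.ethanol_id,),
    )
    model = apply_bound_overrides(model, OVERRIDES)
    model = cap_infinite_bounds(model, 1000.0)

    wt = solve_fba(model)
    print(f"wild-type biomass optimum : {wt.objective_value:.4g}")
    print(f"predicted ethanol flux    : {wt[args.ethanol_id]:.4g} mmol/gDW/h")
    print(f"predicted glycerol flux   : {wt[args.glycerol_id]:.4g} mmol/gDW/h")

    if args.front:
        candidates = sorted(knockout_candidates(model, wt))
        print(f"knockout candidates (nonzero reference flux): {len(candidates)}")
        front = solve_bop(model, args.K, candidates=candidates)
        print(f"frontier points (K={args.K}):")
        for p in front.points:
            print(
                f"  ethanol {p.objectives[0]:8.3f}  biomass {p.objectives[1]:7.4f}  "
                f"knockouts {';'.join(p.witness_knockouts.sorted_members())}"
            )


if __name__ == "__main__":
    main()
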