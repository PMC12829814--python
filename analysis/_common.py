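"""Shared setup for the analysis drivers: parameters, scenario, scale.

Default scale is 5 cohorts of 20,000 women (fast, qualitatively stable);
``--full`` switches to the reporting scale of 10 cohorts of 100,000.
"""

import argparse
from pathlib import Path

from simdcis import ScenarioConfig, ScreeningPolicy, load_parameters
from simdcis.synthetic_params import SyntheticSpec, generate_parameter_set

RESULTS = Path("results")


def standard_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="master seed")
    ap.add_argument("--full", action="store_true",
                    help="full scale (10 cohorts x 100,000) instead of 5 x 20,000")
    ap.add_argument("--params", type=Path, default=None,
                    help="parameter bundle YAML (default: stylized set from --seed)")
    return ap.parse_args()


def load_inputs(args: argparse.Namespace):
    if args.params is not None:
        params = load_parameters(args.params)
    else:
        params = generate_parameter_set(SyntheticSpec(seed=args.seed))
    scenario = ScenarioConfig(
        policy=ScreeningPolicy(50, 74, 2, 0.76),
        cohort_size=100_000 if args.full else 20_000,
        n_cohorts=10 if args.full else 5,
        follow_up_years=25,
        master_seed=args.seed,
    )
    RESULTS.mkdir(exist_ok=True)
    return params, scenario
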