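"""Per-fixture numerical-verification protocols.

Each protocol bundles what a repeated-refit correlation scan needs: the
simulation condition, the time grid, which parameter to sweep over which
range, and any parameter held at a known value.  Time grids span a few
dominant time constants of each model; the three-compartment scan grid
(400 points on [0, 2]) follows the fixture's published protocol, the
others are package choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .examples import builtin_example
from .model import ExperimentCondition, LinearModel, TrueParameterSet

__all__ = ["FixtureProtocol", "fixture_protocol"]


@dataclass(frozen=True)
class FixtureProtocol:
    model: LinearModel
    condition: ExperimentCondition
    true_values: TrueParameterSet
    time_points: np.ndarray
    sweep_param: sp.Symbol
    sweep_range: tuple[float, float]
    fixed: dict  # parameters held at known values during fits

    def simulate(self):
        from .simulate import simulate

        return simulate(self.model, self.true_values, self.condition, self.time_points)

    def scan(self, n_points: int = 10, seed: int | None = None, start=None):
        from .correlation import DEFAULT_SEED
        from .simulate import correlation_scan

        ds = self.simulate()
        values = np.linspace(*self.sweep_range, n_points)
        return correlation_scan(
            self.model, [ds], self.sweep_param, values,
            start=start if start is not None else self.true_values.as_dict(),
            fixed=self.fixed,
            seed=DEFAULT_SEED if seed is None else seed,
        )


def fixture_protocol(example_id: int, case: int = 0) -> FixtureProtocol:
    """Scan protocol for a built-in fixture.

    ``case`` selects among the fixture's conditions where several are
    scannable (the two-compartment model: 0 = x10 nonzero, 1 = x20
    nonzero).
    """
    if example_id == 1:
        model, conds, tv = builtin_example(1)
        if case not in (0, 1):
            raise ValueError("two-compartment protocol has cases 0 and 1")
        # case 0: p4 = 1.4 - 0.7/(1.4 - p1) on the correlation manifold
        # turns negative beyond p1 = 0.9; case 1: the (p2, p4) quadratic
        # loses real roots away from the truth -- both ranges stay on the
        # real positive section of the manifold
        sweep_range = (0.05, 0.85) if case == 0 else (0.5, 0.9)
        return FixtureProtocol(
            model=model,
            condition=conds[case],
            true_values=tv,
            time_points=np.linspace(0, 10, 100),
            sweep_param=sp.Symbol("p1"),
            sweep_range=sweep_range,
            fixed={sp.Symbol("V"): 1.0},  # scale known: y(0) fixes it
        )
    if example_id == 3:
        model, conds, tv = builtin_example(3)
        return FixtureProtocol(
            model=model,
            condition=conds[0],  # x0 = 0, u = 25
            true_values=tv,
            time_points=np.linspace(0, 2, 400),
            sweep_param=sp.Symbol("p21"),
            sweep_range=(0.7, 1.5),
            fixed={},
        )
    if example_id == 4:
        model, conds, tv = builtin_example(4)
        return FixtureProtocol(
            model=model,
            condition=conds[0],  # x0 = 0, u = 5
            true_values=tv,
            time_points=np.linspace(0, 5, 200),
            sweep_param=sp.Symbol("p43"),
            # p03 = 5 - p43 must stay positive, and the quadratic for
            # (p42, p04) (sum 7.2 - 14/p43, product 2.1) needs real roots:
            # feasible p43 is about (3.26, 5)
            sweep_range=(3.4, 4.8),
            fixed={},
        )
    raise ValueError(
        f"no scan protocol for example {example_id} (no published true values)"
    )
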