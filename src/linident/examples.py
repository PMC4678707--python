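"""Built-in compartment-model fixtures.

Five classic partially observed linear compartment models, each bundled
with the experiment conditions under which its identifiability is usually
discussed and (where published) the true parameter values used for
numerical verification.  These are the standard benchmark models of the
identifiability literature: a two-compartment exchange model observed
through a scaled first state, two three-compartment models, a
four-compartment model with two observed pools, and a five-compartment
insulin-receptor trafficking model.
"""

from __future__ import annotations

import sympy as sp

from .model import ExperimentCondition, LinearModel, TrueParameterSet

__all__ = ["builtin_example", "EXAMPLE_IDS"]

EXAMPLE_IDS = (1, 2, 3, 4, 5)

# generic condition symbols, reused across fixtures
_x10, _x20, _x30, _x40 = sp.symbols("x10 x20 x30 x40")
_u = sp.Symbol("u10")


def _example1():
    p1, p2, p3, p4, V = sp.symbols("p1 p2 p3 p4 V")
    model = LinearModel(
        name="two-compartment",
        state_names=("x1", "x2"),
        output_names=("y",),
        input_names=("u",),
        params=(p1, p2, p3, p4, V),
        A=sp.Matrix([[-(p1 + p2), p3], [p2, -(p3 + p4)]]),
        B=sp.Matrix([[1], [0]]),
        C=sp.Matrix([[1 / V, 0]]),
        D=sp.Matrix([[0]]),
    )
    conditions = [
        ExperimentCondition((15, 0), (0,)),     # x10 != 0, x20 = 0
        ExperimentCondition((0, 15), (0,)),     # x10 = 0, x20 != 0
        ExperimentCondition((15, 5), (0,)),     # both nonzero, dataset 1
        ExperimentCondition((5, 15), (0,)),     # both nonzero, dataset 2
    ]
    true = TrueParameterSet.from_mapping({p1: 0.7, p2: 0.7, p3: 1.0, p4: 0.4, V: 1.0})
    return model, conditions, true


def _example2():
    p21, p12, p13 = sp.symbols("p21 p12 p13")
    model = LinearModel(
        name="three-compartment-chain",
        state_names=("x1", "x2", "x3"),
        output_names=("y",),
        input_names=("u",),
        params=(p21, p12, p13),
        A=sp.Matrix([
            [-p21, p12, p13],
            [p21, -p12, 0],
            [0, 0, -p13],
        ]),
        B=sp.Matrix([[1], [0], [0]]),
        C=sp.Matrix([[0, 1, 0]]),  # y = x2
        D=sp.Matrix([[0]]),
    )
    conditions = [
        ExperimentCondition((_x10, _x20, 0), (_u,)),    # x30 = 0: p13 invisible
        ExperimentCondition((_x10, _x20, _x30), (_u,)),  # x30 != 0: all identifiable
    ]
    return model, conditions, None


def _example3():
    p21, p31, p12, p13, p02, p03 = sp.symbols("p21 p31 p12 p13 p02 p03")
    model = LinearModel(
        name="three-compartment-mammillary",
        state_names=("x1", "x2", "x3"),
        output_names=("y",),
        input_names=("u",),
        params=(p21, p31, p12, p13, p02, p03),
        A=sp.Matrix([
            [-(p21 + p31), p12, p13],
            [p21, -(p12 + p02), 0],
            [p31, 0, -(p13 + p03)],
        ]),
        B=sp.Matrix([[1], [0], [0]]),
        C=sp.Matrix([[1, 0, 0]]),  # y = x1
        D=sp.Matrix([[0]]),
    )
    conditions = [
        ExperimentCondition((0, 0, 0), (25,)),           # structural case, u = 25
        ExperimentCondition((_x10, _x20, _x30), (_u,)),  # remedy case, everything on
    ]
    true = TrueParameterSet.from_mapping(
        {p02: 2.0, p12: 3.0, p03: 3.0, p13: 0.4, p21: 1.0, p31: 2.0}
    )
    return model, conditions, true


def _example4():
    p31, p13, p42, p24, p43, p03, p04 = sp.symbols("p31 p13 p42 p24 p43 p03 p04")
    model = LinearModel(
        name="four-compartment",
        state_names=("x1", "x2", "x3", "x4"),
        output_names=("y1", "y2"),
        input_names=("u",),
        params=(p31, p13, p42, p24, p43, p03, p04),
        A=sp.Matrix([
            [-p31, 0, p13, 0],
            [0, -p42, 0, p24],
            [p31, 0, -(p03 + p13 + p43), 0],
            [0, p42, p43, -(p04 + p24)],
        ]),
        B=sp.Matrix([[1], [0], [0], [0]]),
        C=sp.Matrix([[1, 0, 0, 0], [0, 1, 0, 0]]),  # y1 = x1, y2 = x2
        D=sp.Matrix([[0], [0]]),
    )
    conditions = [
        ExperimentCondition((0, 0, 0, 0), (5,)),               # structural case, u = 5
        ExperimentCondition((_x10, _x20, _x30, _x40), (_u,)),  # remedy case
    ]
    true = TrueParameterSet.from_mapping(
        {p31: 3.0, p13: 5.5, p03: 1.0, p04: 0.7, p24: 3.5, p42: 3.0, p43: 4.0}
    )
    return model, conditions, true


_IR_OUTPUT_ROWS = {
    # output name -> C row over (x1..x5)
    "y1": [0, 0, 1, 1, 0],  # total phosphorylated receptor: x3 + x4
    "y2": [0, 0, 0, 1, 1],  # total internalized receptor:   x4 + x5
    "y3": [0, 1, 1, 0, 0],  # total surface-bound receptor:  x2 + x3
}


def _example5(outputs=("y1",)):
    # The receptor-binding step is bilinear in (p21, u); with a constant
    # insulin input the product acts as a single first-order rate, stored
    # here as the parameter p21p.
    p21p, p51, p12, p32, p43, p54, p15 = sp.symbols("p21p p51 p12 p32 p43 p54 p15")
    unknown = [o for o in outputs if o not in _IR_OUTPUT_ROWS]
    if unknown:
        raise ValueError(f"unknown outputs {unknown}; choose from {sorted(_IR_OUTPUT_ROWS)}")
    C = sp.Matrix([_IR_OUTPUT_ROWS[o] for o in outputs])
    model = LinearModel(
        name="insulin-receptor",
        state_names=("x1", "x2", "x3", "x4", "x5"),
        output_names=tuple(outputs),
        input_names=(),
        params=(p21p, p51, p12, p32, p43, p54, p15),
        A=sp.Matrix([
            [-(p21p + p51), p12, 0, 0, p15],
            [p21p, -(p12 + p32), 0, 0, 0],
            [0, p32, -p43, 0, 0],
            [0, 0, p43, -p54, 0],
            [0, 0, 0, p54, -p15],
        ]),
        B=sp.zeros(5, 0),
        C=C,
        D=sp.zeros(len(outputs), 0),
        metadata={
            "aliasing": "p21p stands for the product p21*u with u the constant "
            "insulin input (100 nM); the bilinear term is absorbed into a "
            "single rate parameter.",
            "available_outputs": dict(_IR_OUTPUT_ROWS),
        },
    )
    conditions = [ExperimentCondition((100, 0, 0, 0, 0), ())]
    return model, conditions, None


def builtin_example(example_id: int, *, outputs=None):
    """Return ``(model, conditions, true_values_or_None)`` for fixture 1-5.

    ``outputs`` applies to the insulin-receptor model only and selects which
    measured mixtures form C (any of "y1", "y2", "y3"; default ("y1",)).
    """
    builders = {1: _example1, 2: _example2, 3: _example3, 4: _example4}
    if example_id in builders:
        if outputs is not None:
            raise ValueError("outputs is only selectable for example 5")
        return builders[example_id]()
    if example_id == 5:
        return _example5(tuple(outputs) if outputs is not None else ("y1",))
    raise ValueError(f"unknown example id {example_id!r}; valid ids are 1..5")
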