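"""Synthetic factorial blanching/drying experiments.

The raw measurements behind the pilot-scale blueberry study this package
models are not deposited anywhere, so downstream stages (surrogate
training, optimization, reporting) are exercised against a generator that
reproduces the *published statistical structure* of the experiment: a
three-factor full factorial over blanching time (BT), infrared heating
temperature (T) and air velocity (v), with four endpoint responses —
drying time (DT, min), specific energy consumption (SEC, MJ/kg),
ascorbic-acid content (VC, mg/100 g) and rehydration capacity (RC).

The response surface is a separable multiplicative model

    r(BT, T, v) = r_a * p_BT(BT)/p_BT(BT_a) * p_T(T)/p_T(T_a) * p_v(v)/p_v(v_a)

anchored at (BT_a, T_a, v_a) = (90 s, 80 degC, 1.5 m/s), where each p is a
piecewise-linear profile through the study's published one-dimensional
slice means.  The model is exact at every published slice point by
construction; interaction structure beyond separability is deliberately
not invented.  Replicate scatter is multiplicative zero-mean Gaussian
noise with a configurable coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "FactorialDesign",
    "ResponseSurfaceSpec",
    "RESPONSES",
    "EXPERIMENT_COLUMNS",
    "factorial_design",
    "ground_truth",
    "simulate",
]

RESPONSES = ("dt_min", "sec_mj_kg", "vc_mg_100g", "rc")
EXPERIMENT_COLUMNS = ("bt_s", "t_c", "v_ms", "rep") + RESPONSES

# anchor condition of the published 1-D slices
ANCHOR = {"bt_s": 90.0, "t_c": 80.0, "v_ms": 1.5}


@dataclass(frozen=True)
class FactorialDesign:
    """Full-factorial design over the three process factors.

    Defaults reproduce the study layout: 4 blanching times x 5 temperatures
    x 4 air velocities = 80 conditions, 3 replicates each (240 rows).
    """

    bt_levels: tuple = (30.0, 60.0, 90.0, 120.0)
    t_levels: tuple = (50.0, 60.0, 70.0, 80.0, 90.0)
    v_levels: tuple = (0.01, 0.5, 1.5, 2.5)
    replicates: int = 3

    def __post_init__(self) -> None:
        for name, levels in (
            ("bt_levels", self.bt_levels),
            ("t_levels", self.t_levels),
            ("v_levels", self.v_levels),
        ):
            if len(levels) == 0:
                raise InvalidInputError(f"{name} must be nonempty")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")

    @property
    def n_conditions(self) -> int:
        return len(self.bt_levels) * len(self.t_levels) * len(self.v_levels)


def factorial_design(design: FactorialDesign) -> pd.DataFrame:
    """Enumerate the Cartesian product of factor levels.

    Deterministic ordering: BT is the outer (slowest) factor, T the middle,
    v the inner.  Returns a DataFrame with columns bt_s, t_c, v_ms.
    """
    rows = [
        (bt, t, v)
        for bt in design.bt_levels
        for t in design.t_levels
        for v in design.v_levels
    ]
    return pd.DataFrame(rows, columns=["bt_s", "t_c", "v_ms"], dtype=float)


def _profile(levels, values) -> tuple[np.ndarray, np.ndarray]:
    lv = np.asarray(levels, dtype=float)
    vv = np.asarray(values, dtype=float)
    if lv.shape != vv.shape or lv.ndim != 1:
        raise InvalidInputError("profile levels/values must be 1-D and equal length")
    if np.any(vv <= 0):
        raise InvalidInputError("profile values must be positive")
    return lv, vv


# Published slice means through the anchor condition.  Where only the
# qualitative trend was published (DT/SEC vs temperature: decreasing;
# RC vs temperature: increasing), monotone profiles anchored at the
# published 80 degC values are assumed; see docs/methods.md.
_DEFAULT_PROFILES = {
    "dt_min": {
        "bt_s": ((30, 60, 90, 120), (800.0, 670.0, 548.0, 590.0)),
        "t_c": ((50, 60, 70, 80, 90), (905.0, 760.0, 640.0, 548.0, 498.0)),
        "v_ms": ((0.01, 0.5, 1.5, 2.5), (654.0, 602.0, 548.0, 665.0)),
    },
    "sec_mj_kg": {
        "bt_s": ((30, 60, 90, 120), (7.7, 6.0, 4.9, 6.0)),
        "t_c": ((50, 60, 70, 80, 90), (7.6, 6.6, 5.7, 4.9, 4.4)),
        "v_ms": ((0.01, 0.5, 1.5, 2.5), (6.1, 5.3, 4.9, 7.1)),
    },
    "vc_mg_100g": {
        "bt_s": ((30, 60, 90, 120), (3.60, 4.33, 4.60, 3.82)),
        "t_c": ((50, 60, 70, 80, 90), (1.94, 2.83, 3.71, 4.60, 3.68)),
        # air velocity had no significant effect on VC (p > 0.05): flat
        "v_ms": ((0.01, 2.5), (4.60, 4.60)),
    },
    "rc": {
        "bt_s": ((30, 60, 90, 120), (2.34, 2.73, 3.18, 2.78)),
        "t_c": ((50, 60, 70, 80, 90), (2.58, 2.79, 2.99, 3.18, 3.31)),
        # air velocity had no significant effect on RC (p > 0.05): flat
        "v_ms": ((0.01, 2.5), (3.18, 3.18)),
    },
}

#: Process-factor bounds of the optimization problem; the generator refuses
#: to extrapolate outside them.
FACTOR_BOUNDS = {"bt_s": (30.0, 120.0), "t_c": (50.0, 90.0), "v_ms": (0.01, 2.5)}


@dataclass(frozen=True)
class ResponseSurfaceSpec:
    """Separable response surface anchored at (90 s, 80 degC, 1.5 m/s).

    profiles : per-response, per-factor (levels, values) pairs; each profile
        must pass through the anchor value at the anchor level.
    noise_cv : coefficient of variation of the multiplicative replicate
        noise (default 0.03).
    seed : generator seed for :func:`simulate`.
    """

    profiles: dict = field(default_factory=lambda: _DEFAULT_PROFILES)
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError(f"noise_cv must be >= 0, got {self.noise_cv}")
        for resp in RESPONSES:
            if resp not in self.profiles:
                raise InvalidInputError(f"missing profile for response {resp!r}")
            anchor_vals = []
            for factor in ("bt_s", "t_c", "v_ms"):
                levels, values = _profile(*self.profiles[resp][factor])
                a = float(np.interp(ANCHOR[factor], levels, values))
                anchor_vals.append(a)
            if not np.allclose(anchor_vals, anchor_vals[0], rtol=1e-9):
                raise InvalidInputError(
                    f"profiles for {resp!r} disagree at the anchor condition: "
                    f"{anchor_vals}"
                )

    def anchor_value(self, resp: str) -> float:
        levels, values = _profile(*self.profiles[resp]["bt_s"])
        return float(np.interp(ANCHOR["bt_s"], levels, values))


def ground_truth(bt, t, v, spec: ResponseSurfaceSpec | None = None) -> dict:
    """Noise-free responses at one or more (BT, T, v) conditions.

    Accepts scalars or equally-shaped arrays; returns a dict mapping each
    response name to a float (scalar inputs) or ndarray.  Conditions outside
    the factor bounds raise :class:`OutOfDomainError`-style invalid-input
    errors rather than extrapolating.
    """
    spec = spec or ResponseSurfaceSpec()
    scalar = np.isscalar(bt) and np.isscalar(t) and np.isscalar(v)
    coords = {
        "bt_s": np.atleast_1d(np.asarray(bt, dtype=float)),
        "t_c": np.atleast_1d(np.asarray(t, dtype=float)),
        "v_ms": np.atleast_1d(np.asarray(v, dtype=float)),
    }
    for factor, x in coords.items():
        lo, hi = FACTOR_BOUNDS[factor]
        if np.any(x < lo) or np.any(x > hi):
            raise InvalidInputError(
                f"{factor} out of bounds [{lo}, {hi}]; extrapolation refused"
            )
    out = {}
    for resp in RESPONSES:
        r = np.full(coords["bt_s"].shape, spec.anchor_value(resp))
        for factor, x in coords.items():
            levels, values = _profile(*spec.profiles[resp][factor])
            p = np.interp(x, levels, values)
            p_anchor = np.interp(ANCHOR[factor], levels, values)
            r = r * p / p_anchor
        out[resp] = float(r[0]) if scalar else r
    return out


def simulate(
    design: FactorialDesign | None = None,
    spec: ResponseSurfaceSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a replicated factorial experiment table.

    Each row's responses are ``ground_truth * (1 + eps)`` with
    ``eps ~ N(0, noise_cv^2)`` drawn independently per row and response and
    truncated (resampled) to keep every response positive.  ``seed``
    overrides ``spec.seed`` when given; identical seeds give identical
    tables.
    """
    design = design or FactorialDesign()
    spec = spec or ResponseSurfaceSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    conditions = factorial_design(design)
    table = conditions.loc[conditions.index.repeat(design.replicates)].reset_index(
        drop=True
    )
    table["rep"] = np.tile(np.arange(1, design.replicates + 1), len(conditions))

    truth = ground_truth(table["bt_s"], table["t_c"], table["v_ms"], spec)
    for resp in RESPONSES:
        base = truth[resp]
        noisy = base * (1.0 + spec.noise_cv * rng.standard_normal(len(table)))
        # resample the (vanishingly rare) non-positive draws
        bad = np.flatnonzero(noisy <= 0)
        while bad.size:
            noisy[bad] = base[bad] * (
                1.0 + spec.noise_cv * rng.standard_normal(bad.size)
            )
            bad = np.flatnonzero(noisy <= 0)
        table[resp] = noisy
    return table[list(EXPERIMENT_COLUMNS)]
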