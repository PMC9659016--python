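"""Feed-forward 3-n-4 surrogate network: evaluation and the published model.

A single-hidden-layer perceptron maps the three process factors
(blanching time BT in s, infrared temperature T in degC, air velocity v
in m/s) to the four drying responses (DT, SEC, VC, RC).  Inputs are
min-max scaled to [-1, 1] over the optimization bounds before entering
the network; network outputs are mapped back to physical units by a
per-response affine transform.

The module also reconstructs the *published* trained network from its
printed hidden-layer weight table and output-layer equations.  The source
study prints no input/output normalization, and its tansig-bounded output
sums cannot directly produce values like 366.7 min, so the published
network is completed here by (a) scaling inputs over the optimization
bounds and (b) calibrating the four output affine transforms once by
least squares against the published 30-row Pareto front.  The calibrated
transforms are frozen into the packaged fixture; see docs/methods.md for
the reasoning and the residuals this reconstruction achieves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import InvalidInputError, OutOfDomainError

__all__ = [
    "tansig",
    "logsig",
    "pureline",
    "activation",
    "activation_derivative",
    "AffineTransform",
    "MLPTopology",
    "NetworkWeights",
    "forward",
    "published_network",
    "calibrate_output_transforms",
    "INPUT_BOUNDS",
]

#: Optimization-problem bounds for (BT, T, v); also the input-scaling domain.
INPUT_BOUNDS = np.array([[30.0, 120.0], [50.0, 90.0], [0.01, 2.5]])

RESPONSE_NAMES = ("dt_min", "sec_mj_kg", "vc_mg_100g", "rc")


def tansig(n):
    """Hyperbolic-tangent sigmoid, range (-1, 1): 2/(1+exp(-2n)) - 1."""
    return np.tanh(n)


def logsig(n):
    """Logistic sigmoid, range (0, 1): 1/(1+exp(-n))."""
    n = np.asarray(n, dtype=float)
    out = np.empty_like(n)
    pos = n >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-n[pos]))
    e = np.exp(n[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def pureline(n):
    """Identity activation."""
    return np.asarray(n, dtype=float)


_ACTIVATIONS = {"tansig": tansig, "logsig": logsig, "pureline": pureline}


def activation(n, kind: str):
    """Apply the named activation (tansig, logsig or pureline) to ``n``."""
    try:
        f = _ACTIVATIONS[kind]
    except KeyError:
        raise InvalidInputError(
            f"unknown activation {kind!r}; expected one of {sorted(_ACTIVATIONS)}"
        ) from None
    return f(n)


def activation_derivative(a, kind: str):
    """Derivative of the named activation expressed through its value ``a``."""
    if kind == "tansig":
        return 1.0 - np.square(a)
    if kind == "logsig":
        return a * (1.0 - a)
    if kind == "pureline":
        return np.ones_like(np.asarray(a, dtype=float))
    raise InvalidInputError(f"unknown activation {kind!r}")


@dataclass(frozen=True)
class AffineTransform:
    """Invertible map between physical and network units: net = (x - offset)/gain.

    ``from_range(lo, hi)`` builds the min-max convention mapping lo -> -1 and
    hi -> +1.  ``gain`` must be nonzero.
    """

    gain: float
    offset: float

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise InvalidInputError("gain must be nonzero")

    @classmethod
    def from_range(cls, lo: float, hi: float) -> "AffineTransform":
        if lo >= hi:
            raise InvalidInputError(f"need lo < hi, got [{lo}, {hi}]")
        return cls(gain=(hi - lo) / 2.0, offset=(hi + lo) / 2.0)

    def scale(self, x):
        """Physical units -> network units."""
        return (np.asarray(x, dtype=float) - self.offset) / self.gain

    def unscale(self, y):
        """Network units -> physical units."""
        return np.asarray(y, dtype=float) * self.gain + self.offset


@dataclass(frozen=True)
class MLPTopology:
    """Hidden-layer width and the two activation choices of the 3-n-4 net."""

    hidden_neurons: int = 8
    hidden_activation: str = "tansig"
    output_activation: str = "pureline"

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise InvalidInputError("hidden_neurons must be >= 1")
        for kind in (self.hidden_activation, self.output_activation):
            if kind not in _ACTIVATIONS:
                raise InvalidInputError(f"unknown activation {kind!r}")


#: The 16-cell grid searched when selecting a topology.
DEFAULT_TOPOLOGY_GRID = tuple(
    MLPTopology(n, h, o)
    for h in ("tansig", "logsig")
    for n in (4, 6, 8, 10)
    for o in ("pureline", "logsig")
)


@dataclass(frozen=True)
class NetworkWeights:
    """Complete parameterisation of a trained 3-n-4 network.

    hidden_weights : (n, 3) — row j holds the weights from (BT, T, v) into
        hidden neuron j (scaled input space).
    hidden_bias : (n,)
    output_weights : (4, n) — row k holds the weights from the hidden
        activations into response k.
    output_bias : (4,)
    input_transforms : three AffineTransforms, physical -> [-1, 1].
    output_transforms : four AffineTransforms, network output -> physical.
    """

    hidden_weights: np.ndarray
    hidden_bias: np.ndarray
    output_weights: np.ndarray
    output_bias: np.ndarray
    input_transforms: tuple
    output_transforms: tuple
    topology: MLPTopology = field(default_factory=MLPTopology)
    provenance: str = ""

    def __post_init__(self) -> None:
        hw = np.asarray(self.hidden_weights, dtype=float)
        hb = np.asarray(self.hidden_bias, dtype=float)
        ow = np.asarray(self.output_weights, dtype=float)
        ob = np.asarray(self.output_bias, dtype=float)
        n = hw.shape[0]
        if hw.shape != (n, 3) or hb.shape != (n,) or ow.shape != (4, n) or ob.shape != (4,):
            raise InvalidInputError(
                f"inconsistent weight shapes: {hw.shape}, {hb.shape}, {ow.shape}, {ob.shape}"
            )
        if len(self.input_transforms) != 3 or len(self.output_transforms) != 4:
            raise InvalidInputError("need 3 input and 4 output transforms")
        object.__setattr__(self, "hidden_weights", hw)
        object.__setattr__(self, "hidden_bias", hb)
        object.__setattr__(self, "output_weights", ow)
        object.__setattr__(self, "output_bias", ob)

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    # --- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "topology": {
                "hidden_neurons": self.topology.hidden_neurons,
                "hidden_activation": self.topology.hidden_activation,
                "output_activation": self.topology.output_activation,
            },
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias.tolist(),
            "input_transforms": [
                {"gain": t.gain, "offset": t.offset} for t in self.input_transforms
            ],
            "output_transforms": [
                {"gain": t.gain, "offset": t.offset} for t in self.output_transforms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkWeights":
        try:
            topo = MLPTopology(**d["topology"])
            return cls(
                hidden_weights=np.asarray(d["hidden_weights"], dtype=float),
                hidden_bias=np.asarray(d["hidden_bias"], dtype=float),
                output_weights=np.asarray(d["output_weights"], dtype=float),
                output_bias=np.asarray(d["output_bias"], dtype=float),
                input_transforms=tuple(AffineTransform(**t) for t in d["input_transforms"]),
                output_transforms=tuple(AffineTransform(**t) for t in d["output_transforms"]),
                topology=topo,
                provenance=d.get("provenance", ""),
            )
        except (KeyError, TypeError) as exc:
            raise InvalidInputError(f"corrupt network dictionary: {exc}") from exc

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkWeights":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _scaled_inputs(net: NetworkWeights, X: np.ndarray, check_domain: bool) -> np.ndarray:
    Xs = np.column_stack(
        [net.input_transforms[i].scale(X[:, i]) for i in range(3)]
    )
    if check_domain and (np.any(Xs < -1 - 1e-9) or np.any(Xs > 1 + 1e-9)):
        bad = X[np.any((Xs < -1 - 1e-9) | (Xs > 1 + 1e-9), axis=1)][0]
        raise OutOfDomainError(
            f"input {tuple(bad)} outside the calibrated scaler domain; "
            "extrapolation refused"
        )
    return Xs


def forward(net: NetworkWeights, bt, t, v, check_domain: bool = True):
    """Evaluate the network at one or more physical conditions.

    Returns a dict mapping response names (dt_min, sec_mj_kg, vc_mg_100g,
    rc) to floats (scalar inputs) or arrays.  With ``check_domain`` (the
    default) inputs outside the scaler domain raise
    :class:`OutOfDomainError` instead of silently extrapolating.
    """
    scalar = np.isscalar(bt) and np.isscalar(t) and np.isscalar(v)
    X = np.column_stack(
        [np.atleast_1d(np.asarray(a, dtype=float)) for a in (bt, t, v)]
    )
    Xs = _scaled_inputs(net, X, check_domain)
    D = Xs @ net.hidden_weights.T + net.hidden_bias
    F = activation(D, net.topology.hidden_activation)
    G = activation(F @ net.output_weights.T + net.output_bias,
                   net.topology.output_activation)
    out = {}
    for k, name in enumerate(RESPONSE_NAMES):
        y = net.output_transforms[k].unscale(G[:, k])
        out[name] = float(y[0]) if scalar else y
    return out


def network_outputs_raw(net: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Network-unit outputs (before the output affine transforms), (N, 4)."""
    Xs = _scaled_inputs(net, np.asarray(X, dtype=float), check_domain=False)
    F = activation(Xs @ net.hidden_weights.T + net.hidden_bias,
                   net.topology.hidden_activation)
    return activation(F @ net.output_weights.T + net.output_bias,
                      net.topology.output_activation)


def calibrate_output_transforms(
    net: NetworkWeights, X: np.ndarray, Y: np.ndarray
) -> "NetworkWeights":
    """Least-squares fit of the four output affine transforms.

    For each response k, fits ``y_phys ~ gain * y_net + offset`` over the
    reference conditions ``X`` (N, 3) and physical values ``Y`` (N, 4), and
    returns a copy of ``net`` with the fitted transforms installed.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or Y.shape != (X.shape[0], 4):
        raise InvalidInputError("X must be (N, 3) and Y (N, 4)")
    raw = network_outputs_raw(net, X)
    transforms = []
    for k in range(4):
        A = np.column_stack([raw[:, k], np.ones(len(raw))])
        (gain, offset), *_ = np.linalg.lstsq(A, Y[:, k], rcond=None)
        transforms.append(AffineTransform(gain=float(gain), offset=float(offset)))
    return NetworkWeights(
        hidden_weights=net.hidden_weights,
        hidden_bias=net.hidden_bias,
        output_weights=net.output_weights,
        output_bias=net.output_bias,
        input_transforms=net.input_transforms,
        output_transforms=tuple(transforms),
        topology=net.topology,
        provenance=net.provenance + " | output transforms least-squares calibrated",
    )


def published_network() -> NetworkWeights:
    """The published trained 3-8-4 network, reconstructed from print.

    Hidden weights/biases and output weights/constants are exactly the
    printed values; input scaling covers the optimization bounds; output
    transforms are the frozen least-squares calibration against the
    published Pareto front (see module docstring).
    """
    ref = resources.files("berryopt") / "_data" / "published_network.json"
    try:
        with ref.open() as fh:
            return NetworkWeights.from_dict(json.load(fh))
    except FileNotFoundError as exc:
        raise InvalidInputError("packaged published-network fixture missing") from exc
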