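"""Decision-fusion network: 4 inputs, 3 logistic hidden units, 1 linear output.

The four base classifiers' binary decisions are fused by a single-hidden-layer
feed-forward network.  Hidden neurons use the logistic sigmoid; the output
neuron is linear, so for input x

    score(x) = b_out + sum_k w_out[k] * sigma(b_k + sum_i W[k, i] * x[i]).

Training is extreme-learning-machine style: hidden weights and biases are
drawn i.i.d. uniform(-1, 1), the hidden activation matrix H is formed, and
the output layer is the least-squares (pseudo-inverse) solution of
[H | 1] beta = y.  Several random restarts are tried and the network with the
minimum sum of squared errors (SSE) is kept.  A single-hidden-layer network
with n_hidden >= n distinct samples and full-rank activations interpolates
the targets exactly (zero SSE).

The module also ships a frozen, published 4-3-1 parameter set (19 parameters:
12 hidden weights + 3 hidden biases + 3 output weights + 1 output bias),
loadable via :func:`table2_network`.  Because the sign convention of that
frozen network is not independently verifiable, :func:`classify` exposes the
decision polarity and threshold as configuration, with a calibration helper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

N_INPUTS = 4
N_HIDDEN = 3


class InvalidInputError(ValueError):
    """Non-finite or mis-shaped network input."""


class InvalidModelError(ValueError):
    """Network file with inconsistent or unsupported shapes."""


class ParseError(ValueError):
    """Malformed network file."""


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class FusionNetwork:
    """Weights of a single-hidden-layer fusion network.

    ``hidden_weights[k, i]`` connects input i to hidden neuron k;
    ``output_weights[k]`` connects hidden neuron k to the linear output.
    """

    hidden_weights: np.ndarray  # (n_hidden, n_inputs)
    hidden_biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)
    output_bias: float

    def __post_init__(self) -> None:
        hw = np.asarray(self.hidden_weights, dtype=float)
        hb = np.asarray(self.hidden_biases, dtype=float)
        ow = np.asarray(self.output_weights, dtype=float)
        if hw.ndim != 2:
            raise InvalidModelError("hidden_weights must be a matrix")
        n_hidden = hw.shape[0]
        if hb.shape != (n_hidden,) or ow.shape != (n_hidden,):
            raise InvalidModelError("bias/output-weight shapes inconsistent")
        if not (
            np.isfinite(hw).all()
            and np.isfinite(hb).all()
            and np.isfinite(ow).all()
            and np.isfinite(self.output_bias)
        ):
            raise InvalidModelError("non-finite network parameter")
        object.__setattr__(self, "hidden_weights", hw)
        object.__setattr__(self, "hidden_biases", hb)
        object.__setattr__(self, "output_weights", ow)
        object.__setattr__(self, "output_bias", float(self.output_bias))

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_parameters(self) -> int:
        """Total parameter count (19 for the standard 4-3-1 architecture)."""
        return (
            self.hidden_weights.size
            + self.hidden_biases.size
            + self.output_weights.size
            + 1
        )


@dataclass(frozen=True)
class TrainingRecord:
    """Restart bookkeeping of one ELM training run."""

    sse_per_restart: tuple
    selected_index: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sse_per_restart[self.selected_index] != min(self.sse_per_restart):
            raise InvalidModelError("selected restart is not the SSE minimum")

    @property
    def n_restarts(self) -> int:
        return len(self.sse_per_restart)

    @property
    def selected_sse(self) -> float:
        return self.sse_per_restart[self.selected_index]


# ---------------------------------------------------------------------------
# forward pass and classification
# ---------------------------------------------------------------------------

def forward(net: FusionNetwork, x) -> float:
    """Network score for a single input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise InvalidInputError(
            f"expected {net.n_inputs}-vector, got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise InvalidInputError("non-finite network input")
    hidden = _sigmoid(net.hidden_weights @ x + net.hidden_biases)
    return float(net.output_weights @ hidden + net.output_bias)


def forward_batch(net: FusionNetwork, X) -> np.ndarray:
    """Network scores for the rows of an (n, n_inputs) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise InvalidInputError(
            f"expected (n, {net.n_inputs}) matrix, got shape {X.shape}"
        )
    if not np.isfinite(X).all():
        raise InvalidInputError("non-finite network input")
    H = _sigmoid(X @ net.hidden_weights.T + net.hidden_biases)
    return H @ net.output_weights + net.output_bias


def classify(
    net: FusionNetwork, x, threshold: float = 0.0, polarity: int = +1
) -> int:
    """Binary label in {-1, +1} from the network score.

    ``polarity=+1`` labels +1 when score >= threshold (ties inclusive);
    ``polarity=-1`` inverts the convention (score >= threshold -> -1).
    """
    if polarity not in (+1, -1):
        raise InvalidInputError("polarity must be +1 or -1")
    score = forward(net, x)
    return polarity if score >= threshold else -polarity


def calibrate_polarity(
    net: FusionNetwork, X, y, threshold: float = 0.0
) -> int:
    """Pick the polarity maximizing accuracy of (net, threshold) on (X, y)."""
    scores = forward_batch(net, X)
    y = np.asarray(y)
    base = np.where(scores >= threshold, 1, -1)
    acc_pos = float(np.mean(base == y))
    return +1 if acc_pos >= 1.0 - acc_pos else -1


# ---------------------------------------------------------------------------
# ELM training: random hidden layer + pseudo-inverse output solve
# ---------------------------------------------------------------------------

def train_elm(
    X,
    y,
    n_hidden: int = N_HIDDEN,
    restarts: int = 50,
    rng: np.random.Generator | int | None = None,
) -> tuple[FusionNetwork, TrainingRecord]:
    """Fit the fusion network by random restarts and least squares.

    Per restart, hidden weights and biases are drawn i.i.d. uniform(-1, 1);
    the output layer solves min ||[H | 1] beta - y||^2 by pseudo-inverse
    (rank-revealing SVD).  The restart with minimal SSE wins.  *rng* may be
    a Generator or an integer seed (recorded in the TrainingRecord).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidInputError("training matrix must be non-empty and 2-D")
    if y.shape != (X.shape[0],):
        raise InvalidInputError("target vector length mismatch")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise InvalidInputError("non-finite training data")
    if restarts < 1:
        raise InvalidInputError("restarts must be >= 1")
    seed = None
    if rng is None:
        rng = np.random.default_rng()
    elif isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    n, n_in = X.shape
    best = None
    sses = []
    for r in range(restarts):
        W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_in))
        b = rng.uniform(-1.0, 1.0, size=n_hidden)
        H = _sigmoid(X @ W.T + b)
        design = np.column_stack([H, np.ones(n)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((design @ beta - y) ** 2))
        sses.append(sse)
        if best is None or sse < best[0]:
            best = (sse, W, b, beta)
    _, W, b, beta = best
    net = FusionNetwork(
        hidden_weights=W,
        hidden_biases=b,
        output_weights=beta[:-1],
        output_bias=float(beta[-1]),
    )
    record = TrainingRecord(
        sse_per_restart=tuple(sses),
        selected_index=int(np.argmin(sses)),
        seed=seed,
    )
    return net, record


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_network(net: FusionNetwork, path) -> None:
    payload = {
        "hidden_weights": net.hidden_weights.tolist(),
        "hidden_biases": net.hidden_biases.tolist(),
        "output_weights": net.output_weights.tolist(),
        "output_bias": net.output_bias,
        "activation": "logistic",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _network_from_payload(
    payload: dict, expect_inputs: int | None = N_INPUTS
) -> FusionNetwork:
    try:
        hw = np.asarray(payload["hidden_weights"], dtype=float)
        hb = np.asarray(payload["hidden_biases"], dtype=float)
        ow = np.asarray(payload["output_weights"], dtype=float)
        ob = float(payload["output_bias"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed network payload: {exc}") from exc
    if payload.get("activation", "logistic") != "logistic":
        raise InvalidModelError(
            f"unsupported activation {payload.get('activation')!r}"
        )
    net = FusionNetwork(hw, hb, ow, ob)
    if expect_inputs is not None and net.n_inputs != expect_inputs:
        raise InvalidModelError(
            f"expected {expect_inputs}-input network, file has {net.n_inputs}"
        )
    return net


def load_network(path, expect_inputs: int | None = N_INPUTS) -> FusionNetwork:
    """Load a network JSON; reject files with the wrong input arity."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise ParseError("network file must contain a JSON object")
    return _network_from_payload(payload, expect_inputs)


def table2_network() -> FusionNetwork:
    """The shipped frozen 4-3-1 fusion network (published parameter set)."""
    text = resources.files("mirfuse.data").joinpath("table2.json").read_text()
    return _network_from_payload(json.loads(text), expect_inputs=N_INPUTS)
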