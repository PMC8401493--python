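"""MLP lead reconstruction trained with Levenberg-Marquardt.

One-hidden-layer feed-forward perceptrons (tanh hidden layer, linear output)
map the three acquired leads to the target leads, in two strategies:

* ``per_lead`` -- one single-output network per reconstructed lead;
* ``all_leads`` -- a single network with one output neuron per lead.

Training minimises the sum of squared errors on standardized signals with
the Levenberg-Marquardt update ``(J'J + mu*I) delta = J'r``; the damping
``mu`` is decreased after an accepted step and increased after a rejected
one, interpolating between Gauss-Newton and gradient descent.  The Jacobian
is computed analytically by backpropagation and accumulated in sample
chunks, so memory stays flat regardless of the record length.

Inputs and targets are standardized to zero mean / unit variance on the
training segment only (the scalers are frozen into the model); without it
millivolt-scale signals sit deep in the tanh tail and training stalls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, DivergenceError, EcgReconError

__all__ = [
    "MlpNetwork",
    "LmConfig",
    "init_mlp",
    "forward",
    "train_lm",
    "MlpLeadRegression",
    "MlpLeadResults",
    "fit_ann",
    "predict_ann",
]

_MU_MAX = 1e10


@dataclass
class LmConfig:
    """Levenberg-Marquardt hyperparameters (classical recipe defaults)."""

    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    max_epochs: int = 200
    min_gradient: float = 1e-7
    min_loss_delta: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_init <= 0 or self.mu_increase <= 0 or self.mu_decrease <= 0:
            raise ConfigError("LM damping factors must be positive")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass
class MlpNetwork:
    """Weights, biases and frozen standardization parameters of one MLP."""

    w_hidden: np.ndarray   # (H, n_in)
    b_hidden: np.ndarray   # (H,)
    w_out: np.ndarray      # (M, H)
    b_out: np.ndarray      # (M,)
    input_mean: np.ndarray   # (n_in,)
    input_std: np.ndarray    # (n_in,)
    output_mean: np.ndarray  # (M,)
    output_std: np.ndarray   # (M,)

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.w_out.shape[0]

    @property
    def n_parameters(self) -> int:
        return (self.w_hidden.size + self.b_hidden.size
                + self.w_out.size + self.b_out.size)

    def copy(self) -> "MlpNetwork":
        return MlpNetwork(*(np.array(getattr(self, f)) for f in (
            "w_hidden", "b_hidden", "w_out", "b_out",
            "input_mean", "input_std", "output_mean", "output_std")))

    def to_dict(self) -> dict:
        return {f: getattr(self, f).tolist() for f in (
            "w_hidden", "b_hidden", "w_out", "b_out",
            "input_mean", "input_std", "output_mean", "output_std")}

    @classmethod
    def from_dict(cls, d: dict) -> "MlpNetwork":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


def init_mlp(n_hidden: int, n_outputs: int, seed: int,
             n_inputs: int = 3) -> MlpNetwork:
    """Reproducible Nguyen-Widrow-style initialisation, identity scalers.

    Weights are drawn uniform in [-0.5, 0.5]; hidden rows are rescaled to a
    common norm ``0.7 * H**(1/n_in)`` and hidden biases spread over the
    active tanh range, which keeps the hidden units' linear regions covering
    the standardized input space.
    """
    if n_hidden < 1:
        raise ConfigError(f"n_hidden must be >= 1, got {n_hidden}")
    rng = np.random.default_rng(seed)
    w_h = rng.uniform(-0.5, 0.5, size=(n_hidden, n_inputs))
    factor = 0.7 * n_hidden ** (1.0 / n_inputs)
    norms = np.linalg.norm(w_h, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    w_h = factor * w_h / norms
    b_h = factor * rng.uniform(-1.0, 1.0, size=n_hidden)
    w_o = rng.uniform(-0.5, 0.5, size=(n_outputs, n_hidden))
    b_o = rng.uniform(-0.5, 0.5, size=n_outputs)
    ident = np.ones
    return MlpNetwork(
        w_h, b_h, w_o, b_o,
        input_mean=np.zeros(n_inputs), input_std=ident(n_inputs),
        output_mean=np.zeros(n_outputs), output_std=ident(n_outputs),
    )


def _forward_std(net: MlpNetwork, x_std: np.ndarray) -> np.ndarray:
    a = np.tanh(net.w_hidden @ x_std + net.b_hidden[:, None])
    return net.w_out @ a + net.b_out[:, None]


def forward(net: MlpNetwork, inputs) -> np.ndarray:
    """Network output in physical units (mV) for 3xN inputs."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    if x.shape[0] != net.n_inputs:
        raise EcgReconError(
            f"expected {net.n_inputs} input rows, got {x.shape[0]}"
        )
    x_std = (x - net.input_mean[:, None]) / net.input_std[:, None]
    y_std = _forward_std(net, x_std)
    return y_std * net.output_std[:, None] + net.output_mean[:, None]


# --- Levenberg-Marquardt core ----------------------------------------------

def _pack(net: MlpNetwork) -> np.ndarray:
    return np.concatenate([net.w_hidden.ravel(), net.b_hidden,
                           net.w_out.ravel(), net.b_out])

def _unpack(net: MlpNetwork, theta: np.ndarray) -> MlpNetwork:
    h, ni, m = net.n_hidden, net.n_inputs, net.n_outputs
    out = net.copy()
    i = 0
    out.w_hidden = theta[i:i + h * ni].reshape(h, ni); i += h * ni
    out.b_hidden = theta[i:i + h].copy(); i += h
    out.w_out = theta[i:i + m * h].reshape(m, h); i += m * h
    out.b_out = theta[i:i + m].copy()
    return out


def _accumulate_normal_eqs(net: MlpNetwork, x_std: np.ndarray,
                           y_std: np.ndarray, chunk: int = 4096):
    """J'J, J'r and the SSE for residuals r = y - f(x), without storing J.

    J is the Jacobian of the network output w.r.t. the packed parameters;
    rows are (output m, sample n) pairs.
    """
    h, ni, m = net.n_hidden, net.n_inputs, net.n_outputs
    p = net.n_parameters
    jtj = np.zeros((p, p))
    jtr = np.zeros(p)
    sse = 0.0
    n = x_std.shape[1]
    for lo in range(0, n, chunk):
        xs = x_std[:, lo:lo + chunk]
        ys = y_std[:, lo:lo + chunk]
        nc = xs.shape[1]
        z = net.w_hidden @ xs + net.b_hidden[:, None]
        a = np.tanh(z)                      # (H, nc)
        da = 1.0 - a * a                    # tanh'
        r = ys - (net.w_out @ a + net.b_out[:, None])  # (M, nc)
        sse += float(np.sum(r * r))
        # J rows for output m: [w_o[m,:,None]*da*x_i | w_o[m]*da | a (block m) | e_m]
        jac = np.zeros((m * nc, p))
        g = net.w_out[:, :, None] * da[None, :, :]      # (M, H, nc)
        # d y_m / d w_hidden[h, i] = g[m, h, n] * x[i, n]
        jw = g[:, :, None, :] * xs[None, None, :, :]    # (M, H, ni, nc)
        jac[:, :h * ni] = jw.reshape(m, h * ni, nc).transpose(0, 2, 1) \
                            .reshape(m * nc, h * ni)
        jac[:, h * ni:h * ni + h] = g.transpose(0, 2, 1).reshape(m * nc, h)
        off = h * ni + h
        for mm in range(m):
            rows = slice(mm * nc, (mm + 1) * nc)
            jac[rows, off + mm * h: off + (mm + 1) * h] = a.T
            jac[rows, off + m * h + mm] = 1.0
        jtj += jac.T @ jac
        jtr += jac.T @ r.reshape(m * nc)
    return jtj, jtr, sse


def _sse(net: MlpNetwork, x_std: np.ndarray, y_std: np.ndarray) -> float:
    r = y_std - _forward_std(net, x_std)
    return float(np.sum(r * r))


def train_lm(net: MlpNetwork, inputs, targets,
             config: LmConfig | None = None) -> tuple[MlpNetwork, list[float]]:
    """Train one network by Levenberg-Marquardt; returns (net, loss history).

    The loss is the SSE on standardized targets.  The history records the
    initial loss followed by every accepted step, so it is non-increasing.
    Training stops on ``max_epochs``, a small gradient (max |J'r|), a small
    loss decrease, or when no damping value up to 1e10 yields a decrease.
    """
    config = config or LmConfig()
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise EcgReconError("inputs and targets must share the sample count")
    x_std = (x - net.input_mean[:, None]) / net.input_std[:, None]
    y_std = (y - net.output_mean[:, None]) / net.output_std[:, None]

    net = net.copy()
    theta = _pack(net)
    loss = _sse(net, x_std, y_std)
    if not np.isfinite(loss):
        raise DivergenceError(0)
    history = [loss]
    mu = config.mu_init
    eye = np.eye(theta.size)

    for epoch in range(1, config.max_epochs + 1):
        jtj, jtr, loss = _accumulate_normal_eqs(net, x_std, y_std)
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        if np.max(np.abs(jtr)) < config.min_gradient:
            break
        accepted = False
        while mu <= _MU_MAX:
            try:
                delta = np.linalg.solve(jtj + mu * eye, jtr)
            except np.linalg.LinAlgError:
                mu *= config.mu_increase
                continue
            cand = _unpack(net, theta + delta)
            cand_loss = _sse(cand, x_std, y_std)
            if np.isfinite(cand_loss) and cand_loss < loss:
                theta = theta + delta
                net = cand
                mu = max(mu * config.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            break
        history.append(cand_loss)
        if loss - cand_loss < config.min_loss_delta:
            break
    return net, history


def lm_step_direction(net: MlpNetwork, inputs, targets,
                      mu: float) -> tuple[np.ndarray, np.ndarray]:
    """One LM step ``delta`` and the gradient direction ``J'r`` (diagnostic).

    For large ``mu`` the step approaches ``J'r / mu``, i.e. scaled gradient
    descent on the standardized SSE.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    x_std = (x - net.input_mean[:, None]) / net.input_std[:, None]
    y_std = (y - net.output_mean[:, None]) / net.output_std[:, None]
    jtj, jtr, _ = _accumulate_normal_eqs(net, x_std, y_std)
    delta = np.linalg.solve(jtj + mu * np.eye(jtr.size), jtr)
    return delta, jtr


# --- model / results surface ----------------------------------------------

class MlpLeadRegression:
    """MLP reconstruction model in the ``per_lead`` or ``all_leads`` strategy.

    ``per_lead`` trains M independent single-output networks, ``all_leads``
    one network with M output neurons; both use the same hidden-layer size.
    Standardization scalers are computed from the training data passed here
    and frozen into every network.
    """

    def __init__(self, inputs, targets, *, strategy: str = "per_lead",
                 n_hidden: int = 10, config: LmConfig | None = None,
                 input_names=None, target_names=None):
        if strategy not in ("per_lead", "all_leads"):
            raise ConfigError(f"unknown strategy {strategy!r}")
        self.inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        self.targets = np.atleast_2d(np.asarray(targets, dtype=float))
        if self.inputs.shape[0] != 3:
            raise EcgReconError("expected 3 input leads")
        if self.inputs.shape[1] != self.targets.shape[1]:
            raise EcgReconError("inputs and targets must share sample count")
        self.strategy = strategy
        self.n_hidden = n_hidden
        self.config = config or LmConfig()
        self.input_names = list(input_names or ["in1", "in2", "in3"])
        self.target_names = list(
            target_names or
            [f"lead{k + 1}" for k in range(self.targets.shape[0])]
        )

    def _scalers(self):
        mu_x = self.inputs.mean(axis=1)
        sd_x = self.inputs.std(axis=1)
        mu_y = self.targets.mean(axis=1)
        sd_y = self.targets.std(axis=1)
        sd_x[sd_x == 0] = 1.0
        sd_y[sd_y == 0] = 1.0
        return mu_x, sd_x, mu_y, sd_y

    def fit(self, seed: int | None = None) -> "MlpLeadResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        mu_x, sd_x, mu_y, sd_y = self._scalers()
        m = self.targets.shape[0]
        nets: list[MlpNetwork] = []
        histories: list[list[float]] = []
        if self.strategy == "per_lead":
            for k in range(m):
                net = init_mlp(self.n_hidden, 1, seed=cfg.seed + k)
                net.input_mean, net.input_std = mu_x, sd_x
                net.output_mean = mu_y[k:k + 1]
                net.output_std = sd_y[k:k + 1]
                net, hist = train_lm(net, self.inputs,
                                     self.targets[k:k + 1], cfg)
                nets.append(net)
                histories.append(hist)
        else:
            net = init_mlp(self.n_hidden, m, seed=cfg.seed)
            net.input_mean, net.input_std = mu_x, sd_x
            net.output_mean, net.output_std = mu_y, sd_y
            net, hist = train_lm(net, self.inputs, self.targets, cfg)
            nets.append(net)
            histories.append(hist)
        return MlpLeadResults(self, nets, histories)


@dataclass
class MlpLeadResults:
    """Trained networks, their loss histories, and prediction helpers."""

    model: MlpLeadRegression | None
    networks: list[MlpNetwork]
    loss_histories: list[list[float]]
    strategy: str = field(default="")
    target_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model is not None:
            self.strategy = self.model.strategy
            self.target_names = self.model.target_names

    def predict(self, inputs) -> np.ndarray:
        """Reconstruct all target leads for new 3xN input samples."""
        if self.strategy == "per_lead":
            return np.vstack([forward(net, inputs) for net in self.networks])
        return forward(self.networks[0], inputs)

    def summary(self) -> str:
        lines = [
            f"MLP lead reconstruction ({self.strategy}, "
            f"{self.networks[0].n_hidden} hidden tanh units, "
            "Levenberg-Marquardt)",
            f"  {'lead(s)':>12s} {'epochs':>7s} {'final SSE (std)':>16s}",
        ]
        if self.strategy == "per_lead":
            labels = self.target_names
        else:
            labels = [",".join(self.target_names) or "all"]
        for label, hist in zip(labels, self.loss_histories):
            lines.append(f"  {label[:12]:>12s} {len(hist) - 1:>7d} "
                         f"{hist[-1]:>16.6e}")
        return "\n".join(lines)

    def save(self, path) -> Path:
        """Portable JSON weight file (architecture, scalers, weights)."""
        path = Path(path)
        path.write_text(json.dumps({
            "strategy": self.strategy,
            "target_names": self.target_names,
            "networks": [n.to_dict() for n in self.networks],
            "loss_histories": self.loss_histories,
        }))
        return path

    @classmethod
    def load(cls, path) -> "MlpLeadResults":
        d = json.loads(Path(path).read_text())
        return cls(model=None,
                   networks=[MlpNetwork.from_dict(n) for n in d["networks"]],
                   loss_histories=d["loss_histories"],
                   strategy=d["strategy"],
                   target_names=d["target_names"])


def fit_ann(inputs_train, targets_train, strategy: str = "per_lead",
            n_hidden: int = 10,
            config: LmConfig | None = None, **kwargs) -> MlpLeadResults:
    """Train MLP reconstruction networks on the training segment."""
    return MlpLeadRegression(
        inputs_train, targets_train, strategy=strategy, n_hidden=n_hidden,
        config=config, **kwargs,
    ).fit()


def predict_ann(results: MlpLeadResults, inputs,
                strategy: str | None = None) -> np.ndarray:
    if strategy is not None and strategy != results.strategy:
        raise ConfigError(
            f"models were trained with strategy {results.strategy!r}, "
            f"not {strategy!r}"
        )
    return results.predict(inputs)
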