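"""Firing-rate RNN that integrates angular velocity into head direction.

The network has N fully recurrent units obeying a rate model in which
firing follows synaptic input instantaneously while the synaptic input
relaxes slowly:

    r_i(t) = max(0, tanh(s_i(t)))
    tau ds_i/dt = -s_i + sum_j W_rec[j,i] r_j + sum_k W_in[k,i] I_k + b_i

simulated by Euler steps of dt = 25 ms with tau = 250 ms.  The three
inputs are (cos theta_0, sin theta_0, AHV_t): during a 10-step
initialization phase the first two carry the initial heading and AHV is 0;
afterwards they are 0 and the scalar AHV input follows the AR(1) process
``AHV_t = sigma*X + momentum*AHV_{t-1}`` (sigma = 0.03 rad/step,
momentum = 0.8).  Two linear readouts are trained toward
(cos theta_t, sin theta_t) where theta_t is the exact integral of the
velocity input, under mean-squared error plus an L2 penalty on the firing
rates of recurrent and output units.

Training is backpropagation through time with Adam.  (The loss,
regularization, trial structure and dynamics follow the original
formulation; the second-order optimizer used there is replaced by a
first-order adaptive one, so per-epoch error traces are comparable only
qualitatively.)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .session import Session

__all__ = [
    "RNNConfig",
    "RNNState",
    "TrainedRNN",
    "step_dynamics",
    "make_trial_inputs",
    "make_trial_batch",
    "forward",
    "nmse",
    "total_normalized_error",
    "train",
    "generate_session",
    "deactivate_and_score",
]

TWO_PI = 2.0 * np.pi


@dataclass
class RNNConfig:
    """Architecture, task and training hyperparameters.

    ``sigma`` and ``momentum`` parameterize the per-step AR(1) velocity
    process (radians per 25 ms step).  ``rate_l2`` is the weight of the L2
    penalty on mean squared firing rates; its value is a package default
    (the original report does not state one).
    """

    n_units: int = 100
    tau: float = 0.250          # s
    dt: float = 0.025           # s
    trial_len: int = 500        # steps
    n_trials: int = 500
    init_phase: int = 10        # steps with HD input, zero AHV
    sigma: float = 0.03         # rad/step innovation SD
    momentum: float = 0.8
    zero_ahv_fraction: float = 0.5   # trials containing a zero-AHV segment
    zero_ahv_max: float = 1.0 / 3.0  # max segment length, fraction of trial
    rate_l2: float = 1e-4
    epochs: int = 500
    batch_size: int = 50
    learning_rate: float = 5e-3
    lr_decay: float = 0.2       # step-decay factor at 60% and 85% of epochs
    grad_clip: float = 1.0      # global gradient-norm ceiling for BPTT
    init_gain: float = 1.1      # recurrent weight init scale
    seed: int = 0

    def __post_init__(self):
        if self.dt > self.tau:
            raise ValueError("Euler step dt must not exceed tau")
        if self.init_phase >= self.trial_len:
            raise ValueError("init_phase must be shorter than the trial")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")

    @property
    def alpha(self) -> float:
        """Euler relaxation factor dt/tau."""
        return self.dt / self.tau


@dataclass
class RNNState:
    """Instantaneous network state: synaptic inputs and firing rates."""

    s: np.ndarray
    r: np.ndarray

    @classmethod
    def zeros(cls, n_units: int) -> "RNNState":
        return cls(s=np.zeros(n_units), r=np.zeros(n_units))


def _rates(s: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.tanh(s))


@dataclass
class TrainedRNN:
    """Weights and training trace of a trained integrator network."""

    W_rec: np.ndarray   # (N, N); W_rec[j, i] couples rate j -> input i
    W_in: np.ndarray    # (3, N)
    W_out: np.ndarray   # (N, 2)
    b: np.ndarray       # (N,)
    config: RNNConfig
    nmse_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        for w in (self.W_rec, self.W_in, self.W_out, self.b):
            if not np.all(np.isfinite(w)):
                raise ValueError("non-finite weights")

    @property
    def n_units(self) -> int:
        return self.W_rec.shape[0]

    def save(self, path: str | Path) -> None:
        from .session import _strip_ext

        base = _strip_ext(path)
        np.savez(
            Path(str(base) + ".npz"),
            W_rec=self.W_rec, W_in=self.W_in, W_out=self.W_out, b=self.b,
            nmse_trace=np.asarray(self.nmse_trace),
        )
        Path(str(base) + ".json").write_text(
            json.dumps({"config": asdict(self.config)}, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedRNN":
        from .session import _strip_ext

        base = _strip_ext(path)
        with np.load(Path(str(base) + ".npz")) as a:
            arrays = {k: a[k] for k in a.files}
        cfg = RNNConfig(
            **json.loads(Path(str(base) + ".json").read_text())["config"]
        )
        return cls(
            W_rec=arrays["W_rec"], W_in=arrays["W_in"],
            W_out=arrays["W_out"], b=arrays["b"], config=cfg,
            nmse_trace=list(arrays["nmse_trace"]),
        )


# ----------------------------------------------------------------------
# dynamics
def step_dynamics(
    state: RNNState, inputs: np.ndarray, rnn: TrainedRNN
) -> RNNState:
    """One Euler step of the rate dynamics.

    ``s <- s + (dt/tau) * (-s + X_input)`` with
    ``X_input = r @ W_rec + inputs @ W_in + b``; rates are recomputed as
    ``max(0, tanh(s))``.
    """
    if not (np.all(np.isfinite(state.s)) and np.all(np.isfinite(inputs))):
        raise FloatingPointError("non-finite state or inputs")
    a = rnn.config.alpha
    x = state.r @ rnn.W_rec + np.asarray(inputs) @ rnn.W_in + rnn.b
    s_new = (1.0 - a) * state.s + a * x
    return RNNState(s=s_new, r=_rates(s_new))


# ----------------------------------------------------------------------
# trial construction
def _ar1(rng, n: int, sigma: float, momentum: float) -> np.ndarray:
    x = rng.standard_normal(n)
    out = np.empty(n)
    v = 0.0
    for t in range(n):
        v = sigma * x[t] + momentum * v
        out[t] = v
    return out


def make_trial_inputs(
    config: RNNConfig,
    theta0: float,
    seed: int | None = None,
    zero_segment: bool = False,
):
    """Inputs and targets for a single trial.

    Returns ``(inputs, target)`` of shapes ``(T, 3)`` and ``(T, 2)``.
    Phase 1 (``init_phase`` steps): inputs ``(cos theta0, sin theta0, 0)``.
    Phase 2: inputs ``(0, 0, AHV_t)``.  The target is
    ``(cos theta_t, sin theta_t)`` with theta the exact running integral of
    the velocity input.  With ``zero_segment`` a contiguous stretch of up to
    a third of the trial has AHV forced to 0 (the stability probe used on
    half of the training trials).
    """
    rng = np.random.default_rng(seed)
    T, p = config.trial_len, config.init_phase
    ahv = np.zeros(T)
    ahv[p:] = _ar1(rng, T - p, config.sigma, config.momentum)
    if zero_segment:
        seg_len = int(rng.integers(1, max(2, int(T * config.zero_ahv_max))))
        start = int(rng.integers(p, T - 1))
        ahv[start : min(T, start + seg_len)] = 0.0
    theta = theta0 + np.cumsum(ahv)
    inputs = np.zeros((T, 3))
    inputs[:p, 0] = np.cos(theta0)
    inputs[:p, 1] = np.sin(theta0)
    inputs[p:, 2] = ahv[p:]
    target = np.column_stack([np.cos(theta), np.sin(theta)])
    return inputs, target


def make_trial_batch(config: RNNConfig, n_trials: int, seed: int):
    """Stack of trials: inputs ``(T, B, 3)``, targets ``(T, B, 2)``.

    Trial b gets a zero-AHV segment iff b is in the first
    ``zero_ahv_fraction`` of the batch (the batch is later shuffled for
    minibatching, so position carries no information).
    """
    rng = np.random.default_rng(seed)
    inputs = np.zeros((config.trial_len, n_trials, 3))
    targets = np.zeros((config.trial_len, n_trials, 2))
    n_zero = int(round(config.zero_ahv_fraction * n_trials))
    for b in range(n_trials):
        theta0 = float(rng.uniform(0, TWO_PI))
        trial_seed = int(rng.integers(2**31))
        inp, tgt = make_trial_inputs(
            config, theta0, seed=trial_seed, zero_segment=b < n_zero
        )
        inputs[:, b, :] = inp
        targets[:, b, :] = tgt
    return inputs, targets


# ----------------------------------------------------------------------
# forward / error
def forward(
    rnn: TrainedRNN,
    inputs: np.ndarray,
    deactivate: np.ndarray | None = None,
    return_rates: bool = False,
):
    """Run the network over a batch of trials.

    ``inputs`` is ``(T, B, 3)``; returns outputs ``(T, B, 2)`` and, when
    requested, rates ``(T, B, N)``.  ``deactivate`` is a boolean unit mask
    whose hidden states are clamped to zero after every Euler step.
    """
    cfg = rnn.config
    a = cfg.alpha
    T, B, _ = inputs.shape
    N = rnn.n_units
    s = np.zeros((B, N))
    r = np.zeros((B, N))
    y = np.empty((T, B, 2))
    rates = np.empty((T, B, N)) if return_rates else None
    for t in range(T):
        x = r @ rnn.W_rec + inputs[t] @ rnn.W_in + rnn.b
        s = (1.0 - a) * s + a * x
        if deactivate is not None:
            s[:, deactivate] = 0.0
        r = _rates(s)
        y[t] = r @ rnn.W_out
        if return_rates:
            rates[t] = r
    if not np.all(np.isfinite(y[-1])):
        raise FloatingPointError("network state diverged")
    return (y, rates) if return_rates else y


def nmse(y: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-output normalized mean-squared error, percent.

    ``NMSE_l = 100 * sum (y_l - t_l)^2 / sum (t_l - mean t_l)^2`` over all
    timesteps and trials.
    """
    y2 = y.reshape(-1, y.shape[-1])
    t2 = target.reshape(-1, target.shape[-1])
    num = np.sum((y2 - t2) ** 2, axis=0)
    den = np.sum((t2 - t2.mean(axis=0)) ** 2, axis=0)
    return 100.0 * num / den


def total_normalized_error(y: np.ndarray, target: np.ndarray) -> float:
    """Sum of the per-output NMSEs (a mean predictor scores 200)."""
    return float(np.sum(nmse(y, target)))


# ----------------------------------------------------------------------
# training
def _init_weights(cfg: RNNConfig, rng):
    N = cfg.n_units
    W_rec = rng.standard_normal((N, N)) * cfg.init_gain / np.sqrt(N)
    W_in = rng.standard_normal((3, N)) / np.sqrt(3)
    W_out = rng.standard_normal((N, 2)) / np.sqrt(N)
    b = np.zeros(N)
    return W_rec, W_in, W_out, b


def _forward_backward(rnn: TrainedRNN, inputs, targets):
    """Loss and gradients for one minibatch (BPTT)."""
    cfg = rnn.config
    a = cfg.alpha
    T, B, _ = inputs.shape
    N = rnn.n_units
    lam = cfg.rate_l2

    s_hist = np.empty((T, B, N))
    r_hist = np.empty((T, B, N))
    s = np.zeros((B, N))
    r = np.zeros((B, N))
    for t in range(T):
        x = r @ rnn.W_rec + inputs[t] @ rnn.W_in + rnn.b
        s = (1.0 - a) * s + a * x
        r = _rates(s)
        s_hist[t] = s
        r_hist[t] = r
    y = r_hist @ rnn.W_out

    scale = 1.0 / (T * B)
    err = y - targets
    loss = float(np.sum(err**2) * scale
                 + lam * (np.mean(r_hist**2) + np.mean(y**2)))

    dy = 2.0 * scale * err + 2.0 * lam * y / y.size
    gW_out = np.zeros_like(rnn.W_out)
    gW_rec = np.zeros_like(rnn.W_rec)
    gW_in = np.zeros_like(rnn.W_in)
    gb = np.zeros_like(rnn.b)

    g_next = np.zeros((B, N))          # dL/ds_{t+1}
    dphi = np.where(s_hist > 0, 1.0 - np.tanh(s_hist) ** 2, 0.0)
    r_reg = 2.0 * lam * r_hist / r_hist.size
    for t in range(T - 1, -1, -1):
        dr = dy[t] @ rnn.W_out.T + r_reg[t] + a * (g_next @ rnn.W_rec.T)
        g = dr * dphi[t] + (1.0 - a) * g_next
        gW_out += r_hist[t].T @ dy[t]
        ag = a * g
        r_prev = r_hist[t - 1] if t > 0 else np.zeros((B, N))
        gW_rec += r_prev.T @ ag
        gW_in += inputs[t].T @ ag
        gb += ag.sum(axis=0)
        g_next = g
    return loss, (gW_rec, gW_in, gW_out, gb)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(config: RNNConfig, verbose: bool = False) -> TrainedRNN:
    """Train the integrator network.

    A fixed set of ``n_trials`` training trials is optimized for
    ``epochs`` epochs of minibatch Adam; the per-epoch trace records the
    total normalized error on a held-out set of test trials.  Training
    aborts with diagnostics if that error rises for 10 consecutive epochs.
    """
    rng = np.random.default_rng(config.seed)
    W_rec, W_in, W_out, b = _init_weights(config, rng)
    rnn = TrainedRNN(W_rec=W_rec, W_in=W_in, W_out=W_out, b=b, config=config)

    train_inp, train_tgt = make_trial_batch(
        config, config.n_trials, seed=int(rng.integers(2**31))
    )
    n_test = max(20, config.n_trials // 5)
    test_inp, test_tgt = make_trial_batch(
        config, n_test, seed=int(rng.integers(2**31))
    )

    params = [rnn.W_rec, rnn.W_in, rnn.W_out, rnn.b]
    opt = _Adam(params, lr=config.learning_rate)
    n_rising = 0
    B = config.n_trials
    bs = min(config.batch_size, B)
    for epoch in range(config.epochs):
        # step decay keeps late training stable once the error is small
        if epoch in {int(0.6 * config.epochs), int(0.85 * config.epochs)}:
            opt.lr *= config.lr_decay
        order = rng.permutation(B)
        for start in range(0, B, bs):
            sel = order[start : start + bs]
            _, grads = _forward_backward(
                rnn, train_inp[:, sel, :], train_tgt[:, sel, :]
            )
            if config.grad_clip:
                norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
                if norm > config.grad_clip:
                    grads = [g * (config.grad_clip / norm) for g in grads]
            opt.step(params, grads)
        y_test = forward(rnn, test_inp)
        err = total_normalized_error(y_test, test_tgt)
        if rnn.nmse_trace and err > rnn.nmse_trace[-1]:
            n_rising += 1
            if n_rising >= 10:
                raise RuntimeError(
                    f"training diverged: test error rose for 10 consecutive "
                    f"epochs (epoch {epoch}, NMSE {err:.1f}); trace: "
                    f"{[f'{e:.1f}' for e in rnn.nmse_trace[-10:]]}"
                )
        else:
            n_rising = 0
        rnn.nmse_trace.append(err)
        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  total NMSE {err:8.3f}")
    return rnn


# ----------------------------------------------------------------------
# session generation and deactivation scoring
def generate_session(
    rnn: TrainedRNN,
    n_steps: int = 200_000,
    seed: int = 0,
    trial_len: int = 1000,
) -> Session:
    """Roll the trained network into an analysis session.

    The session concatenates independent trials of ``trial_len`` steps
    (each with its own random initial heading and velocity stream), matching
    the construction of the simulated sessions analyzed downstream; seams
    are recorded in ``meta["trial_seams"]``.  AHV is stored in rad/s, HD as
    the exact integral of the velocity input.
    """
    cfg = rnn.config
    n_trials = int(np.ceil(n_steps / trial_len))
    sess_cfg = RNNConfig(**{**asdict(cfg), "trial_len": trial_len,
                            "zero_ahv_fraction": 0.0})
    rng = np.random.default_rng(seed)
    inputs = np.zeros((trial_len, n_trials, 3))
    theta = np.zeros((trial_len, n_trials))
    for btrial in range(n_trials):
        theta0 = float(rng.uniform(0, TWO_PI))
        inp, tgt = make_trial_inputs(
            sess_cfg, theta0, seed=int(rng.integers(2**31))
        )
        inputs[:, btrial, :] = inp
        theta[:, btrial] = np.arctan2(tgt[:, 1], tgt[:, 0])
    _, rates = forward(rnn, inputs, return_rates=True)

    # time-major concatenation of trials, truncated to n_steps
    hd = np.mod(theta.T.reshape(-1), TWO_PI)[:n_steps]
    ahv_step = inputs[:, :, 2].T.reshape(-1)[:n_steps]
    rate_mat = rates.transpose(1, 0, 2).reshape(-1, rnn.n_units)[:n_steps].T
    return Session(
        hd=hd,
        ahv=ahv_step / cfg.dt,  # rad/step -> rad/s
        rates=rate_mat,
        dt=cfg.dt,
        unit_ids=[f"rnn{i:03d}" for i in range(rnn.n_units)],
        meta={
            "source": "rnn",
            "seed": seed,
            "trial_len": trial_len,
            "trial_seams": list(range(0, n_steps, trial_len)),
        },
    )


def deactivate_and_score(
    rnn: TrainedRNN,
    unit_ids,
    trials: tuple[np.ndarray, np.ndarray],
) -> float:
    """Total normalized error with selected units silenced.

    ``unit_ids`` are indices into the hidden population whose states are
    zeroed after every Euler step; ``trials`` is an ``(inputs, targets)``
    batch.  An empty set scores the intact network.
    """
    inputs, targets = trials
    mask = np.zeros(rnn.n_units, dtype=bool)
    idx = np.asarray(sorted(unit_ids), dtype=int) if len(unit_ids) else None
    if idx is not None:
        if idx.min() < 0 or idx.max() >= rnn.n_units:
            raise ValueError("unit index out of range")
        mask[idx] = True
    y = forward(rnn, inputs, deactivate=mask if idx is not None else None)
    return total_normalized_error(y, targets)
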