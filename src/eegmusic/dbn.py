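"""Deep belief network: stacked RBMs, contrastive divergence, softmax head.

The model is the classic greedy-layerwise construction: a Gaussian-visible
restricted Boltzmann machine on the (z-scored, real-valued) features, then
Bernoulli RBMs on the propagated hidden probabilities, each pretrained with
CD-k.  Supervised fine-tuning attaches a softmax output layer and runs
full-batch gradient descent on the cross-entropy loss with backpropagation
through every sigmoid layer, recording a per-iteration Brier-style MSE trace
(mean over training rows of the squared distance between the predicted
probability vector and the one-hot label).

The user-facing surface is ``DBNClassifier`` (a model object built from a
feature matrix and a training configuration) whose ``fit()`` returns a
``DBNClassifierResults`` carrying the trained parameter stack, the traces,
``predict`` and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class RBMParams:
    """One restricted Boltzmann machine layer."""

    W: np.ndarray           # [n_hidden x n_visible]
    b_visible: np.ndarray   # [n_visible]
    b_hidden: np.ndarray    # [n_hidden]
    unit_type: str = "bernoulli"  # visible units: "bernoulli" | "gaussian"

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b_visible.copy(),
                         self.b_hidden.copy(), self.unit_type)


@dataclass
class DBNModel:
    """Ordered RBM stack (input -> deepest) plus the softmax parameters.

    ``theta`` has one row per class over the top hidden layer plus a bias
    column (appended last).
    """

    rbms: list
    theta: np.ndarray            # [k_classes x (top_dim + 1)]
    class_labels: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.theta.shape[0]

    def copy(self) -> "DBNModel":
        return DBNModel([r.copy() for r in self.rbms], self.theta.copy(),
                        list(self.class_labels))


@dataclass(frozen=True)
class TrainConfig:
    """All knobs of pretraining and fine-tuning; the seed is mandatory."""

    layer_sizes: tuple = (50, 40, 30)
    cd_k: int = 1
    lr_pretrain: float = 0.05
    epochs_pretrain: int = 15
    lr_finetune: float = 0.5
    iterations_finetune: int = 500
    batch_size: int = 0          # 0 -> full batch
    seed: int = 0
    shuffle_each_iteration: bool = True
    momentum: float = 0.0
    weight_decay: float = 0.0
    n_classes: int = 5


@dataclass
class TrainTrace:
    """Per-iteration fine-tuning diagnostics."""

    mse_per_iteration: np.ndarray
    train_accuracy_per_iteration: np.ndarray


# ---------------------------------------------------------------------------
# RBM primitives
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def rbm_init(n_visible: int, n_hidden: int, unit_type: str = "bernoulli",
             seed: int = 0) -> RBMParams:
    """Seeded Gaussian(0, 0.01) weights, zero biases."""
    if n_visible < 1 or n_hidden < 1:
        raise ValueError("layer dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    W = 0.01 * rng.standard_normal((n_hidden, n_visible))
    return RBMParams(W=W, b_visible=np.zeros(n_visible),
                     b_hidden=np.zeros(n_hidden), unit_type=unit_type)


def rbm_conditional_hidden(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h=1 | v) = sigmoid(W v + b_hidden); v may be a batch [n x n_vis]."""
    v = np.asarray(v, float)
    single = v.ndim == 1
    p = _sigmoid(np.atleast_2d(v) @ rbm.W.T + rbm.b_hidden)
    return p[0] if single else p


def rbm_conditional_visible(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    """Mean of the visible units given hidden: sigmoid for Bernoulli units,
    the linear mean ``W^T h + b`` for Gaussian units (unit variance)."""
    h = np.asarray(h, float)
    single = h.ndim == 1
    act = np.atleast_2d(h) @ rbm.W + rbm.b_visible
    out = act if rbm.unit_type == "gaussian" else _sigmoid(act)
    return out[0] if single else out


def cd_k_update(rbm: RBMParams, batch: np.ndarray, k: int = 1,
                lr: float = 0.1, seed: int | np.random.Generator = 0,
                ) -> RBMParams:
    """One contrastive-divergence step; returns updated parameters.

    Positive statistics from the data, negative statistics after ``k``
    seeded Gibbs steps (hidden units sampled, visible units mean-field).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    v0 = np.atleast_2d(np.asarray(batch, float))
    n = v0.shape[0]
    ph0 = rbm_conditional_hidden(rbm, v0)

    ph = ph0
    v = v0
    for _ in range(k):
        h = (rng.random(ph.shape) < ph).astype(float)
        v = rbm_conditional_visible(rbm, h)
        ph = rbm_conditional_hidden(rbm, v)

    dW = (ph0.T @ v0 - ph.T @ v) / n
    db_v = (v0 - v).mean(axis=0)
    db_h = (ph0 - ph).mean(axis=0)
    out = rbm.copy()
    out.W += lr * dW
    out.b_visible += lr * db_v
    out.b_hidden += lr * db_h
    return out


def reconstruction_error(rbm: RBMParams, data: np.ndarray) -> float:
    """RMS one-step reconstruction error (mean-field pass down and up)."""
    ph = rbm_conditional_hidden(rbm, data)
    recon = rbm_conditional_visible(rbm, ph)
    return float(np.sqrt(np.mean((np.atleast_2d(data) - recon) ** 2)))


def pretrain(features: FeatureMatrix | np.ndarray, config: TrainConfig,
             train_mask: np.ndarray | None = None) -> list:
    """Greedy layerwise CD-k pretraining of the RBM stack.

    The first RBM has Gaussian visible units (features are real-valued
    z-scores); deeper RBMs are Bernoulli and are fed the propagated hidden
    probabilities.  ``epochs_pretrain = 0`` returns the freshly initialized,
    untrained stack.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    if train_mask is not None:
        X = X[np.asarray(train_mask, bool)]
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    sizes = list(config.layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least one hidden layer")
    if sizes[0] != X.shape[1]:
        raise ValueError(
            f"layer_sizes[0]={sizes[0]} must equal the feature dim {X.shape[1]}")

    rng = np.random.default_rng(config.seed)
    rbms = []
    data = X
    for li in range(len(sizes) - 1):
        unit_type = "gaussian" if li == 0 else "bernoulli"
        rbm = rbm_init(sizes[li], sizes[li + 1], unit_type=unit_type,
                       seed=int(rng.integers(2**31)))
        n = data.shape[0]
        bs = config.batch_size if config.batch_size > 0 else n
        for _ in range(config.epochs_pretrain):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                batch = data[order[start:start + bs]]
                rbm = cd_k_update(rbm, batch, k=config.cd_k,
                                  lr=config.lr_pretrain, seed=rng)
        rbms.append(rbm)
        data = np.atleast_2d(rbm_conditional_hidden(rbm, data))
    return rbms


# ---------------------------------------------------------------------------
# Softmax head and fine-tuning
# ---------------------------------------------------------------------------

def softmax_probabilities(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class probabilities exp(theta_j^T x) / sum_i exp(theta_i^T x).

    ``x`` is one sample or a batch, *without* the bias term (the bias column
    of theta is applied internally).  Computed with max-subtraction, so it is
    invariant to adding a constant vector to every theta_j.
    """
    theta = np.asarray(theta, float)
    x = np.asarray(x, float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite parameters or inputs")
    single = x.ndim == 1
    Xb = np.hstack([np.atleast_2d(x), np.ones((np.atleast_2d(x).shape[0], 1))])
    logits = Xb @ theta.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def _forward(model: DBNModel, X: np.ndarray):
    """Activations through the sigmoid stack; returns (hiddens, probs)."""
    H = np.atleast_2d(np.asarray(X, float))
    hiddens = [H]
    for rbm in model.rbms:
        H = _sigmoid(H @ rbm.W.T + rbm.b_hidden)
        hiddens.append(H)
    probs = softmax_probabilities(model.theta, H)
    return hiddens, np.atleast_2d(probs)


def loss_and_gradients(model: DBNModel, X: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its analytic gradients.

    Returns ``(loss, grad_theta, rbm_grads)`` with ``rbm_grads`` a list of
    ``(gW, gb_hidden)`` per layer, shallowest first.  Exposed so the
    gradients can be verified against finite differences.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, int)
    n = X.shape[0]
    hiddens, P = _forward(model, X)
    Y = np.zeros_like(P)
    Y[np.arange(n), y] = 1.0
    loss = float(-np.mean(np.log(P[np.arange(n), y] + 1e-300)))

    top = hiddens[-1]
    top_b = np.hstack([top, np.ones((n, 1))])
    delta = (P - Y) / n                       # [n x k]
    grad_theta = delta.T @ top_b

    dH = delta @ model.theta[:, :-1]
    rbm_grads = []
    for li in range(len(model.rbms) - 1, -1, -1):
        H = hiddens[li + 1]
        dZ = dH * H * (1.0 - H)
        gW = dZ.T @ hiddens[li]
        gb = dZ.sum(axis=0)
        rbm_grads.append((gW, gb))
        dH = dZ @ model.rbms[li].W
    rbm_grads.reverse()
    return loss, grad_theta, rbm_grads


def _brier_mse(P: np.ndarray, y: np.ndarray) -> float:
    Y = np.zeros_like(P)
    Y[np.arange(P.shape[0]), y] = 1.0
    return float(np.mean(np.sum((P - Y) ** 2, axis=1)))


def finetune(model: DBNModel, X: np.ndarray, y: np.ndarray,
             config: TrainConfig):
    """Supervised gradient-descent fine-tuning of the whole stack.

    Per iteration: (seeded) reshuffle, one pass of gradient descent over the
    batches, then the Brier MSE and training accuracy are recorded.  A
    non-finite loss aborts, returning the state at the last finite iteration.
    """
    model = model.copy()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, int)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    bs = config.batch_size if config.batch_size > 0 else n

    vel_theta = np.zeros_like(model.theta)
    vel_rbm = [(np.zeros_like(r.W), np.zeros_like(r.b_hidden))
               for r in model.rbms]

    mse_trace, acc_trace = [], []
    last_good = model.copy()
    for _ in range(config.iterations_finetune):
        order = (rng.permutation(n) if config.shuffle_each_iteration
                 else np.arange(n))
        diverged = False
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, g_theta, g_rbms = loss_and_gradients(model, X[idx], y[idx])
            if not np.isfinite(loss):
                diverged = True
                break
            vel_theta = (config.momentum * vel_theta
                         - config.lr_finetune * (g_theta
                                                 + config.weight_decay
                                                 * model.theta))
            model.theta += vel_theta
            for li, (gW, gb) in enumerate(g_rbms):
                vW, vb = vel_rbm[li]
                vW = (config.momentum * vW
                      - config.lr_finetune * (gW + config.weight_decay
                                              * model.rbms[li].W))
                vb = config.momentum * vb - config.lr_finetune * gb
                model.rbms[li].W += vW
                model.rbms[li].b_hidden += vb
                vel_rbm[li] = (vW, vb)
        if diverged:
            model = last_good
            break
        _, P = _forward(model, X)
        mse_trace.append(_brier_mse(P, y))
        acc_trace.append(float(np.mean(P.argmax(axis=1) == y)))
        last_good = model.copy()
    trace = TrainTrace(mse_per_iteration=np.asarray(mse_trace),
                       train_accuracy_per_iteration=np.asarray(acc_trace))
    return model, trace


def predict(model: DBNModel, X: np.ndarray):
    """Predicted labels (argmax, ties to the lowest class) and probabilities."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.rbms[0].n_visible:
        raise ValueError(
            f"expected {model.rbms[0].n_visible} feature columns, "
            f"got {X.shape[1]}")
    _, P = _forward(model, X)
    return P.argmax(axis=1), P


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class DBNClassifier:
    """Deep-belief-network classifier over a 50-column EEG feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Standardized feature rows with aligned labels.
    config : TrainConfig
        Architecture, pretraining and fine-tuning settings.
    train_mask : array of bool, optional
        Rows used for training; all rows when omitted.
    """

    def __init__(self, features: FeatureMatrix, config: TrainConfig,
                 train_mask: np.ndarray | None = None):
        self.features = features
        self.config = config
        self.train_mask = (np.ones(features.n_epochs, bool)
                           if train_mask is None
                           else np.asarray(train_mask, bool))

    def fit(self) -> "DBNClassifierResults":
        """Pretrain the stack, fine-tune with the softmax head."""
        cfg = self.config
        Xtr = self.features.X[self.train_mask]
        ytr = self.features.y[self.train_mask]
        rbms = pretrain(Xtr, cfg)
        top_dim = cfg.layer_sizes[-1]
        theta = np.zeros((cfg.n_classes, top_dim + 1))
        model = DBNModel(rbms=rbms, theta=theta,
                         class_labels=list(range(cfg.n_classes)))
        model, trace = finetune(model, Xtr, ytr, cfg)
        return DBNClassifierResults(self, model, trace)


class DBNClassifierResults:
    """Fitted DBN: parameters, training traces, prediction and summary."""

    def __init__(self, classifier: DBNClassifier, model: DBNModel,
                 trace: TrainTrace):
        self.classifier = classifier
        self.model = model
        self.trace = trace

    def predict(self, X: np.ndarray):
        return predict(self.model, X)

    @property
    def final_mse(self) -> float:
        return float(self.trace.mse_per_iteration[-1])

    @property
    def final_train_accuracy(self) -> float:
        return float(self.trace.train_accuracy_per_iteration[-1])

    def summary(self) -> str:
        cfg = self.classifier.config
        lines = [
            "DBN classifier results",
            "=" * 46,
            f"architecture        {'-'.join(map(str, cfg.layer_sizes))}"
            f" -> softmax({cfg.n_classes})",
            f"training rows       {int(self.classifier.train_mask.sum())}",
            f"pretrain            CD-{cfg.cd_k}, {cfg.epochs_pretrain} epochs,"
            f" lr={cfg.lr_pretrain}",
            f"finetune            {cfg.iterations_finetune} iterations,"
            f" lr={cfg.lr_finetune}",
            f"final train MSE     {self.final_mse:.4f}",
            f"final train acc     {100 * self.final_train_accuracy:.2f}%",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_mse_trace(self, ax=None):
        """MSE-vs-iteration curve; creates an axis when none is given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.mse_per_iteration)
        ax.set_xlabel("iteration")
        ax.set_ylabel("training MSE")
        ax.set_title("classifier MSE per fine-tuning iteration")
        return ax

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        save_model(self.model, path, config=self.classifier.config)


def save_model(model: DBNModel, path, config: TrainConfig | None = None) -> None:
    """Serialize a model (full precision) to a JSON document."""
    doc = {
        "rbms": [
            {
                "W": r.W.tolist(),
                "b_visible": r.b_visible.tolist(),
                "b_hidden": r.b_hidden.tolist(),
                "unit_type": r.unit_type,
            }
            for r in model.rbms
        ],
        "theta": model.theta.tolist(),
        "class_labels": list(model.class_labels),
    }
    if config is not None:
        doc["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in vars(config).items()}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> DBNModel:
    with open(path) as fh:
        doc = json.load(fh)
    rbms = [RBMParams(W=np.asarray(r["W"]),
                      b_visible=np.asarray(r["b_visible"]),
                      b_hidden=np.asarray(r["b_hidden"]),
                      unit_type=r["unit_type"]) for r in doc["rbms"]]
    return DBNModel(rbms=rbms, theta=np.asarray(doc["theta"]),
                    class_labels=doc["class_labels"])
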