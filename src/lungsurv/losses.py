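"""Imbalance-aware binary classification losses, including PEN-BCE.

All losses operate on predicted probabilities ``p`` in (0, 1) and binary
labels ``y``, averaged over the batch with natural logarithms.  The family:

* ``bce`` — plain binary cross-entropy,
  ``-(1/N) Σ [y ln p + (1-y) ln(1-p)]``.
* ``weighted_bce`` — a weight ``w`` on the positive term.
* ``focal_loss`` — modulation ``(1-p_t)^γ`` with ``p_t = p`` for positives
  and ``1-p`` for negatives, down-weighting easy examples.
* ``asl`` — asymmetric focusing ``γ+ / γ-`` with probability shifting
  ``p_m = max(p - margin, 0)`` that hard-thresholds easy negatives.
* ``rwwce`` — real-world-weighted CE with marginal false-negative /
  false-positive costs.
* ``pen_bce`` — the penalized BCE: BCE plus hinge-squared penalties
  ``α·y·max(0, p_FN - p)²`` and ``β·(1-y)·max(0, p - p_FP)²`` that charge
  confident false negatives (positives predicted below ``p_FN``) and
  confident false positives (negatives predicted above ``p_FP``).

Every loss ships a matching analytic gradient with respect to ``p`` (the
subgradient 0 is taken exactly at hinge points), so the same code path drives
both the pure-function API and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # probability clip applied before any log


@dataclass(frozen=True)
class LossParams:
    """PEN-BCE hyper-parameters: FN/FP weights and probability thresholds.

    Defaults are the best-performing combination of the published grid.
    """

    alpha: float = 1.0
    beta: float = 5.0
    p_fn: float = 0.50
    p_fp: float = 0.20

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0 <= self.p_fn <= 1 and 0 <= self.p_fp <= 1):
            raise ValueError("p_fn and p_fp must lie in [0, 1]")


#: the published (α, β, p_FN, p_FP) hyper-parameter grid
PEN_BCE_GRID: tuple[LossParams, ...] = (
    LossParams(5.00, 1.00, 0.40, 0.50),
    LossParams(5.00, 1.00, 0.60, 0.50),
    LossParams(5.00, 1.00, 0.70, 0.50),
    LossParams(1.00, 5.00, 0.50, 0.20),
    LossParams(1.00, 5.00, 0.50, 0.30),
    LossParams(1.00, 5.00, 0.50, 0.40),
    LossParams(5.00, 5.00, 0.50, 0.50),
    LossParams(5.00, 5.00, 0.75, 0.25),
    LossParams(5.00, 5.00, 0.60, 0.20),
)


def _prep(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.clip(np.asarray(probs, dtype=np.float64).ravel(), EPS, 1.0 - EPS)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    if y.size == 0:
        raise ValueError("empty batch")
    return p, y


# ---------------------------------------------------------------- values

def bce(probs, labels) -> float:
    p, y = _prep(probs, labels)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def weighted_bce(probs, labels, w: float) -> float:
    if w <= 0:
        raise ValueError("w must be > 0")
    p, y = _prep(probs, labels)
    return float(-np.mean(w * y * np.log(p) + (1 - y) * np.log1p(-p)))


def focal_loss(probs, labels, gamma: float, *, strict_as_printed: bool = False) -> float:
    """Focal loss with ``p_t`` convention; ``strict_as_printed`` keeps the
    extra ``y`` factor (which silences negative samples entirely)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, y = _prep(probs, labels)
    p_t = np.where(y == 1, p, 1 - p)
    per = -((1 - p_t) ** gamma) * np.log(p_t)
    if strict_as_printed:
        per = y * per
    return float(np.mean(per))


def asl(probs, labels, gamma_pos: float, gamma_neg: float, margin: float) -> float:
    if margin < 0:
        raise ValueError("margin must be >= 0")
    p, y = _prep(probs, labels)
    p_m = np.maximum(p - margin, 0.0)
    pos = y * np.log(p) * (1 - p) ** gamma_pos
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log = np.log1p(-np.clip(p_m, 0.0, 1.0 - EPS))
    neg = (1 - y) * neg_log * np.where(p_m > 0, p_m ** gamma_neg, 0.0 if gamma_neg > 0 else 1.0)
    return float(-np.mean(pos + neg))


def rwwce(probs, labels, w_mcfn: float, w_mcfp: float) -> float:
    if w_mcfn <= 0 or w_mcfp <= 0:
        raise ValueError("weights must be > 0")
    p, y = _prep(probs, labels)
    return float(-np.mean(w_mcfn * y * np.log(p) + w_mcfp * (1 - y) * np.log1p(-p)))


def pen_bce(probs, labels, params: LossParams = LossParams()) -> float:
    p, y = _prep(probs, labels)
    ce = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    fn_pen = params.alpha * y * np.maximum(0.0, params.p_fn - p) ** 2
    fp_pen = params.beta * (1 - y) * np.maximum(0.0, p - params.p_fp) ** 2
    return float(np.mean(ce + fn_pen + fp_pen))


# ------------------------------------------------------------- gradients
# d(loss)/d(p_i), including the 1/N batch factor; hinge points take
# subgradient 0 so the gradient is defined everywhere.

def bce_grad(probs, labels) -> np.ndarray:
    p, y = _prep(probs, labels)
    return (-y / p + (1 - y) / (1 - p)) / p.size


def weighted_bce_grad(probs, labels, w: float) -> np.ndarray:
    p, y = _prep(probs, labels)
    return (-w * y / p + (1 - y) / (1 - p)) / p.size


def focal_loss_grad(probs, labels, gamma: float) -> np.ndarray:
    p, y = _prep(probs, labels)
    p_t = np.where(y == 1, p, 1 - p)
    one_m = 1 - p_t
    if gamma == 0:
        d_pt = -1.0 / p_t
    else:
        d_pt = gamma * one_m ** (gamma - 1) * np.log(p_t) - one_m ** gamma / p_t
    return d_pt * np.where(y == 1, 1.0, -1.0) / p.size


def asl_grad(probs, labels, gamma_pos: float, gamma_neg: float, margin: float) -> np.ndarray:
    p, y = _prep(probs, labels)
    one_m = 1 - p
    if gamma_pos == 0:
        d_pos = -1.0 / p
    else:
        d_pos = gamma_pos * one_m ** (gamma_pos - 1) * np.log(p) - one_m ** gamma_pos / p
    p_m = np.maximum(p - margin, 0.0)
    p_m_c = np.clip(p_m, 0.0, 1.0 - EPS)
    active = p_m > 0
    if gamma_neg == 0:
        d_neg_inner = 1.0 / (1 - p_m_c)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            d_neg_inner = np.where(
                active,
                p_m_c ** gamma_neg / (1 - p_m_c)
                - gamma_neg * np.where(active, p_m_c, 1.0) ** (gamma_neg - 1) * np.log1p(-p_m_c),
                0.0,
            )
    d_neg = np.where(active, d_neg_inner, 0.0)
    return (y * d_pos + (1 - y) * d_neg) / p.size


def rwwce_grad(probs, labels, w_mcfn: float, w_mcfp: float) -> np.ndarray:
    p, y = _prep(probs, labels)
    return (-w_mcfn * y / p + w_mcfp * (1 - y) / (1 - p)) / p.size


def pen_bce_grad(probs, labels, params: LossParams = LossParams()) -> np.ndarray:
    p, y = _prep(probs, labels)
    g = -y / p + (1 - y) / (1 - p)
    g = g - 2.0 * params.alpha * y * np.maximum(0.0, params.p_fn - p)
    g = g + 2.0 * params.beta * (1 - y) * np.maximum(0.0, p - params.p_fp)
    return g / p.size


# ------------------------------------------------- training criteria

class Criterion:
    """A loss usable by the training loop: value plus gradient w.r.t. p.

    Wraps the pure functions above so the numbers seen in training are, by
    construction, identical to the array API.
    """

    def __init__(self, name: str, value_fn, grad_fn):
        self.name = name
        self._value = value_fn
        self._grad = grad_fn

    def value(self, probs, labels) -> float:
        return self._value(probs, labels)

    def grad(self, probs, labels) -> np.ndarray:
        return self._grad(probs, labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Criterion({self.name})"


def make_criterion(name: str, **kwargs) -> Criterion:
    """Build a named criterion: bce, weighted_bce, focal, asl, rwwce, pen_bce."""
    if name == "bce":
        return Criterion("bce", bce, bce_grad)
    if name == "weighted_bce":
        w = kwargs["w"]
        return Criterion(name, lambda p, y: weighted_bce(p, y, w),
                         lambda p, y: weighted_bce_grad(p, y, w))
    if name == "focal":
        g = kwargs["gamma"]
        return Criterion(name, lambda p, y: focal_loss(p, y, g),
                         lambda p, y: focal_loss_grad(p, y, g))
    if name == "asl":
        gp, gn, m = kwargs["gamma_pos"], kwargs["gamma_neg"], kwargs["margin"]
        return Criterion(name, lambda p, y: asl(p, y, gp, gn, m),
                         lambda p, y: asl_grad(p, y, gp, gn, m))
    if name == "rwwce":
        wn, wp = kwargs["w_mcfn"], kwargs["w_mcfp"]
        return Criterion(name, lambda p, y: rwwce(p, y, wn, wp),
                         lambda p, y: rwwce_grad(p, y, wn, wp))
    if name == "pen_bce":
        params = kwargs.get("params", LossParams())
        return Criterion(name, lambda p, y: pen_bce(p, y, params),
                         lambda p, y: pen_bce_grad(p, y, params))
    raise ValueError(f"unknown loss {name!r}")


# ------------------------------------------------------------ loss curves

def loss_curve(loss_name: str, p_grid, y_fixed: int = 1, **kwargs) -> np.ndarray:
    """Per-sample loss over a probability grid at a fixed label.

    Returns an (n, 2) array of (p, loss) rows — the data behind the usual
    BCE-vs-PEN-BCE comparison plot.
    """
    crit = make_criterion(loss_name, **kwargs)
    grid = np.asarray(p_grid, dtype=np.float64)
    if grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("p grid must lie strictly inside (0, 1)")
    vals = np.array([crit.value([p], [y_fixed]) for p in grid])
    return np.column_stack([grid, vals])


def export_loss_curves(path, p_grid=None, params: LossParams = LossParams(),
                       y_fixed: int = 1, plot: bool = False) -> None:
    """Write BCE and PEN-BCE curves over a grid to TSV (and optionally PNG)."""
    import pandas as pd

    if p_grid is None:
        p_grid = np.linspace(0.01, 0.99, 99)
    b = loss_curve("bce", p_grid, y_fixed)
    pb = loss_curve("pen_bce", p_grid, y_fixed, params=params)
    df = pd.DataFrame({"p": b[:, 0], "bce": b[:, 1], "pen_bce": pb[:, 1]})
    df.to_csv(path, sep="\t", index=False)
    if plot:  # pragma: no cover - cosmetic
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(df["p"], df["bce"], "b--", label="BCE")
        ax.plot(df["p"], df["pen_bce"], "r-",
                label=f"PEN-BCE (α={params.alpha}, p_FN={params.p_fn})")
        ax.set_xlabel("predicted probability p")
        ax.set_ylabel(f"loss (y={y_fixed})")
        ax.legend()
        fig.savefig(str(path).rsplit(".", 1)[0] + ".png", dpi=120)
        plt.close(fig)
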