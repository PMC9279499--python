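"""First-order optimizer update rules: SGDM, RMSProp and ADAM.

Each rule maintains exponentially weighted moving averages of the gradient
and/or its square and applies, per step,

    SGDM:    S = b*S + (1-b)*dW;                W -= a*S
    RMSProp: V = b*V + (1-b)*dW^2;              W -= a * dW / sqrt(V + eps)
    ADAM:    S = b1*S + (1-b1)*dW
             V = b2*V + (1-b2)*dW^2
             W -= a * (S / (1 - b1^t)) / sqrt(V / (1 - b2^t) + eps)

ADAM's bias-correction divisors are the standard (1 - beta^t); the stabilizer
eps sits inside the square root.  The step counter t starts at 1 and
increments after each update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KINDS = ("sgdm", "rmsprop", "adam")


@dataclass
class OptimizerState:
    """Per-parameter-array optimizer state.

    `beta` is the single EWMA coefficient of SGDM/RMSProp; `beta1`/`beta2`
    are ADAM's first- and second-moment coefficients.  Accumulators are
    lazily initialized to zero arrays on the first update.
    """

    kind: str
    alpha: float = 1e-4
    beta: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    s_dw: np.ndarray | None = None
    v_dw: np.ndarray | None = None
    t: int = field(default=1)

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        for b in (self.beta, self.beta1, self.beta2):
            if not 0 <= b < 1:
                raise ValueError("momentum coefficients must be in [0, 1)")


def optimizer_step(
    state: OptimizerState, w: np.ndarray, dw: np.ndarray
) -> np.ndarray:
    """Apply one update of `state.kind` to parameters `w`; returns the new w.

    The state's accumulators and step counter are advanced in place.
    """
    w = np.asarray(w, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if w.shape != dw.shape:
        raise ValueError("parameter and gradient shapes differ")
    if state.s_dw is None:
        state.s_dw = np.zeros_like(w)
    if state.v_dw is None:
        state.v_dw = np.zeros_like(w)

    if state.kind == "sgdm":
        state.s_dw = state.beta * state.s_dw + (1 - state.beta) * dw
        new_w = w - state.alpha * state.s_dw
    elif state.kind == "rmsprop":
        state.v_dw = state.beta * state.v_dw + (1 - state.beta) * dw**2
        new_w = w - state.alpha * dw / np.sqrt(state.v_dw + state.epsilon)
    else:  # adam
        state.s_dw = state.beta1 * state.s_dw + (1 - state.beta1) * dw
        state.v_dw = state.beta2 * state.v_dw + (1 - state.beta2) * dw**2
        s_corr = state.s_dw / (1 - state.beta1**state.t)
        v_corr = state.v_dw / (1 - state.beta2**state.t)
        new_w = w - state.alpha * s_corr / np.sqrt(v_corr + state.epsilon)
    state.t += 1
    return new_w
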