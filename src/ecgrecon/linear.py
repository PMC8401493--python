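"""Least-squares linear lead reconstruction and its P-wave-segmented variant.

Under the single-dipole (cardiac vector) approximation any lead voltage is a
fixed linear combination of three independent leads,

    NewLead = Coef1*Lead1 + Coef2*Lead2 + Coef3*Lead3,

so each target lead is fitted by ordinary least squares on three acquired
leads (no intercept by default: the signals are high-pass filtered and the
dipole projection has no offset term).  The segmented variant fits two
coefficient sets -- beta0 on P-wave samples, beta1 on the rest -- because
least squares is dominated by the high-energy QRS complex and can underfit
the clinically relevant low-energy P wave.

The solver uses a numerically stable least-squares factorisation; its
equivalence with the explicit normal-equations (Gram inverse) solution is a
test, not the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConditioningError, EcgReconError
from .segmentation import (
    PWaveWindows,
    SegmentationParams,
    interleave_buffers,
    split_by_windows,
)

__all__ = [
    "LinearLeadRegression",
    "LinearLeadResults",
    "SegmentedLinearRegression",
    "SegmentedLinearResults",
    "fit_linear",
    "predict_linear",
    "fit_segmented",
    "predict_segmented",
]

_DEFAULT_COND_BOUND = 1e10


def _as_matrix(x, name: str, rows: int | None = None) -> np.ndarray:
    m = np.atleast_2d(np.asarray(x, dtype=float))
    if rows is not None and m.shape[0] != rows:
        raise EcgReconError(f"{name} must have {rows} rows, got {m.shape[0]}")
    return m


class LinearLeadRegression:
    """Least-squares model mapping 3 input leads to M target leads.

    Parameters
    ----------
    inputs : ndarray, shape (3, N)
        Acquired lead samples (mV).
    targets : ndarray, shape (M, N)
        Target lead samples (mV).
    input_names, target_names : sequence of str, optional
        Lead-name metadata carried into the results.
    intercept : bool
        Add a constant regressor (off by default).
    cond_bound : float
        Maximum allowed condition number of the input Gram matrix.
    """

    def __init__(self, inputs, targets, *, input_names=None,
                 target_names=None, intercept: bool = False,
                 cond_bound: float = _DEFAULT_COND_BOUND):
        self.inputs = _as_matrix(inputs, "inputs", rows=3)
        self.targets = _as_matrix(targets, "targets")
        if self.inputs.shape[1] != self.targets.shape[1]:
            raise EcgReconError(
                "inputs and targets must share the sample count, got "
                f"{self.inputs.shape[1]} vs {self.targets.shape[1]}"
            )
        if self.inputs.shape[1] < 3:
            raise EcgReconError("need at least 3 samples to fit 3 coefficients")
        self.intercept = intercept
        self.cond_bound = cond_bound
        self.input_names = list(input_names or
                                [f"in{i + 1}" for i in range(3)])
        self.target_names = list(
            target_names or
            [f"lead{k + 1}" for k in range(self.targets.shape[0])]
        )

    def _design(self, inputs: np.ndarray) -> np.ndarray:
        a = inputs.T
        if self.intercept:
            a = np.column_stack([a, np.ones(a.shape[0])])
        return a

    def fit(self) -> "LinearLeadResults":
        a = self._design(self.inputs)
        gram = a.T @ a
        cond = float(np.linalg.cond(gram))
        if not np.isfinite(cond) or cond > self.cond_bound:
            raise ConditioningError(cond, self.cond_bound)
        coef, *_ = np.linalg.lstsq(a, self.targets.T, rcond=None)
        resid = self.targets - (a @ coef).T
        return LinearLeadResults(
            model=self,
            coefficients=coef.T[:, :3],
            intercepts=(coef.T[:, 3] if self.intercept
                        else np.zeros(self.targets.shape[0])),
            train_sse=np.sum(resid * resid, axis=1),
            gram_condition=cond,
            n_train=self.inputs.shape[1],
        )


@dataclass
class LinearLeadResults:
    """Fitted coefficients plus training diagnostics."""

    model: LinearLeadRegression
    coefficients: np.ndarray  # (M, 3)
    intercepts: np.ndarray    # (M,)
    train_sse: np.ndarray     # (M,)
    gram_condition: float
    n_train: int

    @property
    def input_names(self) -> list[str]:
        return self.model.input_names

    @property
    def target_names(self) -> list[str]:
        return self.model.target_names

    def predict(self, inputs) -> np.ndarray:
        """Reconstruct all target leads for new 3xN input samples."""
        x = _as_matrix(inputs, "inputs", rows=3)
        return self.coefficients @ x + self.intercepts[:, None]

    def summary(self) -> str:
        lines = [
            "Linear lead reconstruction (least squares)",
            f"  inputs : {', '.join(self.input_names)}"
            f"   n_train={self.n_train}"
            f"   cond(Gram)={self.gram_condition:.3e}",
            f"  {'lead':>8s}  {'Coef1':>12s} {'Coef2':>12s} {'Coef3':>12s}"
            f" {'train RMS (uV)':>15s}",
        ]
        rms = 1000.0 * np.sqrt(self.train_sse / self.n_train)
        for k, name in enumerate(self.target_names):
            c = self.coefficients[k]
            lines.append(
                f"  {name:>8s}  {c[0]:>12.6f} {c[1]:>12.6f} {c[2]:>12.6f}"
                f" {rms[k]:>15.3f}"
            )
        return "\n".join(lines)

    def save(self, path) -> Path:
        """Plain-text coefficient table (one target lead per line)."""
        path = Path(path)
        lines = ["# target_lead coef1 coef2 coef3 intercept"]
        lines.append("# inputs: " + " ".join(self.input_names))
        for k, name in enumerate(self.target_names):
            c = self.coefficients[k]
            lines.append(
                f"{name} {c[0]:.12g} {c[1]:.12g} {c[2]:.12g} "
                f"{self.intercepts[k]:.12g}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


class SegmentedLinearRegression:
    """Dual-regressor model: beta0 on P-wave samples, beta1 on the rest.

    Falls back to the plain fit for a buffer that is too small or rank
    deficient (with a warning), so degenerate segmentations degrade
    gracefully to simple linear regression.
    """

    def __init__(self, inputs, targets, windows: PWaveWindows, *,
                 params: SegmentationParams | None = None,
                 input_names=None, target_names=None,
                 cond_bound: float = _DEFAULT_COND_BOUND):
        self.inputs = _as_matrix(inputs, "inputs", rows=3)
        self.targets = _as_matrix(targets, "targets")
        self.windows = windows
        self.params = params or SegmentationParams()
        self.input_names = input_names
        self.target_names = target_names
        self.cond_bound = cond_bound

    def fit(self) -> "SegmentedLinearResults":
        in0, in1, idx0, idx1 = split_by_windows(self.inputs, self.windows)
        tg0, tg1, _, _ = split_by_windows(self.targets, self.windows)
        overall = LinearLeadRegression(
            self.inputs, self.targets, input_names=self.input_names,
            target_names=self.target_names, cond_bound=self.cond_bound,
        ).fit()

        def _buffer_fit(x, y, label):
            if x.shape[1] < 3:
                warnings.warn(
                    f"{label} buffer has {x.shape[1]} samples; "
                    "falling back to the unsegmented fit", stacklevel=3)
                return overall
            try:
                return LinearLeadRegression(
                    x, y, input_names=self.input_names,
                    target_names=self.target_names,
                    cond_bound=self.cond_bound,
                ).fit()
            except ConditioningError as exc:
                warnings.warn(
                    f"{label} buffer rank deficient ({exc}); "
                    "falling back to the unsegmented fit", stacklevel=3)
                return overall

        beta0 = _buffer_fit(in0, tg0, "P-wave (0)")
        beta1 = _buffer_fit(in1, tg1, "rest (1)")
        return SegmentedLinearResults(self, beta0, beta1)


@dataclass
class SegmentedLinearResults:
    """Two fitted coefficient sets sharing lead-name metadata."""

    model: SegmentedLinearRegression
    beta0: LinearLeadResults
    beta1: LinearLeadResults

    @property
    def target_names(self) -> list[str]:
        return self.beta1.target_names

    def predict(self, inputs, windows: PWaveWindows) -> np.ndarray:
        """Predict with beta0 inside P windows and beta1 elsewhere.

        The two buffer predictions are re-interleaved exactly, so the
        output has the input's sample count.
        """
        x = _as_matrix(inputs, "inputs", rows=3)
        in0, in1, idx0, idx1 = split_by_windows(x, windows)
        out0 = self.beta0.predict(in0) if idx0.size else \
            np.empty((self.beta0.coefficients.shape[0], 0))
        out1 = self.beta1.predict(in1) if idx1.size else \
            np.empty((self.beta1.coefficients.shape[0], 0))
        return interleave_buffers(out0, out1, idx0, idx1)

    def summary(self) -> str:
        return ("Segmented linear lead reconstruction\n"
                "== beta0 (P-wave buffer) ==\n" + self.beta0.summary() +
                "\n== beta1 (rest) ==\n" + self.beta1.summary())


# --- thin functional surface ----------------------------------------------

def fit_linear(inputs, targets, **kwargs) -> LinearLeadResults:
    """Least-squares fit of 3 input leads to M target leads."""
    return LinearLeadRegression(inputs, targets, **kwargs).fit()


def predict_linear(results: LinearLeadResults, inputs) -> np.ndarray:
    return results.predict(inputs)


def fit_segmented(inputs, targets, windows: PWaveWindows,
                  **kwargs) -> SegmentedLinearResults:
    """Dual-regressor fit on the P-wave buffer and the rest."""
    return SegmentedLinearRegression(inputs, targets, windows, **kwargs).fit()


def predict_segmented(results: SegmentedLinearResults, inputs,
                      windows: PWaveWindows) -> np.ndarray:
    return results.predict(inputs, windows)
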