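"""Piecewise-linear secretion-rate functions.

The deconvolution step represents the C-peptide secretion rate CPSR(t) as a
continuous piecewise-linear function whose breakpoints are the sampling
times; beyond the last breakpoint the rate is held at the last node value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError


@dataclass
class PiecewiseLinearSecretion:
    """CPSR(t) in pmol/min: node values at breakpoints, linear in between,
    constant at the last node beyond the final breakpoint."""

    breakpoints: np.ndarray  # min, strictly increasing
    node_values: np.ndarray  # pmol/min, >= 0

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.node_values = np.asarray(self.node_values, dtype=float)
        if self.breakpoints.ndim != 1 or self.breakpoints.shape != self.node_values.shape:
            raise ValidationError("breakpoints and node_values must be 1-d arrays of equal length")
        if self.breakpoints.size < 1:
            raise ValidationError("at least one breakpoint is required")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValidationError("breakpoints must be strictly increasing")
        if np.any(self.node_values < -1e-12):
            raise ValidationError("node_values must be nonnegative")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("secretion is defined for t >= 0 only")
        # np.interp clamps on both sides; clamping below breakpoints[0] is
        # irrelevant because the first breakpoint is the start of the test.
        out = np.interp(t, self.breakpoints, self.node_values)
        return out if out.ndim else float(out)

    def slopes(self) -> np.ndarray:
        """Slope of each linear segment (pmol/min^2)."""
        return np.diff(self.node_values) / np.diff(self.breakpoints)


def evaluate_secretion(sr: PiecewiseLinearSecretion, t) -> float:
    """Evaluate CPSR at time(s) ``t`` (min, nonnegative)."""
    return sr(t)
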