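"""Fourier decomposition of transformed displacement series.

Each individual's mean-removed series is decomposed by FFT into periodogram
ordinates psi_f = |F_f|**2 / L and phases theta_f = arg(F_f) at the whole-
cycle frequencies f = 1..L/2-1. The zero frequency carries no information
after mean removal and the Nyquist component is excluded: its phase is
degenerate (0 or pi) and its ordinate is a squared real Gaussian rather than
exponential, which would break the Whittle likelihood downstream. Frequency f
counts whole cycles per record, so the time scale of frequency f is L/f days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TransformedPanel

__all__ = ["SpectralDecomposition", "decompose"]


@dataclass
class SpectralDecomposition:
    """Phases and periodogram ordinates of an N-individual panel.

    phases: (l, N) radians in (-pi, pi]; ordinates: (m, N) non-negative,
    with l = m = L/2 - 1 and frequency index f = 1..l (cycles per record).
    """

    phases: np.ndarray
    ordinates: np.ndarray
    L: int
    nyquist_ordinates: np.ndarray | None = None  # (N,), excluded from the model

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.ordinates = np.asarray(self.ordinates, dtype=float)
        if self.phases.shape != self.ordinates.shape:
            raise ValueError("phases and ordinates must have identical shape")
        if np.any(self.ordinates < 0):
            raise ValueError("periodogram ordinates must be non-negative")

    @property
    def l(self) -> int:
        return self.phases.shape[0]

    @property
    def m(self) -> int:
        return self.ordinates.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.phases.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(1, self.l + 1)

    def timescale_days(self, f: int) -> int:
        """Whole-day time scale of frequency index f (L/f, truncated)."""
        return self.L // f


def decompose(panel: TransformedPanel | np.ndarray) -> SpectralDecomposition:
    """Decompose a transformed panel into phases and periodogram ordinates.

    Parameters
    ----------
    panel:
        TransformedPanel or plain (N, L) array; L must be even and >= 4, and
        every series must have non-zero variance.
    """
    x = panel.values if isinstance(panel, TransformedPanel) else np.asarray(panel, float)
    if x.ndim != 2:
        raise ValueError("panel must be 2-D (individuals x days)")
    n, L = x.shape
    if L < 4 or L % 2 != 0:
        raise ValueError(f"series length must be even and >= 4, got L={L}")
    if np.any(np.ptp(x, axis=1) == 0):
        raise ValueError("zero-variance series cannot be decomposed")

    xc = x - x.mean(axis=1, keepdims=True)
    coef = np.fft.fft(xc, axis=1)  # (N, L)
    half = L // 2
    inner = coef[:, 1:half]  # f = 1..L/2-1
    psi = (np.abs(inner) ** 2 / L).T  # (l, N)
    theta = np.angle(inner).T
    # angle returns (-pi, pi]; -pi can appear from rounding, fold it to pi
    theta = np.where(theta <= -np.pi, np.pi, theta)
    nyq = np.abs(coef[:, half]) ** 2 / L
    return SpectralDecomposition(
        phases=theta, ordinates=psi, L=L, nyquist_ordinates=nyq
    )
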