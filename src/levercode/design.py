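"""Gaussian temporal basis and GLM design-matrix expansion.

Each behavioral variable is convolved with 21 evenly spaced Gaussian basis
functions (centers -3.0 ... +3.0 s in 0.3 s steps, half-width at half-height
0.52 s, unit peak, truncated beyond three standard deviations from each
center), giving 20 x 21 = 420 regressors.  A basis centered at +c seconds
lets the activity at time t depend on behavior at t - c, i.e. positive
centers reach into the behavioral past, so fitted kernels read as "behavior
preceding activity"; the convention can be flipped via ``past_positive``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .behavior import BehaviorMatrix, CANONICAL_COLUMNS, CATEGORIES

N_BASES = 21
CENTER_SPAN = 3.0  # s, outermost centers
CENTER_STEP = 0.3  # s
HWHM = 0.52  # s, half-width at half-height
TRUNCATION_SIGMAS = 3.0


@dataclass(frozen=True)
class BasisSet:
    """The canonical set of Gaussian temporal basis functions."""

    centers: np.ndarray  # (21,) s, symmetric about 0, strictly increasing
    hwhm: float  # s
    frame_rate: float  # Hz
    past_positive: bool = True
    truncation: float = TRUNCATION_SIGMAS

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if self.hwhm <= 0:
            raise ValueError("half-width at half-height must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("basis centers must be strictly increasing")
        if not np.allclose(c, -c[::-1]):
            raise ValueError("basis centers must be symmetric about 0")
        object.__setattr__(self, "centers", c)

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation implied by the half-width at half-height."""
        return self.hwhm / np.sqrt(2.0 * np.log(2.0))

    @property
    def n_bases(self) -> int:
        return len(self.centers)

    def lag_frames(self) -> np.ndarray:
        """Integer frame lags spanning the union support of all bases."""
        reach = self.centers[-1] + self.truncation * self.sigma
        L = int(np.ceil(reach * self.frame_rate))
        return np.arange(-L, L + 1)

    def sample(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample the bases on the frame clock.

        Returns ``(lags_s, B)`` where ``B[j, l]`` is basis ``j`` evaluated at
        lag ``lags_s[l]``; each basis has unit peak and is exactly zero beyond
        ``truncation`` standard deviations from its center.
        """
        lags = self.lag_frames() / self.frame_rate
        d = lags[None, :] - self.centers[:, None]
        B = np.exp(-0.5 * (d / self.sigma) ** 2)
        B[np.abs(d) > self.truncation * self.sigma] = 0.0
        return lags, B


def gaussian_basis(
    frame_rate: float = 30.0,
    hwhm: float = HWHM,
    past_positive: bool = True,
) -> BasisSet:
    """The canonical 21-Gaussian basis on a given frame clock."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n_side = int(round(CENTER_SPAN / CENTER_STEP))
    centers = np.arange(-n_side, n_side + 1) * CENTER_STEP
    return BasisSet(
        centers=centers, hwhm=hwhm, frame_rate=frame_rate,
        past_positive=past_positive,
    )


@dataclass
class DesignMatrix:
    """Basis-expanded behavioral design matrix.

    ``X`` has one column per (variable, basis center) pair; ``omitted`` marks
    rows whose lag window touched an omitted behavior frame, which must be
    excluded from all fits and scores.
    """

    X: np.ndarray  # (frames, n_vars * n_bases)
    columns: list[tuple[str, float]]  # (variable, basis center)
    variables: tuple[str, ...]
    basis: BasisSet
    omitted: np.ndarray  # (frames,) bool

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def category_column_indices(self, category: str) -> np.ndarray:
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {sorted(CATEGORIES)}"
            )
        names = set(CATEGORIES[category])
        return np.array(
            [k for k, (var, _) in enumerate(self.columns) if var in names], dtype=int
        )

    def subset(self, category: str, leave_out: bool = False) -> "DesignMatrix":
        """Columns of one category (or everything but that category)."""
        idx = self.category_column_indices(category)
        if leave_out:
            idx = np.setdiff1d(np.arange(self.n_columns), idx)
        return DesignMatrix(
            X=self.X[:, idx],
            columns=[self.columns[k] for k in idx],
            variables=tuple(dict.fromkeys(self.columns[k][0] for k in idx)),
            basis=self.basis,
            omitted=self.omitted,
        )


def expand_design(behavior: BehaviorMatrix, basis: BasisSet) -> DesignMatrix:
    """Convolve each of the 20 behavioral variables with every basis function.

    Column (v, c) at frame t equals ``sum_tau g_c(tau) * v(t - tau)`` with the
    signal treated as zero outside the recording (``t + tau`` when
    ``past_positive`` is False).  Rows whose lag window includes an omitted
    behavior frame are flagged in the output row mask.
    """
    if tuple(behavior.columns) != CANONICAL_COLUMNS:
        raise ValueError("behavior matrix lacks the canonical 20 columns")
    if abs(behavior.frame_rate - basis.frame_rate) > 1e-9:
        raise ValueError("behavior and basis frame rates differ")
    n = behavior.n_frames
    _, B = basis.sample()  # (n_bases, n_lags)
    kernels = B if basis.past_positive else B[:, ::-1]
    L = (kernels.shape[1] - 1) // 2

    # batched FFT convolution: (vars, 1, frames) * (1, bases, lags)
    data = behavior.data.T[:, None, :]
    conv = fftconvolve(data, kernels[None, :, :], axes=-1)  # (vars, bases, n+2L)
    conv = conv[:, :, L : L + n]
    n_vars = len(CANONICAL_COLUMNS)
    X = conv.reshape(n_vars * basis.n_bases, n).T.copy()

    columns = [
        (var, float(c)) for var in CANONICAL_COLUMNS for c in basis.centers
    ]
    if behavior.omitted.any():
        spread = fftconvolve(
            behavior.omitted.astype(float), np.ones(kernels.shape[1]), mode="full"
        )[L : L + n]
        omitted = spread > 0.5
    else:
        omitted = np.zeros(n, dtype=bool)
    return DesignMatrix(
        X=X,
        columns=columns,
        variables=CANONICAL_COLUMNS,
        basis=basis,
        omitted=omitted,
    )
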